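"""Readers and writers for every artifact the pipeline touches.

Formats are deliberately plain: FASTA for (aligned) sequences, TSV for the
sample table, pileups, traces, annotations and node annotations, Newick for
trees (with a sidecar TSV for node annotations), and YAML for configuration.
All coordinates in annotation files are 1-based inclusive, following the
GenBank convention.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .trees import TimeTree, parse_newick, tree_to_newick

logger = logging.getLogger("tipdating")

ALPHABET = set("ACGTN-")

__all__ = [
    "SampleRecord",
    "AgeStatus",
    "AnnotationTable",
    "AnnotationRow",
    "read_fasta",
    "write_fasta",
    "read_sample_table",
    "write_sample_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_pileup",
    "write_pileup",
    "read_trace",
    "write_trace",
    "read_newick",
    "write_newick",
    "load_config",
    "config_hash",
    "log_run",
]


class AgeStatus(str, Enum):
    CALIBRATED_FIXED = "calibrated_fixed"
    UNDATED = "undated"
    OUTGROUP_MODERN = "outgroup_modern"


@dataclass(frozen=True)
class SampleRecord:
    """Calibration metadata for one sequence.

    ``fixed_age`` (years BP) is required for calibrated and modern-outgroup
    samples; undated samples instead carry uniform prior bounds
    ``(prior_lo, prior_hi)``.
    """

    sample_id: str
    age_status: AgeStatus
    fixed_age: float | None = None
    prior_lo: float | None = None
    prior_hi: float | None = None

    def __post_init__(self):
        if self.age_status in (AgeStatus.CALIBRATED_FIXED, AgeStatus.OUTGROUP_MODERN):
            if self.fixed_age is None:
                raise ValueError(f"{self.sample_id}: fixed_age required for {self.age_status.value}")
            if self.fixed_age < 0:
                raise ValueError(f"{self.sample_id}: negative age")
        elif self.age_status is AgeStatus.UNDATED:
            if self.prior_lo is None or self.prior_hi is None:
                raise ValueError(f"{self.sample_id}: undated sample needs prior bounds")
            if not self.prior_lo < self.prior_hi:
                raise ValueError(f"{self.sample_id}: prior_lo must be < prior_hi")
            if self.prior_lo < 0:
                raise ValueError(f"{self.sample_id}: negative prior bound")


FEATURE_CLASSES = ("tRNA", "rRNA", "CDS", "control_region", "VNTR")


@dataclass(frozen=True)
class AnnotationRow:
    feature_class: str
    start: int  # 1-based inclusive, reference coordinates
    end: int
    codon_phase_origin: int | None = None  # reference coord of codon position 1 (CDS only)

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad interval {self.start}..{self.end}")
        if self.feature_class == "CDS" and self.codon_phase_origin is None:
            raise ValueError("CDS row requires codon_phase_origin")


@dataclass
class AnnotationTable:
    rows: list[AnnotationRow]

    def __post_init__(self):
        # distinct classes may not overlap, except VNTR within control_region
        for i, a in enumerate(self.rows):
            for b in self.rows[i + 1:]:
                if a.feature_class == b.feature_class:
                    continue
                pair = {a.feature_class, b.feature_class}
                if pair == {"VNTR", "control_region"}:
                    continue
                if a.start <= b.end and b.start <= a.end:
                    raise ValueError(
                        f"overlapping features {a.feature_class} and {b.feature_class}"
                    )

    def has_vntr(self) -> bool:
        return any(row.feature_class == "VNTR" for row in self.rows)

    def vntr(self) -> AnnotationRow:
        for row in self.rows:
            if row.feature_class == "VNTR":
                return row
        raise ValueError("annotation table has no VNTR row")


# ----------------------------------------------------------------------- FASTA
def read_fasta(path, alignment: bool = False) -> list[tuple[str, str]]:
    """Read FASTA records, uppercased and validated against {A,C,G,T,N,-}.

    With ``alignment=True``, all sequences must have equal length.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for name, seq in SimpleFastaParser(fh):
            rid = name.split()[0]
            if rid in seen:
                raise ValueError(f"duplicate FASTA id {rid!r}")
            seen.add(rid)
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence for {rid!r}")
            bad = set(seq) - ALPHABET
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in {rid!r}")
            records.append((rid, seq))
    if alignment and len({len(s) for _, s in records}) > 1:
        raise ValueError("ragged alignment: sequences differ in length")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------- sample table
_SAMPLE_COLS = ["sample_id", "age_status", "fixed_age", "prior_lo", "prior_hi"]


def read_sample_table(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(_SAMPLE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids {dups}")
    records = []
    for _, row in df.iterrows():
        def opt(col):
            v = row[col]
            return None if pd.isna(v) else float(v)
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                age_status=AgeStatus(row["age_status"]),
                fixed_age=opt("fixed_age"),
                prior_lo=opt("prior_lo"),
                prior_hi=opt("prior_hi"),
            )
        )
    return records


def write_sample_table(path, records: Sequence[SampleRecord]) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "age_status": r.age_status.value,
                "fixed_age": r.fixed_age,
                "prior_lo": r.prior_lo,
                "prior_hi": r.prior_hi,
            }
            for r in records
        ],
        columns=_SAMPLE_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ annotation
def read_annotation_table(path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t")
    rows = []
    for _, row in df.iterrows():
        origin = row.get("codon_phase_origin")
        rows.append(
            AnnotationRow(
                feature_class=row["feature_class"],
                start=int(row["start"]),
                end=int(row["end"]),
                codon_phase_origin=None if pd.isna(origin) else int(origin),
            )
        )
    return AnnotationTable(rows)


def write_annotation_table(path, table: AnnotationTable) -> None:
    pd.DataFrame(
        [
            {
                "feature_class": r.feature_class,
                "start": r.start,
                "end": r.end,
                "codon_phase_origin": r.codon_phase_origin,
            }
            for r in table.rows
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------- pileup
def read_pileup(path) -> np.ndarray:
    """Read a pileup TSV (columns pos, A, C, G, T, del) into an (L, 5) count array."""
    df = pd.read_csv(path, sep="\t")
    need = ["pos", "A", "C", "G", "T", "del"]
    if list(df.columns) != need:
        raise ValueError(f"pileup columns must be {need}")
    if not (df["pos"].values == np.arange(1, len(df) + 1)).all():
        raise ValueError("pileup positions must be 1..L in order")
    counts = df[["A", "C", "G", "T", "del"]].to_numpy(dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("negative pileup count")
    return counts


def write_pileup(path, counts: np.ndarray) -> None:
    df = pd.DataFrame(counts, columns=["A", "C", "G", "T", "del"])
    df.insert(0, "pos", np.arange(1, len(df) + 1))
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------- trace
def write_trace(path, trace) -> None:
    """Write a Trace as TSV at full float precision (lossless round-trip)."""
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    cols = ["iteration", "log_posterior", "log_likelihood", "log_prior"] + trace.parameter_names
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i in range(trace.n_samples):
            vals = [str(int(trace.iterations[i]))]
            vals += [format(v, ".17g") for v in (
                trace.log_posterior[i], trace.log_likelihood[i], trace.log_prior[i])]
            vals += [format(trace.parameters[name][i], ".17g") for name in trace.parameter_names]
            fh.write("\t".join(vals) + "\n")


def read_trace(path):
    from .mcmc_engine import Trace

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    fixed = ["iteration", "log_posterior", "log_likelihood", "log_prior"]
    for col in fixed:
        if col not in df.columns:
            raise ValueError(f"trace missing column {col!r}")
    if df["log_posterior"].isna().any() or not np.isfinite(df["log_posterior"]).all():
        raise ValueError("non-finite log_posterior in trace")
    pnames = [c for c in df.columns if c not in fixed]
    return Trace(
        iterations=df["iteration"].to_numpy(dtype=np.int64),
        log_posterior=df["log_posterior"].to_numpy(),
        log_likelihood=df["log_likelihood"].to_numpy(),
        log_prior=df["log_prior"].to_numpy(),
        parameters={name: df[name].to_numpy(dtype=float) for name in pnames},
    )


# ---------------------------------------------------------------------- newick
def write_newick(path, tree: TimeTree, annotations: dict[int, dict] | None = None) -> None:
    """Write plain Newick (branch lengths in years) plus an optional sidecar
    TSV (``<path>.nodes.tsv``) of per-node annotations keyed by clade."""
    Path(path).write_text(tree_to_newick(tree) + "\n")
    if annotations is not None:
        rows = []
        masks = tree.clade_bitmask()
        for node, ann in annotations.items():
            clade = "|".join(sorted(
                tree.labels[i] for i in range(tree.n_tips) if masks[node] >> i & 1))
            rows.append({"clade": clade, **ann})
        pd.DataFrame(rows).to_csv(str(path) + ".nodes.tsv", sep="\t", index=False)


def read_newick(path, tip_ages: dict[str, float] | None = None) -> TimeTree:
    return parse_newick(Path(path).read_text(), tip_ages=tip_ages)


# ---------------------------------------------------------------------- config
def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def log_run(cfg: dict, seeds: Sequence[int]) -> None:
    """Every run logs its config hash and all seeds (provenance contract)."""
    logger.info("run config_hash=%s seeds=%s", config_hash(cfg), list(seeds))
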