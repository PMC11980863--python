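"""Post-processing of a multiple sequence alignment.

The pipeline order is: remove singleton-support columns, transfer reference
annotations into alignment coordinates, mask the VNTR, and label every
column with one of the six analysis partitions (tRNA, rRNA, codon positions
1-3, control region).  Columns mapped from the VNTR are excluded from all
likelihood work, as are columns outside any annotated feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AnnotationTable

__all__ = [
    "PartitionedAlignment",
    "PARTITION_NAMES",
    "remove_singleton_columns",
    "ref_to_alignment_columns",
    "mask_vntr",
    "assign_partitions",
]

# order matters: integer codes index into this tuple
PARTITION_NAMES = (
    "tRNA", "rRNA", "codon1", "codon2", "codon3", "control_region", "masked", "unassigned",
)
MASKED = PARTITION_NAMES.index("masked")
UNASSIGNED = PARTITION_NAMES.index("unassigned")


@dataclass
class PartitionedAlignment:
    """Aligned sequences plus a per-column partition label.

    ``column_partition`` holds integer codes into :data:`PARTITION_NAMES`;
    columns are ``unassigned`` until :func:`assign_partitions` has run.
    """

    records: list[tuple[str, str]]
    reference_row_id: str
    column_partition: np.ndarray = field(default=None)

    def __post_init__(self):
        lengths = {len(s) for _, s in self.records}
        if len(lengths) > 1:
            raise ValueError("alignment sequences differ in length")
        if self.reference_row_id not in {rid for rid, _ in self.records}:
            raise ValueError(f"reference row {self.reference_row_id!r} not in alignment")
        if self.column_partition is None:
            self.column_partition = np.full(self.n_columns, UNASSIGNED, dtype=np.int8)
        elif len(self.column_partition) != self.n_columns:
            raise ValueError("column_partition length mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    def reference_sequence(self) -> str:
        for rid, seq in self.records:
            if rid == self.reference_row_id:
                return seq
        raise KeyError(self.reference_row_id)

    def partition_columns(self, name: str) -> np.ndarray:
        """0-based column indices carrying the given partition label."""
        return np.flatnonzero(self.column_partition == PARTITION_NAMES.index(name))

    def partition_records(self, name: str) -> list[tuple[str, str]]:
        """Sub-alignment restricted to one partition's columns."""
        cols = self.partition_columns(name)
        return [(rid, "".join(seq[c] for c in cols)) for rid, seq in self.records]


def remove_singleton_columns(
    aln: PartitionedAlignment,
) -> tuple[PartitionedAlignment, list[int]]:
    """Drop columns supported by a single sequence.

    A column is removed iff exactly one sequence carries a determinate base
    (A/C/G/T) and every other sequence carries '-'; such columns are
    single-sequence insertion artifacts.  All-gap columns are removed too.
    An N does not count as a gap assignment, so (A, N, -) is kept.
    Returned indices are 1-based alignment columns.
    """
    mat = np.array([list(seq) for _, seq in aln.records])
    is_base = np.isin(mat, list("ACGT"))
    is_gap = mat == "-"
    n_base = is_base.sum(axis=0)
    n_gap = is_gap.sum(axis=0)
    n_rows = mat.shape[0]
    singleton = (n_base == 1) & (n_gap == n_rows - 1)
    all_gap = n_gap == n_rows
    drop = singleton | all_gap
    keep = ~drop
    records = [(rid, "".join(np.compress(keep, list(seq)))) for rid, seq in aln.records]
    out = PartitionedAlignment(
        records=records,
        reference_row_id=aln.reference_row_id,
        column_partition=aln.column_partition[keep].copy(),
    )
    return out, [int(i) + 1 for i in np.flatnonzero(drop)]


def ref_to_alignment_columns(
    aln: PartitionedAlignment,
    start: int,
    end: int,
    include_gap_columns: bool = True,
) -> list[int]:
    """Map a 1-based inclusive reference interval to 1-based alignment columns.

    The k-th non-gap character of the reference row realizes reference
    position k.  Gap columns of the reference row that fall strictly inside
    the mapped span are included when ``include_gap_columns`` (the masking
    convention) and skipped otherwise.
    """
    ref = aln.reference_sequence()
    ungapped = sum(c != "-" for c in ref)
    if not (1 <= start <= end <= ungapped):
        raise ValueError(f"interval {start}..{end} outside ungapped reference (length {ungapped})")
    cols: list[int] = []
    k = 0
    first = last = None
    for col, c in enumerate(ref, start=1):
        if c == "-":
            continue
        k += 1
        if start <= k <= end:
            if first is None:
                first = col
            last = col
            cols.append(col)
    if include_gap_columns:
        return list(range(first, last + 1))
    return cols


def mask_vntr(aln: PartitionedAlignment, annotation: AnnotationTable) -> PartitionedAlignment:
    """Mask every alignment column mapped from the VNTR interval (idempotent)."""
    vntr = annotation.vntr()
    cols = ref_to_alignment_columns(aln, vntr.start, vntr.end, include_gap_columns=True)
    out = PartitionedAlignment(
        records=list(aln.records),
        reference_row_id=aln.reference_row_id,
        column_partition=aln.column_partition.copy(),
    )
    out.column_partition[np.asarray(cols) - 1] = MASKED
    return out


def assign_partitions(aln: PartitionedAlignment, annotation: AnnotationTable) -> PartitionedAlignment:
    """Label every unmasked column with its analysis partition.

    CDS columns are split into codon positions by
    ``(refpos - codon_phase_origin) mod 3`` cycling 1, 2, 3 from the feature's
    own origin.  Columns outside every feature stay unassigned (excluded from
    likelihood).  Previously masked columns stay masked.
    """
    out = PartitionedAlignment(
        records=list(aln.records),
        reference_row_id=aln.reference_row_id,
        column_partition=aln.column_partition.copy(),
    )
    ref = aln.reference_sequence()
    # refpos per alignment column (0 where the reference row is gapped)
    refpos = np.zeros(aln.n_columns, dtype=np.int64)
    k = 0
    for col, c in enumerate(ref):
        if c != "-":
            k += 1
            refpos[col] = k

    code = {"tRNA": 0, "rRNA": 1, "control_region": 5}
    for row in annotation.rows:
        if row.feature_class == "VNTR":
            continue  # handled by mask_vntr
        cols = ref_to_alignment_columns(aln, row.start, row.end, include_gap_columns=False)
        for col in cols:
            idx = col - 1
            if out.column_partition[idx] == MASKED:
                continue
            if row.feature_class == "CDS":
                phase = (refpos[idx] - row.codon_phase_origin) % 3  # 0,1,2 -> codon 1,2,3
                label = 2 + phase
            else:
                label = code[row.feature_class]
            if out.column_partition[idx] not in (UNASSIGNED, label):
                raise ValueError(f"conflicting feature assignment at column {col}")
            out.column_partition[idx] = label
    return out
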