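"""Synthetic heterochronous mitogenome datasets with known truth.

The generator emulates the structure of a deep-time mitogenome study: a
serially sampled ingroup whose calibrated tips span the radiocarbon range
(0-50 ka), undated deep-time tips with true ages up to ~1.3 Ma, and a modern
outgroup clade splitting from the ingroup near 5.3 Ma.  Sequences evolve
along the simulated genealogy under a strict clock with partitioned
HKY+Gamma+Invariant models; pileups add depth-variable sequencing evidence
with a uniform per-read error rate.  A truth table records everything the
recovery tests need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment_ops import PartitionedAlignment, assign_partitions, mask_vntr
from .clock_model import DemographicModel, SubstitutionParams, site_rate_mixture, _hky_eigensystem
from .io_formats import AgeStatus, AnnotationRow, AnnotationTable, SampleRecord
from .trees import TimeTree

__all__ = [
    "StudyConfig",
    "TruthTable",
    "simulate_genealogy",
    "simulate_alignment",
    "simulate_pileup",
    "make_study_dataset",
    "mammoth_annotation",
    "compact_annotation",
    "default_partition_params",
]

MITO_LENGTH = 16_770  # woolly reference mitogenome length
VNTR_START, VNTR_END = 16_157, 16_476


# ------------------------------------------------------------------- genealogy
def simulate_genealogy(
    sampling_ages: list[float],
    demog: DemographicModel,
    seed: int | np.random.Generator,
    labels: list[str] | None = None,
) -> TimeTree:
    """Simulate a serially sampled coalescent genealogy.

    Going back in time, lineages activate at their sampling ages and each
    active pair coalesces with hazard 1/Ne(t), i.e. total hazard
    k(k-1)/(2 Ne(t)) for k active lineages.  Grid demographies use exact
    piecewise-exponential waiting times.
    """
    n = len(sampling_ages)
    if n < 2:
        raise ValueError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if labels is None:
        labels = [f"t{i}" for i in range(n)]

    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    age = np.zeros(n_nodes)
    age[:n] = sampling_ages

    pending = sorted(range(n), key=lambda i: sampling_ages[i])
    active: list[int] = []
    t = sampling_ages[pending[0]]
    next_internal = n
    while len(active) + len(pending) > 1 or len(active) == 0:
        while pending and age[pending[0]] <= t + 1e-12:
            active.append(pending.pop(0))
        if len(active) < 2:
            t = age[pending[0]]
            continue
        k = len(active)
        target = rng.exponential()  # unit-exponential hazard budget
        horizon = age[pending[0]] if pending else np.inf
        t_coal = _advance_time(t, k, demog, target, horizon)
        if t_coal is None:  # hit the next sampling event first
            t = horizon
            continue
        t = t_coal
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        node = next_internal
        next_internal += 1
        age[node] = t
        left[node], right[node] = a, b
        parent[a] = parent[b] = node
        active = [x for x in active if x not in (a, b)] + [node]
    tree = TimeTree(labels=labels, parent=parent, left=left, right=right,
                    age=age, root=n_nodes - 1)
    tree.validate()
    return tree


def _advance_time(t0, k, demog, target, horizon):
    """Solve for the next coalescence under piecewise-constant Ne, or None if
    the hazard budget is not spent before ``horizon``."""
    pair = 0.5 * k * (k - 1)
    t = t0
    while True:
        ne = demog.size_at(t)
        if demog.mode == "grid":
            later = demog.boundaries[demog.boundaries > t]
            seg_end = float(later[0]) if len(later) else np.inf
        else:
            seg_end = np.inf
        seg_end = min(seg_end, horizon)
        hazard = pair / ne
        capacity = hazard * (seg_end - t)
        if target <= capacity:
            return t + target / hazard
        if seg_end >= horizon:
            return None
        target -= capacity
        t = seg_end


# -------------------------------------------------------------------- sequences
def _evolve_partition(tree, n_sites, params, clock_rate, rng) -> np.ndarray:
    """Simulate one partition's columns (n_tips, n_sites) of base codes 0..3."""
    cats = site_rate_mixture(params.gamma_shape, params.n_categories, params.p_inv)
    rates = np.array([r for r, _ in cats])
    weights = np.array([w for _, w in cats])
    site_cat = rng.choice(len(cats), size=n_sites, p=weights)
    U, lam, Uinv = _hky_eigensystem(params.kappa, params.freqs)

    states = np.empty((tree.n_nodes, n_sites), dtype=np.int8)
    states[tree.root] = rng.choice(4, size=n_sites, p=params.freqs)
    for node in tree.postorder()[::-1]:  # preorder: parents before children
        node = int(node)
        if node == tree.root:
            continue
        dur = tree.age[int(tree.parent[node])] - tree.age[node]
        dist = clock_rate * params.relative_rate * dur * rates  # per category
        P = np.einsum("ij,cj,jk->cik", U, np.exp(lam[None, :] * dist[:, None]), Uinv)
        P = np.clip(P, 0.0, None)
        P /= P.sum(axis=2, keepdims=True)
        probs = P[site_cat, states[int(tree.parent[node])]]  # (n_sites, 4)
        u = rng.random(n_sites)
        states[node] = (u[:, None] > probs.cumsum(axis=1)).sum(axis=1)
    return states[: tree.n_tips]


def simulate_alignment(
    tree: TimeTree,
    annotation: AnnotationTable,
    length: int,
    params_by_partition: dict[str, SubstitutionParams],
    clock_rate: float,
    seed: int | np.random.Generator,
) -> PartitionedAlignment:
    """Evolve a gap-free partitioned alignment down a dated genealogy.

    Column partitions come from the annotation (first tip is the reference
    row; the alignment is ungapped so reference and alignment coordinates
    coincide).  Masked (VNTR) and unassigned columns are simulated under the
    control-region model so that every column carries sequence.
    """
    if clock_rate < 0:
        raise ValueError("clock_rate must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blank = PartitionedAlignment(
        records=[(lab, "A" * length) for lab in tree.labels],
        reference_row_id=tree.labels[0],
    )
    if annotation.has_vntr():
        blank = mask_vntr(blank, annotation)
    labelled = assign_partitions(blank, annotation)
    col_part = labelled.column_partition

    from .alignment_ops import MASKED, PARTITION_NAMES, UNASSIGNED

    mat = np.empty((tree.n_tips, length), dtype=np.int8)
    for code in np.unique(col_part):
        cols = np.flatnonzero(col_part == code)
        name = PARTITION_NAMES[code]
        if code in (MASKED, UNASSIGNED):
            name = "control_region"
        params = params_by_partition[name]
        mat[:, cols] = _evolve_partition(tree, len(cols), params, clock_rate, rng)

    bases = np.array(list("ACGT"))
    records = [(lab, "".join(bases[mat[i]])) for i, lab in enumerate(tree.labels)]
    return PartitionedAlignment(records=records, reference_row_id=tree.labels[0],
                                column_partition=col_part)


# ---------------------------------------------------------------------- pileups
def simulate_pileup(
    true_seq: str,
    mean_depth: float,
    depth_dispersion: float = 5.0,
    error_rate: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate per-position base counts over (A, C, G, T, del).

    Depth is negative-binomial with the given mean and dispersion (variance
    mean + mean^2/dispersion); each read base equals the truth with
    probability 1 - error_rate, otherwise uniform over the three alternative
    bases.  A '-' in the truth yields deletion-supporting reads.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not (0 <= error_rate < 0.25):
        raise ValueError("error_rate must lie in [0, 0.25)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    symbols = "ACGT-"
    L = len(true_seq)
    p = depth_dispersion / (depth_dispersion + mean_depth)
    depths = rng.negative_binomial(depth_dispersion, p, size=L)
    counts = np.zeros((L, 5), dtype=np.int64)
    for pos, (truth, depth) in enumerate(zip(true_seq, depths)):
        if depth == 0:
            continue
        k = symbols.index(truth)
        if truth == "-":
            counts[pos, 4] = depth
            continue
        errors = rng.binomial(depth, error_rate)
        counts[pos, k] = depth - errors
        if errors:
            alts = [i for i in range(4) if i != k]
            counts[pos, alts] += rng.multinomial(errors, [1 / 3] * 3)
    return counts


# ----------------------------------------------------------------- study dataset
def mammoth_annotation() -> AnnotationTable:
    """Six-partition layout of a 16,770 bp mitogenome with the VNTR at
    reference positions 16157-16476 inside the control region."""
    rows = [
        AnnotationRow("tRNA", 1, 70),
        AnnotationRow("rRNA", 71, 1030),
        AnnotationRow("tRNA", 1031, 1175),
        AnnotationRow("rRNA", 1176, 2750),
        AnnotationRow("tRNA", 2751, 2895),
        AnnotationRow("CDS", 2896, 7000, codon_phase_origin=2896),
        AnnotationRow("tRNA", 7001, 7145),
        AnnotationRow("CDS", 7146, 11000, codon_phase_origin=7146),
        AnnotationRow("tRNA", 11001, 11145),
        AnnotationRow("CDS", 11146, 15300, codon_phase_origin=11146),
        AnnotationRow("tRNA", 15301, 15446),
        AnnotationRow("control_region", 15447, MITO_LENGTH),
        AnnotationRow("VNTR", VNTR_START, VNTR_END),
    ]
    return AnnotationTable(rows)


def compact_annotation(length: int) -> AnnotationTable:
    """Proportionally scaled layout for desk-scale alignments (>= 100 bp)."""
    if length < 100:
        raise ValueError("compact annotation needs length >= 100")
    t_end = max(1, length // 20)
    r_end = t_end + max(1, (15 * length) // 100)
    c_end = r_end + max(3, (55 * length) // 100)
    c_end = min(c_end, length - 20)
    cr_start = c_end + 1
    cr_len = length - cr_start + 1
    v_start = cr_start + cr_len // 3
    v_end = v_start + cr_len // 3
    rows = [
        AnnotationRow("tRNA", 1, t_end),
        AnnotationRow("rRNA", t_end + 1, r_end),
        AnnotationRow("CDS", r_end + 1, c_end, codon_phase_origin=r_end + 1),
        AnnotationRow("control_region", cr_start, length),
        AnnotationRow("VNTR", v_start, v_end),
    ]
    return AnnotationTable(rows)


def default_partition_params(
    column_counts: dict[str, int] | None = None,
) -> dict[str, SubstitutionParams]:
    """Mitogenome-flavoured substitution parameters per partition.

    Relative rates reflect the usual contrast between constrained (codon 2,
    tRNA) and fast (codon 3, control region) sites; if ``column_counts`` is
    given they are renormalized to a column-weighted mean of 1.
    """
    freqs = np.array([0.31, 0.26, 0.13, 0.30])
    spec = {
        "tRNA": dict(gamma_shape=None, p_inv=0.6, relative_rate=0.5),
        "rRNA": dict(gamma_shape=0.3, p_inv=0.4, relative_rate=0.7),
        "codon1": dict(gamma_shape=0.3, p_inv=0.4, relative_rate=0.8),
        "codon2": dict(gamma_shape=0.3, p_inv=0.5, relative_rate=0.4),
        "codon3": dict(gamma_shape=0.3, p_inv=0.2, relative_rate=2.5),
        "control_region": dict(gamma_shape=0.3, p_inv=0.3, relative_rate=3.0),
    }
    if column_counts:
        total = sum(column_counts.values())
        mean = sum(spec[n]["relative_rate"] * c for n, c in column_counts.items()) / total
        for n in spec:
            spec[n]["relative_rate"] /= mean
    return {n: SubstitutionParams(kappa=20.0, freqs=freqs.copy(), **kw) for n, kw in spec.items()}


@dataclass
class StudyConfig:
    """Generating conditions for a synthetic study dataset."""

    n_calibrated: int = 20
    n_undated: int = 1
    n_outgroup: int = 2
    seq_length: int = MITO_LENGTH
    annotation: AnnotationTable | None = None
    Ne: float = 5e5                      # ingroup pairwise-coalescence scale, years
    outgroup_Ne: float = 5e5
    clock_rate: float = 3e-8             # substitutions/site/year
    root_median: float = 5.3e6           # ingroup/outgroup divergence, years BP
    root_sigma: float = 0.05
    calibrated_age_range: tuple[float, float] = (0.0, 50_000.0)
    undated_age_range: tuple[float, float] = (100_000.0, 1_300_000.0)
    tip_prior: tuple[float, float] = (1_000.0, 2_000_000.0)

    def resolved_annotation(self) -> AnnotationTable:
        if self.annotation is not None:
            return self.annotation
        if self.seq_length == MITO_LENGTH:
            return mammoth_annotation()
        return compact_annotation(self.seq_length)


@dataclass
class TruthTable:
    """Everything the generator knows that the inference is asked to recover."""

    tip_ages: dict[str, float]
    clock_rate: float
    params_by_partition: dict[str, SubstitutionParams]
    demog: DemographicModel
    root_age: float
    undated_ids: list[str] = field(default_factory=list)


def make_study_dataset(
    config: StudyConfig, seed: int
) -> tuple[PartitionedAlignment, list[SampleRecord], TimeTree, TruthTable]:
    """Generate (alignment, sample table, true genealogy, truth table).

    The sample table hides the undated tips' true ages behind the uniform
    prior bounds; calibrated and outgroup tips carry their generating ages.
    """
    if config.n_undated > 0 and config.n_calibrated < 2:
        raise ValueError("undated tips require at least 2 calibrated reference tips")
    if config.n_calibrated + config.n_undated < 2:
        raise ValueError("ingroup needs at least 2 tips")
    rng = np.random.default_rng(seed)

    cal_ages = rng.uniform(*config.calibrated_age_range, size=config.n_calibrated)
    und_ages = np.sort(rng.uniform(*config.undated_age_range, size=config.n_undated))
    cal_ids = [f"cal{i:03d}" for i in range(config.n_calibrated)]
    und_ids = [f"und{i:03d}" for i in range(config.n_undated)]
    out_ids = [f"out{i:03d}" for i in range(config.n_outgroup)]

    demog = DemographicModel(mode="constant", Ne=config.Ne)
    ingroup = simulate_genealogy(
        list(cal_ages) + list(und_ages), demog, rng, labels=cal_ids + und_ids)

    if config.n_outgroup == 0:
        tree = ingroup
        root_age = float(tree.age[tree.root])
    else:
        if config.n_outgroup == 1:
            out_tree = None
            out_root_age = 0.0
        else:
            out_demog = DemographicModel(mode="constant", Ne=config.outgroup_Ne)
            out_tree = simulate_genealogy([0.0] * config.n_outgroup, out_demog,
                                          rng, labels=out_ids)
            out_root_age = float(out_tree.age[out_tree.root])
        # divergence age from the calibration distribution, forced above both
        # subtree roots so the joined tree is valid
        floor = 1.01 * max(float(ingroup.age[ingroup.root]), out_root_age)
        root_age = float(config.root_median * rng.lognormal(0.0, config.root_sigma))
        root_age = max(root_age, floor)
        tree = _join_at_root(ingroup, out_tree, out_ids, root_age)

    annotation = config.resolved_annotation()
    blank = PartitionedAlignment(
        records=[(lab, "A" * config.seq_length) for lab in tree.labels],
        reference_row_id=tree.labels[0])
    if annotation.has_vntr():
        blank = mask_vntr(blank, annotation)
    labelled = assign_partitions(blank, annotation)
    from .alignment_ops import PARTITION_NAMES

    counts = {
        name: int((labelled.column_partition == code).sum())
        for code, name in enumerate(PARTITION_NAMES)
        if name not in ("masked", "unassigned")
        and (labelled.column_partition == code).any()
    }
    params = default_partition_params(counts)
    aln = simulate_alignment(tree, annotation, config.seq_length, params,
                             config.clock_rate, rng)

    table: list[SampleRecord] = []
    for sid, a in zip(cal_ids, cal_ages):
        table.append(SampleRecord(sid, AgeStatus.CALIBRATED_FIXED, fixed_age=float(a)))
    for sid in und_ids:
        table.append(SampleRecord(sid, AgeStatus.UNDATED,
                                  prior_lo=config.tip_prior[0], prior_hi=config.tip_prior[1]))
    for sid in out_ids:
        table.append(SampleRecord(sid, AgeStatus.OUTGROUP_MODERN, fixed_age=0.0))

    truth = TruthTable(
        tip_ages={lab: float(tree.age[i]) for i, lab in enumerate(tree.labels)},
        clock_rate=config.clock_rate,
        params_by_partition=params,
        demog=demog,
        root_age=root_age,
        undated_ids=und_ids,
    )
    return aln, table, tree, truth


def _join_at_root(ingroup: TimeTree, out_tree: TimeTree | None,
                  out_ids: list[str], root_age: float) -> TimeTree:
    """Join ingroup and outgroup subtrees under a new root at ``root_age``."""
    n_out = len(out_ids)
    labels = list(ingroup.labels) + out_ids
    n_tips = len(labels)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    age = np.zeros(n_nodes)

    def copy_subtree(sub: TimeTree, tip_offset: int, internal_offset: int):
        remap = {}
        for node in range(sub.n_nodes):
            remap[node] = node + tip_offset if sub.is_tip(node) else node + internal_offset
        for node in range(sub.n_nodes):
            new = remap[node]
            age[new] = sub.age[node]
            if not sub.is_tip(node):
                l, r = sub.children(node)
                left[new], right[new] = remap[l], remap[r]
                parent[remap[l]] = new
                parent[remap[r]] = new
        return remap[sub.root]

    in_root = copy_subtree(ingroup, 0, n_out)  # internal nodes shift by n_out new tips
    if out_tree is None:
        out_root = ingroup.n_tips  # the single outgroup tip
        age[out_root] = 0.0
    else:
        out_root = copy_subtree(out_tree, ingroup.n_tips, ingroup.n_nodes)
    root = n_nodes - 1
    age[root] = root_age
    left[root], right[root] = in_root, out_root
    parent[in_root] = parent[out_root] = root
    tree = TimeTree(labels=labels, parent=parent, left=left, right=right, age=age, root=root)
    tree.validate()
    return tree
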