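"""Metropolis-Hastings sampling over tip ages, node heights, topology and
model parameters, with trace diagnostics and MCC-tree summarization.

The sampler is a random-scan single-move MH chain.  Scale moves act on the
clock rate, kappa, Gamma shape and Ne; undated tip ages get uniform-window
and scale moves; node heights slide within their parent/child bounds; the
root height is rescaled above its oldest child; topology is sampled by
narrow exchange plus a leaf prune-and-reattach move for undated tips.
Proposal scales are auto-tuned toward ~23% acceptance during burn-in only.

Diagnostics follow the usual practice for Bayesian tip dating: effective
sample size from the initial-positive-sequence autocorrelation estimator,
shortest-interval HPDs, split-chain potential scale reduction for a chain
pair, and a kernel-density unimodality check on tip-age posteriors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alignment_ops import PartitionedAlignment, PARTITION_NAMES
from .clock_model import (
    CalibrationPrior,
    ClockModel,
    DemographicModel,
    ParameterPriors,
    PartitionLikelihood,
    SubstitutionParams,
    log_prior,
)
from .io_formats import AgeStatus, SampleRecord
from .trees import TimeTree

logger = logging.getLogger("tipdating")

__all__ = [
    "MCMCConfig",
    "Trace",
    "TipDateEstimate",
    "ConvergenceReport",
    "run_chain",
    "effective_sample_size",
    "hpd_interval",
    "check_convergence",
    "unimodality_check",
    "mcc_tree",
]


# ---------------------------------------------------------------- configuration
@dataclass
class MCMCConfig:
    """Sampler and model settings for one dating analysis.

    Desk-scale defaults; the study-scale analogue (two chains of 1e8
    iterations thinned every 1e4) is obtained by overriding the first three
    fields.
    """

    n_iterations: int = 20_000
    thin: int = 10
    burn_in_fraction: float = 0.1
    n_chains: int = 2
    prior_only: bool = False
    sample_topology: bool = True
    sample_trees: bool = False
    sample_substitution_params: bool = True
    ne_init: float = 5e5
    sample_ne: bool = True
    clock_init: float = 2e-8
    kappa_init: float = 10.0
    alpha_init: float = 0.5
    pinv_init: float = 0.3
    no_gamma_partitions: tuple[str, ...] = ("tRNA",)
    root_median: float | None = 5.3e6
    root_sigma: float = 0.05
    priors: ParameterPriors = field(default_factory=ParameterPriors)


# ----------------------------------------------------------------------- traces
@dataclass
class Trace:
    """Retained (post burn-in, thinned) MCMC samples."""

    iterations: np.ndarray
    log_posterior: np.ndarray
    log_likelihood: np.ndarray
    log_prior: np.ndarray
    parameters: dict[str, np.ndarray]
    trees: list[TimeTree] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.iterations) and (np.diff(self.iterations) <= 0).any():
            raise ValueError("trace iterations must be strictly increasing")
        if len(self.iterations) and not np.isfinite(self.log_posterior).all():
            raise ValueError("non-finite log_posterior in retained trace")

    @property
    def n_samples(self) -> int:
        return len(self.iterations)

    @property
    def parameter_names(self) -> list[str]:
        return list(self.parameters)

    def get(self, name: str) -> np.ndarray:
        if name not in self.parameters:
            raise KeyError(f"parameter {name!r} not in trace")
        return self.parameters[name]


@dataclass
class TipDateEstimate:
    """Posterior age summary for one sample, averaged over a chain pair."""

    sample_id: str
    mean: float
    hpd_lo: float
    hpd_hi: float
    ess: float
    unimodal: bool
    converged: bool
    per_chain: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)  # config hash, seeds, Rhat

    @property
    def reliable(self) -> bool:
        return self.converged and self.unimodal


@dataclass
class ConvergenceReport:
    passed: bool
    ess_a: float
    ess_b: float
    rhat: float


# ----------------------------------------------------------------- chain state
class _ChainState:
    __slots__ = ("tree", "clock", "kappa", "alpha", "pinv", "relrate", "ne",
                 "grid_log_sizes", "tau", "part_ll")

    def copy(self):
        s = _ChainState()
        s.tree = self.tree.copy()
        s.clock = self.clock
        s.kappa = self.kappa.copy()
        s.alpha = list(self.alpha)
        s.pinv = self.pinv.copy()
        s.relrate = self.relrate.copy()
        s.ne = self.ne
        s.grid_log_sizes = None if self.grid_log_sizes is None else self.grid_log_sizes.copy()
        s.tau = self.tau
        s.part_ll = self.part_ll.copy()
        return s


class _Model:
    """Bundles the dataset-dependent pieces: partition likelihoods, empirical
    frequencies, calibrations, and the prior evaluation."""

    def __init__(self, alignment: PartitionedAlignment, samples: list[SampleRecord],
                 config: MCMCConfig):
        self.config = config
        ids = [r.sample_id for r in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        by_id = dict(alignment.records)
        missing = [i for i in ids if i not in by_id]
        if missing:
            raise ValueError(f"alignment missing samples {missing}")

        self.ingroup = [r for r in samples if r.age_status != AgeStatus.OUTGROUP_MODERN]
        self.outgroup = [r for r in samples if r.age_status == AgeStatus.OUTGROUP_MODERN]
        self.samples = self.ingroup + self.outgroup
        self.labels = [r.sample_id for r in self.samples]
        self.undated = [r for r in self.samples if r.age_status == AgeStatus.UNDATED]

        # partitions with assigned columns; fall back to a single partition
        self.part_names = [
            name for name in PARTITION_NAMES[:6]
            if (alignment.column_partition == PARTITION_NAMES.index(name)).any()
        ]
        if self.part_names:
            part_records = {n: alignment.partition_records(n) for n in self.part_names}
        else:
            self.part_names = ["all"]
            part_records = {"all": [(rid, by_id[rid]) for rid in self.labels]}
        self.col_counts = np.array(
            [len(part_records[n][0][1]) for n in self.part_names], dtype=float)
        self.likelihoods = [
            PartitionLikelihood(part_records[n], self.labels) for n in self.part_names
        ]
        self.freqs = [self._empirical_freqs(part_records[n]) for n in self.part_names]
        self._precomp: dict[int, tuple] = {}

        tip_priors: dict[str, tuple] = {}
        for r in self.samples:
            if r.age_status == AgeStatus.UNDATED:
                tip_priors[r.sample_id] = ("uniform", r.prior_lo, r.prior_hi)
            else:
                tip_priors[r.sample_id] = ("fixed", r.fixed_age)
        self.calibrations = CalibrationPrior(
            root_median=config.root_median,
            root_sigma=config.root_sigma,
            tip_priors=tip_priors,
            outgroup_labels=tuple(r.sample_id for r in self.outgroup),
        )

    @staticmethod
    def _empirical_freqs(records) -> np.ndarray:
        counts = np.ones(4)
        for _, seq in records:
            for i, b in enumerate("ACGT"):
                counts[i] += seq.count(b)
        return counts / counts.sum()

    def n_parts(self) -> int:
        return len(self.part_names)

    def params_for(self, state: _ChainState, p: int) -> SubstitutionParams:
        # bypass dataclass validation in the sampler hot path; proposals
        # guarantee positivity and the priors guard the support
        obj = SubstitutionParams.__new__(SubstitutionParams)
        obj.kappa = float(state.kappa[p])
        obj.freqs = self.freqs[p]
        obj.gamma_shape = state.alpha[p]
        obj.n_categories = 4
        obj.p_inv = float(state.pinv[p])
        obj.relative_rate = float(state.relrate[p])
        return obj

    def demog_for(self, state: _ChainState) -> DemographicModel:
        return DemographicModel(mode="constant", Ne=state.ne)

    def log_prior(self, state: _ChainState) -> float:
        params = [self.params_for(state, p) for p in range(self.n_parts())]
        return log_prior(state.tree, params, ClockModel(state.clock),
                         self.demog_for(state), self.calibrations, self.config.priors)

    def partition_ll(self, state: _ChainState, p: int) -> float:
        if self.config.prior_only:
            return 0.0
        params = self.params_for(state, p)
        key = (p, params.kappa, params.gamma_shape, params.p_inv)
        precomp = self._precomp.get(key)
        if precomp is None:
            if len(self._precomp) > 64:
                self._precomp.clear()
            precomp = PartitionLikelihood.precompute(params)
            self._precomp[key] = precomp
        return self.likelihoods[p].loglik(
            state.tree, params, ClockModel(state.clock), precomp=precomp)


# ------------------------------------------------------------------- proposals
def _scale_factor(rng, s):
    return float(np.exp(s * (rng.random() - 0.5)))


def _init_state(model: _Model, config: MCMCConfig, rng) -> _ChainState:
    from .synthetic_data import _join_at_root, simulate_genealogy

    state = _ChainState()
    P = model.n_parts()
    state.clock = config.clock_init
    state.kappa = np.full(P, config.kappa_init)
    state.alpha = [None if model.part_names[p] in config.no_gamma_partitions
                   else config.alpha_init for p in range(P)]
    state.pinv = np.full(P, config.pinv_init)
    state.relrate = np.ones(P)
    state.ne = config.ne_init
    state.grid_log_sizes = None
    state.tau = None
    state.part_ll = np.zeros(P)

    def init_age(r: SampleRecord) -> float:
        if r.age_status == AgeStatus.UNDATED:
            return 0.5 * (r.prior_lo + r.prior_hi)  # prior midpoint
        return r.fixed_age

    in_ages = [init_age(r) for r in model.ingroup]
    in_labels = [r.sample_id for r in model.ingroup]
    demog = DemographicModel(mode="constant", Ne=config.ne_init)
    if len(model.ingroup) >= 2:
        ingroup_tree = simulate_genealogy(in_ages, demog, rng, labels=in_labels)
    else:
        raise ValueError("need at least 2 ingroup samples")
    if model.outgroup:
        out_labels = [r.sample_id for r in model.outgroup]
        if len(out_labels) == 1:
            out_tree = None
        else:
            out_tree = simulate_genealogy([r.fixed_age for r in model.outgroup],
                                          demog, rng, labels=out_labels)
        floor = 1.05 * max(
            float(ingroup_tree.age[ingroup_tree.root]),
            0.0 if out_tree is None else float(out_tree.age[out_tree.root]),
            max(r.fixed_age for r in model.outgroup),
        )
        target = config.root_median if config.root_median else floor
        tree = _join_at_root(ingroup_tree, out_tree, out_labels, max(floor, target))
    else:
        tree = ingroup_tree
    state.tree = tree
    return state


def _move_tip_age(state, model, rng, scale, kind):
    und = model.undated
    if not und:
        return None
    r = und[rng.integers(len(und))]
    i = state.tree.labels.index(r.sample_id)
    new = state.copy()
    old_age = state.tree.age[i]
    if kind == "window":
        new_age = old_age + scale * (rng.random() - 0.5)
        logh = 0.0
    else:
        f = _scale_factor(rng, scale)
        new_age = old_age * f
        logh = np.log(f)
    parent = int(new.tree.parent[i])
    if new_age < 0 or (parent >= 0 and new_age >= new.tree.age[parent]):
        return None
    new.tree.age[i] = new_age
    return new, logh, "tree"


def _move_tip_stem(state, model, rng, scale):
    """Translate an undated tip together with its parent node, preserving the
    stem length; escapes the squeeze between a tip and its parent."""
    und = model.undated
    if not und:
        return None
    r = und[rng.integers(len(und))]
    tree = state.tree
    x = tree.labels.index(r.sample_id)
    p = int(tree.parent[x])
    delta = scale * (rng.random() - 0.5)
    new_tip = tree.age[x] + delta
    new_p = tree.age[p] + delta
    if new_tip < 0:
        return None
    sib = int(tree.left[p]) if int(tree.right[p]) == x else int(tree.right[p])
    if new_p <= max(new_tip, tree.age[sib]):
        return None
    gp = int(tree.parent[p])
    if gp >= 0 and new_p >= tree.age[gp]:
        return None
    new = state.copy()
    new.tree.age[x] = new_tip
    new.tree.age[p] = new_p
    return new, 0.0, "tree"


def _move_node_slide(state, model, rng, scale):
    tree = state.tree
    internal = [n for n in range(tree.n_tips, tree.n_nodes) if n != tree.root]
    if not internal:
        return None
    node = internal[rng.integers(len(internal))]
    lo = max(tree.age[c] for c in tree.children(node))
    hi = tree.age[int(tree.parent[node])]
    if hi <= lo:
        return None
    new = state.copy()
    new.tree.age[node] = lo + (hi - lo) * rng.random()
    return new, 0.0, "tree"


def _move_root_scale(state, model, rng, scale):
    tree = state.tree
    c = max(tree.age[ch] for ch in tree.children(tree.root))
    f = _scale_factor(rng, scale)
    new = state.copy()
    new.tree.age[tree.root] = c + (tree.age[tree.root] - c) * f
    return new, float(np.log(f)), "tree"


def _move_narrow_exchange(state, model, rng, scale):
    tree = state.tree
    cands = [n for n in range(tree.n_tips, tree.n_nodes) if n != tree.root]
    if not cands:
        return None
    p = int(cands[rng.integers(len(cands))])
    g = int(tree.parent[p])
    s = int(tree.left[g]) if int(tree.right[g]) == p else int(tree.right[g])
    c = int(tree.left[p]) if rng.random() < 0.5 else int(tree.right[p])
    if tree.age[p] <= tree.age[s]:
        return None
    new = state.copy()
    t = new.tree
    # swap c and s
    if int(t.left[p]) == c:
        t.left[p] = s
    else:
        t.right[p] = s
    if int(t.left[g]) == s:
        t.left[g] = c
    else:
        t.right[g] = c
    t.parent[s] = p
    t.parent[c] = g
    t.invalidate()
    return new, 0.0, "tree"


def _move_tip_reattach(state, model, rng, scale):
    """Prune an undated tip and reattach it on a uniformly chosen edge at a
    uniform height, or above the root at an exponentially distributed height
    (rate set by the current Ne, unchanged by the move, so the proposal is
    symmetric in its parametrization)."""
    und = model.undated
    if not und:
        return None
    r = und[rng.integers(len(und))]
    tree = state.tree
    x = tree.labels.index(r.sample_id)
    p = int(tree.parent[x])
    p_was_root = p == tree.root
    sib = int(tree.left[p]) if int(tree.right[p]) == x else int(tree.right[p])

    new = state.copy()
    t = new.tree
    # detach: p floats; sib takes p's place (or becomes the root)
    if p_was_root:
        t.parent[sib] = -1
        t.root = sib
    else:
        g = int(t.parent[p])
        if int(t.left[g]) == p:
            t.left[g] = sib
        else:
            t.right[g] = sib
        t.parent[sib] = g
    t.parent[p] = -1

    lam = max(float(state.ne), 1.0)  # above-root height scale
    lo_old = max(t.age[x], t.age[sib])
    if p_was_root:
        old_logq = -np.log(lam) - (tree.age[p] - lo_old) / lam
    else:
        old_logq = -float(np.log(t.age[g] - lo_old))

    # candidate edges in the pruned tree, plus the above-root option
    cands = []
    for b in range(t.n_nodes):
        if b in (x, p) or int(t.parent[b]) == -1:
            continue
        q = int(t.parent[b])
        lo = max(t.age[x], t.age[b])
        if t.age[q] > lo:
            cands.append((b, q, lo))
    n_options = len(cands) + 1
    pick = int(rng.integers(n_options))
    if pick == len(cands):  # attach above the pruned root
        root = t.root
        lo = max(t.age[x], t.age[root])
        h = lo + rng.exponential(lam)
        new_logq = -np.log(lam) - (h - lo) / lam
        t.parent[root] = p
        t.left[p], t.right[p] = root, x
        t.parent[x] = p
        t.age[p] = h
        t.parent[p] = -1
        t.root = p
    else:
        b, q, lo = cands[pick]
        h = lo + (t.age[q] - lo) * rng.random()
        new_logq = -float(np.log(t.age[q] - lo))
        if int(t.left[q]) == b:
            t.left[q] = p
        else:
            t.right[q] = p
        t.parent[p] = q
        t.left[p], t.right[p] = b, x
        t.parent[b] = p
        t.parent[x] = p
        t.age[p] = h
    t.invalidate()
    return new, float(old_logq - new_logq), "tree"


def _move_updown(state, model, rng, scale):
    """Scale the clock rate down and all internal-node ages up by a common
    factor (tip ages fixed), breaking the rate-height anticorrelation."""
    tree = state.tree
    f = _scale_factor(rng, scale)
    new = state.copy()
    new.clock = state.clock / f
    internal = np.arange(tree.n_tips, tree.n_nodes)
    new.tree.age[internal] = tree.age[internal] * f
    # validity: every tip must stay below its parent
    tips = np.arange(tree.n_tips)
    if (new.tree.age[tree.parent[tips]] <= new.tree.age[tips]).any():
        return None
    k = len(internal)
    return new, float((k - 1) * np.log(f)), "all_parts"


def _move_tree_scale(state, model, rng, scale):
    """Scale all internal-node ages by a common factor (tips fixed)."""
    tree = state.tree
    f = _scale_factor(rng, scale)
    new = state.copy()
    internal = np.arange(tree.n_tips, tree.n_nodes)
    new.tree.age[internal] = tree.age[internal] * f
    tips = np.arange(tree.n_tips)
    if (new.tree.age[tree.parent[tips]] <= new.tree.age[tips]).any():
        return None
    return new, float(len(internal) * np.log(f)), "tree"


def _move_clock(state, model, rng, scale):
    f = _scale_factor(rng, scale)
    new = state.copy()
    new.clock = state.clock * f
    return new, float(np.log(f)), "all_parts"


def _move_kappa(state, model, rng, scale):
    p = rng.integers(model.n_parts())
    f = _scale_factor(rng, scale)
    new = state.copy()
    new.kappa[p] = state.kappa[p] * f
    return new, float(np.log(f)), ("part", int(p))


def _move_alpha(state, model, rng, scale):
    parts = [p for p in range(model.n_parts()) if state.alpha[p] is not None]
    if not parts:
        return None
    p = parts[rng.integers(len(parts))]
    f = _scale_factor(rng, scale)
    new = state.copy()
    new.alpha[p] = state.alpha[p] * f
    return new, float(np.log(f)), ("part", int(p))


def _move_pinv(state, model, rng, scale):
    p = rng.integers(model.n_parts())
    new = state.copy()
    v = state.pinv[p] + scale * (rng.random() - 0.5)
    if not (0.0 <= v <= 0.99):
        return None
    new.pinv[p] = v
    return new, 0.0, ("part", int(p))


def _move_relrate(state, model, rng, scale):
    P = model.n_parts()
    if P < 2:
        return None
    i, j = rng.choice(P, size=2, replace=False)
    d = scale * (rng.random() - 0.5)
    wi, wj = model.col_counts[i], model.col_counts[j]
    new = state.copy()
    new.relrate[i] = state.relrate[i] + d
    new.relrate[j] = state.relrate[j] - d * wi / wj
    if new.relrate[i] <= 0 or new.relrate[j] <= 0:
        return None
    return new, 0.0, ("part2", int(i), int(j))


def _move_ne(state, model, rng, scale):
    f = _scale_factor(rng, scale)
    new = state.copy()
    new.ne = state.ne * f
    return new, float(np.log(f)), "prior"


# -------------------------------------------------------------------- the chain
def run_chain(
    dataset: tuple[PartitionedAlignment, list[SampleRecord]],
    config: MCMCConfig,
    n_iterations: int | None = None,
    thin: int | None = None,
    burn_in_fraction: float | None = None,
    seed: int | None = None,
) -> Trace:
    """Run one MH chain and return the retained trace.

    ``dataset`` is (alignment, sample table).  A seed is mandatory; there is
    no silent default randomness.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    alignment, samples = dataset
    n_iterations = n_iterations or config.n_iterations
    thin = thin or config.thin
    burn_frac = config.burn_in_fraction if burn_in_fraction is None else burn_in_fraction

    rng = np.random.default_rng(seed)
    model = _Model(alignment, samples, config)

    state = None
    for _ in range(1000):
        cand = _init_state(model, config, rng)
        lp = model.log_prior(cand)
        if np.isfinite(lp):
            state = cand
            break
    if state is None:
        raise RuntimeError("no finite-posterior initial state after 1000 attempts")
    for p in range(model.n_parts()):
        state.part_ll[p] = model.partition_ll(state, p)
    cur_prior = model.log_prior(state)
    cur_ll = float(state.part_ll.sum())

    moves = [
        ("clock", 3.0, lambda s, r, sc: _move_clock(s, model, r, sc), 0.5),
        ("updown", 4.0, lambda s, r, sc: _move_updown(s, model, r, sc), 0.2),
        ("tree_scale", 3.0, lambda s, r, sc: _move_tree_scale(s, model, r, sc), 0.2),
        ("ne", 3.0, lambda s, r, sc: _move_ne(s, model, r, sc), 1.0),
        ("tip_window", 4.0, lambda s, r, sc: _move_tip_age(s, model, r, sc, "window"), 2e5),
        ("tip_scale", 2.0, lambda s, r, sc: _move_tip_age(s, model, r, sc, "scale"), 0.7),
        ("tip_stem", 4.0, lambda s, r, sc: _move_tip_stem(s, model, r, sc), 4e5),
        ("node_slide", 8.0, lambda s, r, sc: _move_node_slide(s, model, r, sc), 1.0),
        ("root_scale", 2.0, lambda s, r, sc: _move_root_scale(s, model, r, sc), 0.3),
    ]
    if config.sample_substitution_params:
        moves += [
            ("kappa", 2.0, lambda s, r, sc: _move_kappa(s, model, r, sc), 0.5),
            ("alpha", 2.0, lambda s, r, sc: _move_alpha(s, model, r, sc), 0.7),
            ("pinv", 2.0, lambda s, r, sc: _move_pinv(s, model, r, sc), 0.15),
        ]
        if model.n_parts() > 1:
            moves += [("relrate", 2.0, lambda s, r, sc: _move_relrate(s, model, r, sc), 0.3)]
    if not config.sample_ne:
        moves = [m for m in moves if m[0] != "ne"]
    if config.sample_topology and state.tree.n_tips >= 3:
        moves += [
            ("narrow", 4.0, lambda s, r, sc: _move_narrow_exchange(s, model, r, sc), 1.0),
        ]
        if model.undated:
            moves += [
                ("reattach", 4.0, lambda s, r, sc: _move_tip_reattach(s, model, r, sc), 1.0),
            ]
    names = [m[0] for m in moves]
    weights = np.array([m[1] for m in moves])
    weights /= weights.sum()
    funcs = [m[2] for m in moves]
    scales = {n: m[3] for n, m in zip(names, moves)}
    proposed = {n: 0 for n in names}
    accepted = {n: 0 for n in names}
    batch = {n: [0, 0] for n in names}  # proposals, acceptances in current tuning batch

    burn_end = int(burn_frac * n_iterations)
    iters, lposts, llikes, lpriors = [], [], [], []
    par_samples: dict[str, list[float]] = {}
    trees: list[TimeTree] = []

    def record(it):
        iters.append(it)
        lposts.append(cur_prior + cur_ll)
        llikes.append(cur_ll)
        lpriors.append(cur_prior)
        cols = _state_columns(state, model)
        for k, v in cols.items():
            par_samples.setdefault(k, []).append(v)
        if config.sample_trees:
            trees.append(state.tree.copy())

    for it in range(1, n_iterations + 1):
        mi = rng.choice(len(moves), p=weights)
        name = names[mi]
        proposed[name] += 1
        batch[name][0] += 1
        out = funcs[mi](state, rng, scales[name])
        if out is not None:
            cand, logh, affected = out
            new_prior = model.log_prior(cand)
            if np.isfinite(new_prior):
                if affected == "prior":
                    pass
                elif affected == "tree" or affected == "all_parts":
                    for p in range(model.n_parts()):
                        cand.part_ll[p] = model.partition_ll(cand, p)
                elif affected[0] == "part":
                    p = affected[1]
                    cand.part_ll[p] = model.partition_ll(cand, p)
                elif affected[0] == "part2":
                    for p in affected[1:]:
                        cand.part_ll[p] = model.partition_ll(cand, p)
                new_ll = float(cand.part_ll.sum())
                log_ratio = (new_prior + new_ll) - (cur_prior + cur_ll) + logh
                if np.log(rng.random()) < log_ratio:
                    state, cur_prior, cur_ll = cand, new_prior, new_ll
                    accepted[name] += 1
                    batch[name][1] += 1
        # burn-in-only tuning toward ~23% acceptance
        if it <= burn_end and batch[name][0] >= 50:
            rate = batch[name][1] / batch[name][0]
            scales[name] = float(np.clip(
                scales[name] * np.exp(rate - 0.234), scales[name] * 0.5, scales[name] * 2.0))
            batch[name] = [0, 0]
        if it > burn_end and it % thin == 0:
            record(it)

    acc_rates = {n: (accepted[n] / proposed[n] if proposed[n] else float("nan"))
                 for n in names}
    logger.info("chain seed=%s acceptance=%s", seed,
                {k: round(v, 3) for k, v in acc_rates.items()})
    return Trace(
        iterations=np.array(iters, dtype=np.int64),
        log_posterior=np.array(lposts),
        log_likelihood=np.array(llikes),
        log_prior=np.array(lpriors),
        parameters={k: np.array(v) for k, v in par_samples.items()},
        trees=trees if config.sample_trees else None,
        meta={"acceptance_rates": acc_rates, "seed": seed,
              "n_iterations": n_iterations, "thin": thin,
              "burn_in_fraction": burn_frac, "final_scales": dict(scales)},
    )


def _state_columns(state: _ChainState, model: _Model) -> dict[str, float]:
    cols = {"clock_rate": state.clock, "Ne": state.ne,
            "root_age": float(state.tree.age[state.tree.root])}
    for p, name in enumerate(model.part_names):
        cols[f"kappa_{name}"] = float(state.kappa[p])
        if state.alpha[p] is not None:
            cols[f"alpha_{name}"] = float(state.alpha[p])
        cols[f"pinv_{name}"] = float(state.pinv[p])
        cols[f"relrate_{name}"] = float(state.relrate[p])
    for r in model.undated:
        i = state.tree.labels.index(r.sample_id)
        cols[f"tip_age_{r.sample_id}"] = float(state.tree.age[i])
    return cols


# ------------------------------------------------------------------ diagnostics
def effective_sample_size(series: np.ndarray) -> float:
    """ESS from the initial-positive-sequence autocorrelation estimator:
    N / (1 + 2 sum rho_k), truncated at the first non-positive pair sum."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 samples")
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        raise ValueError("constant series has no defined ESS")
    # autocovariance by FFT
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    # Geyer initial positive sequence on paired sums
    tau = 0.0
    for k in range(0, n - 1, 2):
        pair = rho[k] + (rho[k + 1] if k + 1 < n else 0.0)
        if pair <= 0:
            break
        tau += pair
    iat = max(2.0 * tau - 1.0, 1.0)
    return float(n / iat)


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval over the order statistics containing
    ceil(mass * N) points (ties resolved toward the lowest lower bound)."""
    if not (0 < mass < 1):
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 20:
        raise ValueError("need at least 20 samples")
    m = int(np.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def check_convergence(trace_a: Trace, trace_b: Trace, parameter: str,
                      ess_threshold: float = 200.0,
                      rhat_threshold: float = 1.05) -> ConvergenceReport:
    """Chain-pair convergence: both ESS above threshold and split-chain
    potential scale reduction below threshold."""
    a = trace_a.get(parameter)
    b = trace_b.get(parameter)
    ess_a = effective_sample_size(a)
    ess_b = effective_sample_size(b)
    rhat = _split_rhat([a, b])
    passed = ess_a > ess_threshold and ess_b > ess_threshold and rhat < rhat_threshold
    return ConvergenceReport(passed=bool(passed), ess_a=ess_a, ess_b=ess_b, rhat=rhat)


def _split_rhat(chains: list[np.ndarray]) -> float:
    halves = []
    for c in chains:
        h = len(c) // 2
        halves += [c[:h], c[h: 2 * h]]
    n = min(len(h) for h in halves)
    halves = np.stack([h[:n] for h in halves])
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def unimodality_check(samples: np.ndarray, rel_height: float = 0.10) -> bool:
    """Mode count of a Silverman-bandwidth KDE; modes below ``rel_height`` of
    the global maximum are ignored.  True iff exactly one mode survives."""
    x = np.asarray(samples, dtype=float)
    if len(x) < 100:
        raise ValueError("need at least 100 samples")
    if np.ptp(x) == 0:
        return True
    kde = stats.gaussian_kde(x, bw_method="silverman")
    bw = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, 1024)
    d = kde(grid)
    interior = (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])
    peaks = d[1:-1][interior]
    n_modes = int((peaks >= rel_height * d.max()).sum())
    return n_modes <= 1


# --------------------------------------------------------------------- MCC tree
def mcc_tree(trees: list[TimeTree]) -> tuple[TimeTree, dict[int, dict]]:
    """Maximum clade credibility summary of a posterior tree sample.

    The MCC tree is the *sampled* tree maximizing the sum of log posterior
    clade frequencies; its nodes are annotated with clade support and the
    mean and 95% HPD of matching-clade heights across the whole sample.
    """
    if not trees:
        raise ValueError("empty tree sample")
    tipset = tuple(sorted(trees[0].labels))
    order = {lab: i for i, lab in enumerate(sorted(trees[0].labels))}

    def clades(tree: TimeTree) -> dict[int, int]:
        """node -> canonical clade bitmask (over sorted labels)."""
        masks = {}
        for node in tree.postorder():
            node = int(node)
            if tree.is_tip(node):
                masks[node] = 1 << order[tree.labels[node]]
            else:
                masks[node] = masks[int(tree.left[node])] | masks[int(tree.right[node])]
        return masks

    freq: dict[int, int] = {}
    heights: dict[int, list[float]] = {}
    per_tree_masks = []
    for tree in trees:
        if tuple(sorted(tree.labels)) != tipset:
            raise ValueError("inconsistent tip sets in tree sample")
        masks = clades(tree)
        per_tree_masks.append(masks)
        for node, mask in masks.items():
            if tree.is_tip(node):
                continue
            freq[mask] = freq.get(mask, 0) + 1
            heights.setdefault(mask, []).append(float(tree.age[node]))

    n = len(trees)
    best_i, best_score = 0, -np.inf
    for i, masks in enumerate(per_tree_masks):
        score = sum(np.log(freq[mask] / n)
                    for node, mask in masks.items() if not trees[i].is_tip(node))
        if score > best_score:
            best_i, best_score = i, score
    best = trees[best_i].copy()
    annotations: dict[int, dict] = {}
    for node, mask in per_tree_masks[best_i].items():
        if best.is_tip(node):
            continue
        hs = np.array(heights[mask])
        if len(hs) >= 20:
            lo, hi = hpd_interval(hs, 0.95)
        else:
            lo, hi = float(hs.min()), float(hs.max())
        annotations[node] = {
            "posterior": freq[mask] / n,
            "height_mean": float(hs.mean()),
            "height_hpd_lo": lo,
            "height_hpd_hi": hi,
        }
    return best, annotations
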