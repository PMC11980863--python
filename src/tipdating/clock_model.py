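"""Probabilistic core: partitioned HKY+Gamma+Invariant likelihood on a dated
tree under a strict clock, heterochronous coalescent tree priors (constant or
piecewise-constant "skygrid" effective size), and calibration/tip priors.

Everything is evaluable as a log-density.  The substitution process is the
HKY85 model with its rate matrix normalized to one expected substitution per
site per unit distance at stationarity, so a branch's distance is simply
``clock_rate x relative_rate x category_rate x duration``.  Among-site rate
variation uses the discrete-Gamma approximation (equal-weight quantile bins,
per-bin mean rates) plus an optional proportion of invariant sites; the
mixture is renormalized to mean rate exactly 1.

Tree likelihoods are computed by Felsenstein's pruning algorithm with site
pattern compression; N and '-' are fully ambiguous states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, special, stats

from .trees import TimeTree

__all__ = [
    "SubstitutionParams",
    "ClockModel",
    "DemographicModel",
    "CalibrationPrior",
    "ParameterPriors",
    "hky_transition_matrix",
    "site_rate_mixture",
    "PartitionLikelihood",
    "partition_log_likelihood",
    "coalescent_log_density",
    "gmrf_log_prior",
    "log_prior",
    "log_posterior",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


# ------------------------------------------------------------------- parameters
@dataclass
class SubstitutionParams:
    """HKY+Gamma+Invariant parameters for one partition.

    ``gamma_shape=None`` drops the Gamma component (HKY+I); ``relative_rate``
    scales this partition's clock relative to the others (mean-1 constraint
    across partitions is enforced at the model level, not per instance).
    """

    kappa: float
    freqs: np.ndarray
    gamma_shape: float | None = None
    n_categories: int = 4
    p_inv: float = 0.0
    relative_rate: float = 1.0

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.freqs.shape != (4,) or (self.freqs <= 0).any():
            raise ValueError("freqs must be 4 positive values")
        if abs(self.freqs.sum() - 1.0) > 1e-12:
            raise ValueError("freqs must sum to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must lie in [0, 1)")
        if self.relative_rate <= 0:
            raise ValueError("relative_rate must be positive")


@dataclass
class ClockModel:
    """Strict molecular clock: one rate (substitutions/site/year) for all branches."""

    rate: float

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("clock rate must be positive")


@dataclass
class DemographicModel:
    """Constant or grid ("skygrid") effective size.

    Sizes are on the haploid-lineage scale, in years of pairwise coalescence
    time.  Grid mode has K epoch boundaries (years BP, increasing) and K+1
    sizes; ``sizes[0]`` applies on [0, boundaries[0]) and ``sizes[-1]``
    beyond the last boundary.  ``gmrf_precision`` is the smoothing precision
    of the Gaussian random walk on log sizes (grid mode only).
    """

    mode: str = "constant"
    Ne: float | None = None
    boundaries: np.ndarray | None = None
    sizes: np.ndarray | None = None
    gmrf_precision: float | None = None

    def __post_init__(self):
        if self.mode == "constant":
            if self.Ne is None or self.Ne <= 0:
                raise ValueError("constant mode requires Ne > 0")
        elif self.mode == "grid":
            self.boundaries = np.asarray(self.boundaries, dtype=float)
            self.sizes = np.asarray(self.sizes, dtype=float)
            if (self.sizes <= 0).any():
                raise ValueError("all grid sizes must be positive")
            if len(self.sizes) != len(self.boundaries) + 1:
                raise ValueError("grid needs K boundaries and K+1 sizes")
            if (np.diff(self.boundaries) <= 0).any() or (self.boundaries <= 0).any():
                raise ValueError("boundaries must be positive and strictly increasing")
            if self.gmrf_precision is not None and self.gmrf_precision <= 0:
                raise ValueError("gmrf_precision must be positive")
        else:
            raise ValueError(f"unknown demographic mode {self.mode!r}")

    def size_at(self, t: float) -> float:
        if self.mode == "constant":
            return float(self.Ne)
        idx = int(np.searchsorted(self.boundaries, t, side="right"))
        return float(self.sizes[idx])

    def inverse_size_integral(self, t0: float, t1: float) -> float:
        """Integral of 1/Ne(t) over [t0, t1] (piecewise exact)."""
        if t1 < t0:
            raise ValueError("t1 < t0")
        if self.mode == "constant":
            return (t1 - t0) / self.Ne
        edges = np.concatenate([[t0], self.boundaries[(self.boundaries > t0) & (self.boundaries < t1)], [t1]])
        total = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            total += (b - a) / self.size_at(0.5 * (a + b))
        return total


@dataclass
class CalibrationPrior:
    """Root calibration plus per-tip age priors.

    The root (ingroup/outgroup divergence) carries a log-normal prior with
    real-space median ``root_median`` and log-scale sd ``root_sigma``; set
    ``root_median=None`` to disable.  ``tip_priors`` maps sample id to either
    ``("fixed", age)`` or ``("uniform", lo, hi)``.  If ``outgroup_labels`` is
    non-empty, ingroup monophyly is required (violations get -inf) and the
    calibration applies to the root.
    """

    root_median: float | None = 5.3e6
    root_sigma: float = 0.05
    tip_priors: dict[str, tuple] = field(default_factory=dict)
    outgroup_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.root_median is not None and self.root_median <= 0:
            raise ValueError("root_median must be positive")
        if self.root_sigma <= 0:
            raise ValueError("root_sigma must be positive")
        for sid, spec in self.tip_priors.items():
            if spec[0] == "uniform" and not spec[1] < spec[2]:
                raise ValueError(f"{sid}: uniform prior needs lo < hi")


@dataclass
class ParameterPriors:
    """Vague priors on the free model parameters (all configurable).

    kappa: log-normal on log kappa; gamma shape: exponential; p_inv: uniform
    on [0,1); clock rate and Ne: scale-uniform (1/x) within bounds.
    """

    kappa_log_mu: float = 1.0
    kappa_log_sigma: float = 1.25
    alpha_exp_mean: float = 0.5
    clock_bounds: tuple[float, float] = (1e-12, 1e-4)
    ne_bounds: tuple[float, float] = (1e2, 1e9)
    gmrf_tau_shape: float = 0.001
    gmrf_tau_rate: float = 0.001


# ------------------------------------------------------------------ HKY kernel
def _hky_eigensystem(kappa: float, freqs: np.ndarray):
    """Eigendecomposition (U, lam, Uinv) of the mean-rate-1 HKY generator."""
    pi = np.asarray(freqs, dtype=float)
    Q = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            transition = (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1))  # A<->G, C<->T
            Q[i, j] = (kappa if transition else 1.0) * pi[j]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))  # mean rate at stationarity
    Q /= mu
    d = np.sqrt(pi)
    B = (Q * d[:, None]) / d[None, :]
    B = 0.5 * (B + B.T)  # symmetrize against rounding
    lam, V = np.linalg.eigh(B)
    U = V / d[:, None]
    Uinv = V.T * d[None, :]
    return U, lam, Uinv


def hky_transition_matrix(params: SubstitutionParams, expected_subs: float) -> np.ndarray:
    """HKY transition-probability matrix at a branch distance in subs/site."""
    if expected_subs < 0:
        raise ValueError("negative branch distance")
    U, lam, Uinv = _hky_eigensystem(params.kappa, params.freqs)
    P = (U * np.exp(lam * expected_subs)) @ Uinv
    return np.clip(P, 0.0, None)


# ------------------------------------------------------------------ rate mixture
def site_rate_mixture(
    alpha: float | None, n_categories: int = 4, p_inv: float = 0.0
) -> list[tuple[float, float]]:
    """(rate, weight) categories of the Gamma+Invariant site-rate mixture.

    One category of rate 0 carries the invariant weight; the Gamma part is
    discretized into ``n_categories`` equal-weight quantile bins, each
    represented by its within-bin mean rate.  The whole mixture is rescaled
    to mean rate exactly 1.
    """
    if p_inv >= 1 or p_inv < 0:
        raise ValueError("p_inv must lie in [0, 1)")
    if alpha is None:
        gamma_rates = np.array([1.0])
    else:
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        n = n_categories
        # bin edges on the Gamma(alpha, scale=1/alpha) scale
        edges = special.gammaincinv(alpha, np.arange(n + 1) / n) / alpha
        # within-bin means: E[X; a<X<b] = P(alpha+1 bin) / (1/n), with E[X]=1
        upper = special.gammainc(alpha + 1, alpha * edges[1:])
        lower = special.gammainc(alpha + 1, alpha * edges[:-1])
        gamma_rates = n * (upper - lower)
    weights = np.full(len(gamma_rates), (1.0 - p_inv) / len(gamma_rates))
    rates = gamma_rates / (1.0 - p_inv)
    # renormalize to mean exactly 1 (closed form is already exact up to rounding)
    rates /= np.dot(weights, rates)
    cats = [(0.0, float(p_inv))] if p_inv > 0 else []
    cats += [(float(r), float(w)) for r, w in zip(rates, weights)]
    return cats


# --------------------------------------------------------------- tree likelihood
try:  # compiled pruning kernel; numpy fallback keeps the module importable
    from numba import njit

    @njit(cache=False, fastmath=True)
    def _prune_kernel(order, left, right, n_tips, dist, rates, U, lam, Uinv,
                      tipL, counts, freqs, weights, partial, logscale):
        C = rates.shape[0]
        npat = tipL.shape[2]
        logscale[:] = 0.0
        Pc = np.empty((C, 4, 4))
        for oi in range(order.shape[0]):
            node = order[oi]
            if node < n_tips:
                continue
            acc = partial[node - n_tips]
            for side in range(2):
                ch = left[node] if side == 0 else right[node]
                d = dist[ch]
                for c in range(C):
                    e0 = np.exp(lam[0] * d * rates[c])
                    e1 = np.exp(lam[1] * d * rates[c])
                    e2 = np.exp(lam[2] * d * rates[c])
                    e3 = np.exp(lam[3] * d * rates[c])
                    for i in range(4):
                        for j in range(4):
                            v = (U[i, 0] * e0 * Uinv[0, j] + U[i, 1] * e1 * Uinv[1, j]
                                 + U[i, 2] * e2 * Uinv[2, j] + U[i, 3] * e3 * Uinv[3, j])
                            Pc[c, i, j] = v if v > 0.0 else 0.0
                if ch < n_tips:
                    src = tipL[ch]
                    for c in range(C):
                        for i in range(4):
                            p0, p1, p2, p3 = Pc[c, i, 0], Pc[c, i, 1], Pc[c, i, 2], Pc[c, i, 3]
                            if side == 0:
                                for p in range(npat):
                                    acc[c, i, p] = (p0 * src[0, p] + p1 * src[1, p]
                                                    + p2 * src[2, p] + p3 * src[3, p])
                            else:
                                for p in range(npat):
                                    acc[c, i, p] *= (p0 * src[0, p] + p1 * src[1, p]
                                                     + p2 * src[2, p] + p3 * src[3, p])
                else:
                    chp = partial[ch - n_tips]
                    for c in range(C):
                        for i in range(4):
                            p0, p1, p2, p3 = Pc[c, i, 0], Pc[c, i, 1], Pc[c, i, 2], Pc[c, i, 3]
                            if side == 0:
                                for p in range(npat):
                                    acc[c, i, p] = (p0 * chp[c, 0, p] + p1 * chp[c, 1, p]
                                                    + p2 * chp[c, 2, p] + p3 * chp[c, 3, p])
                            else:
                                for p in range(npat):
                                    acc[c, i, p] *= (p0 * chp[c, 0, p] + p1 * chp[c, 1, p]
                                                     + p2 * chp[c, 2, p] + p3 * chp[c, 3, p])
            for p in range(npat):
                m = 0.0
                for c in range(C):
                    for i in range(4):
                        if acc[c, i, p] > m:
                            m = acc[c, i, p]
                if m <= 0.0:
                    m = 1.0
                for c in range(C):
                    for i in range(4):
                        acc[c, i, p] /= m
                logscale[p] += np.log(m)
        root = order[order.shape[0] - 1]
        total = 0.0
        for p in range(npat):
            site = 0.0
            for c in range(C):
                s = 0.0
                for j in range(4):
                    s += freqs[j] * partial[root - n_tips, c, j, p]
                site += weights[c] * s
            if site <= 0.0:
                return -np.inf
            total += counts[p] * (np.log(site) + logscale[p])
        return total

    @njit(cache=False)
    def _coal_const_kernel(age, n_tips, n_nodes, ne):
        idx = np.argsort(age)
        logp = 0.0
        k = 0
        i = 0
        n_events = n_nodes
        t_prev = age[idx[0]]
        while i < n_events:
            t = age[idx[i]]
            if k >= 2 and t > t_prev:
                logp -= 0.5 * k * (k - 1) * (t - t_prev) / ne
            # process all events at this age: samplings first, then coalescences
            j = i
            n_samp = 0
            n_coal = 0
            while j < n_events and age[idx[j]] == t:
                if idx[j] < n_tips:
                    n_samp += 1
                else:
                    n_coal += 1
                j += 1
            k += n_samp
            for _ in range(n_coal):
                if k < 2:
                    return np.nan
                logp -= np.log(ne)
                k -= 1
            t_prev = t
            i = j
        if k != 1:
            return np.nan
        return logp

    @njit(cache=False)
    def _mono_kernel(order, left, right, n_tips, is_out):
        """True iff some clade contains every non-outgroup tip and nothing else."""
        n_in = 0
        for i in range(n_tips):
            if is_out[i] == 0:
                n_in += 1
        n_all = np.zeros(order.shape[0], dtype=np.int64)
        n_o = np.zeros(order.shape[0], dtype=np.int64)
        for oi in range(order.shape[0]):
            node = order[oi]
            if node < n_tips:
                n_all[node] = 1
                n_o[node] = is_out[node]
            else:
                n_all[node] = n_all[left[node]] + n_all[right[node]]
                n_o[node] = n_o[left[node]] + n_o[right[node]]
            if n_all[node] == n_in and n_o[node] == 0:
                return True
        return False

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to 0..3 for bases, 4 for fully ambiguous (N, -)."""
    out = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


class PartitionLikelihood:
    """Pruning likelihood for one partition, reusable across MCMC proposals.

    Site patterns and tip partials are precomputed once; :meth:`loglik` then
    evaluates the partition's log-likelihood for any (tree, params, clock).
    """

    def __init__(self, records: list[tuple[str, str]], tip_labels: list[str]):
        by_id = dict(records)
        if set(tip_labels) - set(by_id):
            missing = sorted(set(tip_labels) - set(by_id))
            raise ValueError(f"alignment missing sequences for tips {missing}")
        mat = np.stack([_encode(by_id[lab]) for lab in tip_labels])
        self.n_sites = mat.shape[1]
        if self.n_sites == 0:
            self.patterns = np.zeros((len(tip_labels), 0), dtype=np.int8)
            self.counts = np.zeros(0)
        else:
            patterns, counts = np.unique(mat, axis=1, return_counts=True)
            self.patterns = patterns
            self.counts = counts.astype(float)
        # tip partial templates: (n_tips, 4, n_patterns)
        n_tips, npat = self.patterns.shape
        tipL = np.zeros((n_tips, 4, npat))
        for s in range(4):
            tipL[:, s, :] = (self.patterns == s) | (self.patterns == 4)
        self.tip_partials = tipL
        self._scratch = None  # reusable pruning buffers (numba path)

    @staticmethod
    def precompute(params: SubstitutionParams) -> tuple:
        """Rate mixture and HKY eigensystem, reusable while the partition's
        parameters are unchanged (tree moves don't invalidate it)."""
        cats = site_rate_mixture(params.gamma_shape, params.n_categories, params.p_inv)
        rates = np.array([r for r, _ in cats])
        weights = np.array([w for _, w in cats])
        U, lam, Uinv = _hky_eigensystem(params.kappa, params.freqs)
        return rates, weights, U, lam, Uinv

    def loglik(
        self,
        tree: TimeTree,
        params: SubstitutionParams,
        clock: ClockModel,
        precomp: tuple | None = None,
    ) -> float:
        npat = self.patterns.shape[1]
        if npat == 0:
            return 0.0
        if precomp is None:
            precomp = self.precompute(params)
        rates, weights, U, lam, Uinv = precomp

        order = tree.postorder()
        parent = tree.parent
        # distances per node (to its parent): substitutions/site
        durations = np.where(parent >= 0, tree.age[parent] - tree.age, 0.0)
        if (durations < -1e-9).any():
            raise ValueError("negative branch duration")
        dist = clock.rate * params.relative_rate * np.clip(durations, 0.0, None)

        if _HAVE_NUMBA:
            n_int = tree.n_nodes - tree.n_tips
            scratch = self._scratch
            if scratch is None or scratch[0].shape[0] != n_int or scratch[0].shape[1] != len(rates):
                scratch = (np.empty((n_int, len(rates), 4, npat)), np.empty(npat))
                self._scratch = scratch
            return float(_prune_kernel(
                order, tree.left, tree.right, tree.n_tips, dist, rates,
                U, lam, Uinv, self.tip_partials, self.counts,
                params.freqs, weights, scratch[0], scratch[1]))

        expo = np.exp(lam[None, None, :] * (dist[:, None] * rates[None, :])[:, :, None])
        # P[n, c] = U diag(expo) Uinv  -> (n_nodes, C, 4, 4)
        P = np.einsum("ij,ncj,jk->ncik", U, expo, Uinv)
        np.clip(P, 0.0, None, out=P)

        partial = [None] * tree.n_nodes
        logscale = np.zeros(npat)
        for node in order:
            node = int(node)
            if tree.is_tip(node):
                continue
            acc = None
            for child in tree.children(node):
                if tree.is_tip(child):
                    contrib = np.matmul(P[child], self.tip_partials[child])
                else:
                    contrib = np.matmul(P[child], partial[child])
                    partial[child] = None
                acc = contrib if acc is None else acc * contrib
            # rescale per pattern to avoid underflow
            m = acc.max(axis=(0, 1))
            m = np.where(m > 0, m, 1.0)
            acc /= m
            logscale += np.log(m)
            partial[node] = acc
        rootL = partial[tree.root]  # (C, 4, npat)
        site = np.einsum("c,j,cjp->p", weights, params.freqs, rootL)
        if (site <= 0).any():
            return -np.inf
        return float(np.dot(self.counts, np.log(site) + logscale))


def partition_log_likelihood(
    tree: TimeTree,
    records: list[tuple[str, str]],
    params: SubstitutionParams,
    clock: ClockModel,
) -> float:
    """Log-likelihood of one partition's columns on a dated tree.

    ``records`` are (tip label, sequence) pairs restricted to the partition's
    columns; N and '-' are fully ambiguous.
    """
    return PartitionLikelihood(records, tree.labels).loglik(tree, params, clock)


# ------------------------------------------------------------------- coalescent
def coalescent_log_density(tree: TimeTree, demog: DemographicModel) -> float:
    """Heterochronous coalescent log-density of a dated genealogy.

    Going back in time, with k active lineages the pair-coalescence hazard is
    k(k-1)/(2 Ne(t)); each coalescence contributes log(1/Ne(t)).  This is the
    density of the labelled genealogy given the tip sampling times, and
    integrates to one over genealogies.
    """
    n = tree.n_tips
    if demog.mode == "constant" and _HAVE_NUMBA:
        logp = _coal_const_kernel(tree.age, n, tree.n_nodes, demog.Ne)
        if np.isnan(logp):
            raise ValueError("invalid event sequence for a coalescent genealogy")
        return float(logp)
    if demog.mode == "constant":
        # vectorized: sampling events add a lineage, coalescences remove one
        kind = np.concatenate([np.zeros(n), np.ones(tree.n_nodes - n)])
        idx = np.lexsort((kind, tree.age))  # ties: sampling before coalescence
        ages = tree.age[idx]
        delta = np.where(kind[idx] == 0, 1, -1)
        full = np.cumsum(delta)
        if full[-1] != 1 or (full < 1).any():
            raise ValueError("invalid event sequence for a coalescent genealogy")
        k_in_interval = full[:-1]  # lineage count between consecutive events
        pairs = 0.5 * k_in_interval * (k_in_interval - 1)
        logp = -float(np.dot(pairs, np.diff(ages))) / demog.Ne
        logp -= (n - 1) * np.log(demog.Ne)
        return float(logp)
    events = [(float(tree.age[i]), 0) for i in range(n)]  # sampling: k += 1
    events += [(float(tree.age[i]), 1) for i in range(n, tree.n_nodes)]  # coalescence
    events.sort()
    logp = 0.0
    k = 0
    t_prev = events[0][0]
    for t, kind in events:
        if t > t_prev and k >= 2:
            logp -= 0.5 * k * (k - 1) * demog.inverse_size_integral(t_prev, t)
        t_prev = max(t_prev, t)
        if kind == 0:
            k += 1
        else:
            if k < 2:
                raise ValueError("coalescence with fewer than 2 active lineages")
            logp -= np.log(demog.size_at(t))
            k -= 1
    return float(logp)


def gmrf_log_prior(demog: DemographicModel, priors: ParameterPriors | None = None) -> float:
    """First-order Gaussian random-walk prior on log Ne over the grid, plus a
    Gamma hyperprior on the precision tau."""
    if demog.mode != "grid":
        raise ValueError("GMRF prior applies to grid mode only")
    if demog.gmrf_precision is None:
        raise ValueError("grid model has no gmrf_precision")
    priors = priors or ParameterPriors()
    tau = demog.gmrf_precision
    diffs = np.diff(np.log(demog.sizes))
    logp = float(np.sum(stats.norm.logpdf(diffs, scale=1.0 / np.sqrt(tau))))
    logp += float(stats.gamma.logpdf(tau, a=priors.gmrf_tau_shape,
                                     scale=1.0 / priors.gmrf_tau_rate))
    return logp


# ------------------------------------------------------------------ joint prior
def log_prior(
    tree: TimeTree,
    params_list: list[SubstitutionParams],
    clock: ClockModel,
    demog: DemographicModel,
    calibrations: CalibrationPrior,
    priors: ParameterPriors | None = None,
) -> float:
    """Sum of coalescent, GMRF (grid mode), calibration, tip and parameter
    prior log-densities.  States outside any support return -inf rather than
    raising, so the sampler can reject them."""
    priors = priors or ParameterPriors()
    ages = tree.tip_ages()

    # tip priors: uniform contributes 0 inside bounds, -inf outside
    for sid, spec in calibrations.tip_priors.items():
        if sid not in ages:
            continue
        if spec[0] == "uniform":
            lo, hi = spec[1], spec[2]
            if not (lo <= ages[sid] <= hi):
                return -np.inf
        elif spec[0] == "fixed":
            if abs(ages[sid] - spec[1]) > 1e-6:
                return -np.inf

    # ingroup monophyly under an outgroup-rooted calibration
    if calibrations.outgroup_labels:
        out = set(calibrations.outgroup_labels)
        if tree.n_tips - len(out) >= 2:
            is_out = np.array([1 if lab in out else 0 for lab in tree.labels],
                              dtype=np.int8)
            if _HAVE_NUMBA:
                ok = _mono_kernel(tree.postorder(), tree.left, tree.right,
                                  tree.n_tips, is_out)
            else:
                want = int(np.sum((is_out == 0) * (1 << np.arange(tree.n_tips, dtype=object))))
                ok = want in set(tree.clade_bitmask().values())
            if not ok:
                return -np.inf

    logp = coalescent_log_density(tree, demog)
    if demog.mode == "grid":
        logp += gmrf_log_prior(demog, priors)

    if calibrations.root_median is not None:
        root_age = float(tree.age[tree.root])
        if root_age <= 0:
            return -np.inf
        # log-normal log-density, written out for speed in the MCMC hot path
        s = calibrations.root_sigma
        z = np.log(root_age / calibrations.root_median)
        logp += -np.log(root_age * s) - 0.5 * np.log(2 * np.pi) - z * z / (2 * s * s)

    lo, hi = priors.clock_bounds
    if not (lo <= clock.rate <= hi):
        return -np.inf
    logp += -np.log(clock.rate)  # scale-uniform within bounds

    if demog.mode == "constant":
        nlo, nhi = priors.ne_bounds
        if not (nlo <= demog.Ne <= nhi):
            return -np.inf
        logp += -np.log(demog.Ne)

    for p in params_list:
        z = (np.log(p.kappa) - priors.kappa_log_mu) / priors.kappa_log_sigma
        logp += (-np.log(priors.kappa_log_sigma) - 0.5 * np.log(2 * np.pi)
                 - 0.5 * z * z - np.log(p.kappa))
        if p.gamma_shape is not None:
            logp += -np.log(priors.alpha_exp_mean) - p.gamma_shape / priors.alpha_exp_mean
        # p_inv: uniform on [0,1) contributes 0
    return float(logp)


def log_posterior(
    tree: TimeTree,
    partitions: dict[str, list[tuple[str, str]]],
    params_by_partition: dict[str, SubstitutionParams],
    clock: ClockModel,
    demog: DemographicModel,
    calibrations: CalibrationPrior,
    priors: ParameterPriors | None = None,
) -> float:
    """log prior + sum of per-partition pruning log-likelihoods."""
    lp = log_prior(tree, list(params_by_partition.values()), clock, demog,
                   calibrations, priors)
    if not np.isfinite(lp):
        return -np.inf
    ll = 0.0
    for name, records in partitions.items():
        ll += partition_log_likelihood(tree, records, params_by_partition[name], clock)
    return float(lp + ll)
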