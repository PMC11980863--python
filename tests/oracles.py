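"""Independent oracles used by the test suite.

Each function recomputes a quantity by a route deliberately different from
the implementation: brute-force enumeration for the pruning likelihood,
matrix exponentials for the HKY kernel, piecewise numeric integration for
the coalescent density, and naive scans for alignment bookkeeping.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import integrate
from scipy.linalg import expm

from tipdating.clock_model import site_rate_mixture
from tipdating.trees import TimeTree

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def hky_rate_matrix(kappa: float, freqs: np.ndarray) -> np.ndarray:
    """Mean-rate-1 HKY generator built longhand."""
    pi = np.asarray(freqs, dtype=float)
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            transition = (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1))
            Q[i, j] = (kappa if transition else 1.0) * pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q / -np.dot(pi, np.diag(Q))


def hky_expm(kappa, freqs, distance):
    return expm(hky_rate_matrix(kappa, freqs) * distance)


def brute_force_log_likelihood(tree: TimeTree, records, params, clock) -> float:
    """Sum over all internal-node state assignments, one site at a time."""
    by_id = dict(records)
    L = len(records[0][1])
    cats = site_rate_mixture(params.gamma_shape, params.n_categories, params.p_inv)
    internals = [n for n in range(tree.n_nodes) if not tree.is_tip(n)]
    total = 0.0
    for site in range(L):
        site_lik = 0.0
        for rate, weight in cats:
            s = 0.0
            P = {}
            for node in range(tree.n_nodes):
                if node == tree.root:
                    continue
                par = int(tree.parent[node])
                d = clock.rate * params.relative_rate * rate * (tree.age[par] - tree.age[node])
                P[node] = hky_expm(params.kappa, params.freqs, d)
            for assign in itertools.product(range(4), repeat=len(internals)):
                amap = dict(zip(internals, assign))
                pr = params.freqs[amap[tree.root]]
                for node in range(tree.n_nodes):
                    if node == tree.root:
                        continue
                    par = amap[int(tree.parent[node])]
                    if tree.is_tip(node):
                        ch = by_id[tree.labels[node]][site]
                        if ch in BASE_INDEX:
                            pr *= P[node][par, BASE_INDEX[ch]]
                        # N or '-': fully ambiguous, row sums to 1
                    else:
                        pr *= P[node][par, amap[node]]
                s += pr
            site_lik += weight * s
        total += np.log(site_lik)
    return float(total)


def coalescent_numeric_log_density(tree: TimeTree, demog) -> float:
    """Heterochronous coalescent density via an adaptive numeric integrator."""
    n = tree.n_tips
    events = sorted(
        [(float(tree.age[i]), "s") for i in range(n)]
        + [(float(tree.age[i]), "c") for i in range(n, tree.n_nodes)]
    )
    logp, k = 0.0, 0
    t_prev = events[0][0]
    for t, kind in events:
        if t > t_prev and k >= 2:
            breaks = None
            if demog.mode == "grid":
                inside = demog.boundaries[(demog.boundaries > t_prev)
                                          & (demog.boundaries < t)]
                breaks = list(inside) if len(inside) else None
            integral, _ = integrate.quad(lambda u: 1.0 / demog.size_at(u), t_prev, t,
                                         points=breaks, limit=200)
            logp -= 0.5 * k * (k - 1) * integral
        t_prev = max(t_prev, t)
        if kind == "s":
            k += 1
        else:
            logp -= np.log(demog.size_at(t))
            k -= 1
    return float(logp)


def gamma_category_rates_numeric(alpha: float, n: int) -> np.ndarray:
    """Within-bin mean rates of the discrete Gamma by numeric integration."""
    from scipy import stats as st

    edges = st.gamma.ppf(np.linspace(0, 1, n + 1), a=alpha, scale=1.0 / alpha)
    rates = []
    for a, b in zip(edges[:-1], edges[1:]):
        hi = np.inf if not np.isfinite(b) else b
        num, _ = integrate.quad(lambda x: x * st.gamma.pdf(x, a=alpha, scale=1.0 / alpha),
                                a, hi, limit=200)
        rates.append(num * n)
    return np.array(rates)


def random_time_tree(rng: np.random.Generator, n_tips: int,
                     max_tip_age: float = 1.0) -> TimeTree:
    """Random dated tree by sequential pair-joining (not a coalescent draw)."""
    ages = rng.uniform(0, max_tip_age, size=n_tips)
    labels = [f"t{i}" for i in range(n_tips)]
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    age = np.zeros(n_nodes)
    age[:n_tips] = ages
    active = list(range(n_tips))
    nxt = n_tips
    t = float(ages.max())
    while len(active) > 1:
        t += rng.exponential(0.5 * max_tip_age + 0.1)
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        age[nxt] = t
        left[nxt], right[nxt] = a, b
        parent[a] = parent[b] = nxt
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    tree = TimeTree(labels=labels, parent=parent, left=left, right=right,
                    age=age, root=n_nodes - 1)
    tree.validate()
    return tree


def random_sequences(rng: np.random.Generator, labels, length,
                     alphabet="ACGTN-") -> list[tuple[str, str]]:
    probs = np.array([0.22, 0.22, 0.22, 0.22, 0.06, 0.06])[: len(alphabet)]
    probs = probs / probs.sum()
    return [(lab, "".join(rng.choice(list(alphabet), size=length, p=probs)))
            for lab in labels]
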