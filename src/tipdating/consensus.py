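"""Consensus calling from reference-indexed pileups.

Ancient-DNA assemblies are summarized per reference position as base counts
(A, C, G, T and deletion).  A position is emitted as the majority symbol only
if it clears a minimum depth and a minimum agreement fraction; otherwise it
is masked as ``N``.  The default policy masks positions with less than 3x
coverage or agreement below 67%; a strict policy (for damage-prone
libraries) requires 10x and 90%.

Agreement is compared as an exact rational (majority count / depth) against
the policy fraction, so the 2/3-vs-0.67 edge case is decided exactly:
2 of 3 reads agreeing is 66.67% and fails the 67% default.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction

import numpy as np

__all__ = ["ConsensusPolicy", "DEFAULT_POLICY", "STRICT_POLICY", "call_consensus", "coverage_stats"]

_SYMBOLS = np.array(list("ACGT-"))


@dataclass(frozen=True)
class ConsensusPolicy:
    """Depth/agreement thresholds; positions meeting both emit a base.

    ``min_agreement`` may be given as a string ("0.67"), Decimal or float and
    is stored as an exact Fraction.  A value of exactly the threshold passes;
    "less than" fails.
    """

    min_depth: int
    min_agreement: Fraction

    def __post_init__(self):
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        agr = self.min_agreement
        if not isinstance(agr, Fraction):
            agr = Fraction(Decimal(str(agr)))
            object.__setattr__(self, "min_agreement", agr)
        if not (Fraction(1, 2) < self.min_agreement <= 1):
            raise ValueError("min_agreement must lie in (0.5, 1]")


DEFAULT_POLICY = ConsensusPolicy(3, Fraction(67, 100))
STRICT_POLICY = ConsensusPolicy(10, Fraction(90, 100))


def call_consensus(pileup: np.ndarray, policy: ConsensusPolicy = DEFAULT_POLICY) -> str:
    """Call one consensus symbol per pileup position.

    ``pileup`` is an (L, 5) array of counts over (A, C, G, T, deletion).
    Positions failing the depth or agreement rule become ``N``.  Because any
    policy requires agreement > 1/2, a tied majority can never pass, so
    tie-breaking is moot.
    """
    pileup = np.asarray(pileup)
    if pileup.ndim != 2 or pileup.shape[1] != 5:
        raise ValueError("pileup must have shape (L, 5)")
    if (pileup < 0).any():
        raise ValueError("negative pileup count")
    out = []
    for counts in pileup:
        depth = int(counts.sum())
        if depth < policy.min_depth:
            out.append("N")
            continue
        m = int(counts.max())
        if Fraction(m, depth) < policy.min_agreement:
            out.append("N")
            continue
        out.append(str(_SYMBOLS[int(counts.argmax())]))
    return "".join(out)


def coverage_stats(pileup: np.ndarray, consensus: str) -> tuple[float, float]:
    """(mean depth, breadth) of a consensus.

    Mean depth averages over *all* positions, zero-depth included; breadth is
    the fraction of non-N consensus positions.
    """
    pileup = np.asarray(pileup)
    if len(pileup) != len(consensus):
        raise ValueError("pileup and consensus lengths differ")
    if len(consensus) == 0:
        return 0.0, 0.0
    mean_depth = float(pileup.sum(axis=1).mean())
    breadth = sum(c != "N" for c in consensus) / len(consensus)
    return mean_depth, breadth
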