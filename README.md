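# tipdating

Bayesian molecular-clock **tip dating** of heterochronous mitogenomes — a
desk-scale, fully tested re-implementation of the analysis pipeline used to
estimate the ages of ancient specimens (e.g. Pleistocene mammoths) that lie
beyond the ~50 ka radiocarbon limit, directly from their mitochondrial
genome sequences.

## Who this is for

Palaeogenomicists and molecular evolution researchers who want a
transparent, scriptable alternative to a BEAST-centred workflow for:

* calling consensus mitogenomes from reference-indexed pileups under
  depth/agreement thresholds (default: mask positions with <3× coverage or
  <67% agreement; a strict 10×/90% policy for damage-prone libraries),
* post-processing a multiple sequence alignment (removing single-sequence
  insertion columns, masking the hypervariable VNTR of the control region,
  and partitioning columns into tRNA / rRNA / codon positions 1–3 /
  control region),
* estimating unknown tip ages by Metropolis–Hastings MCMC under a
  partitioned HKY+Γ+I substitution model, a strict molecular clock, a
  heterochronous coalescent tree prior and a log-normal root calibration,
* and validating the whole procedure on synthetic data with known truth.

## The model

For an alignment partitioned into ``p = 1..P`` blocks with column counts
``w_p``, the posterior over the dated genealogy ``G`` (topology and node
ages, tips possibly at unknown ages **t**), clock rate ``r`` and
substitution parameters ``θ_p = (κ_p, α_p, p_inv,p, ρ_p)`` is

```
P(G, t, r, θ, Ne | D) ∝ Π_p L_p(D_p | G, r·ρ_p, θ_p) · C(G | t, Ne) · π(t) · π(root) · π(r, θ, Ne)
```

* ``L_p`` — Felsenstein-pruning likelihood under HKY85 with discrete-Γ (4
  equal-weight quantile categories, within-bin means) plus an invariant
  class, mixture renormalised to mean rate 1; branch distance =
  ``r · ρ_p · category rate · duration`` (substitutions/site, durations in
  years). `N` and `-` are fully ambiguous.
* ``C`` — serially sampled coalescent density with constant or
  piecewise-constant ("skygrid-style") effective size ``Ne(t)``, the grid
  smoothed by a Gaussian random walk on log ``Ne`` with a Gamma hyperprior
  on its precision.
* ``π(t)`` — fixed ages for calibrated tips (delta), Uniform(1 ka, 2 Ma)
  for undated tips.
* ``π(root)`` — log-normal calibration of the ingroup/outgroup divergence
  (default median 5.3 Ma), with ingroup monophyly enforced.

Undated samples are dated **one at a time** against the calibrated
reference set (single-sample dating); the package also implements joint
(multi-sample) dating and an experiment quantifying the systematic
older-age bias that joint dating introduces — reproducing, on synthetic
data, the direction reported for real deep-time datasets.

## Worked example

```python
import numpy as np
from tipdating import (StudyConfig, make_study_dataset, MCMCConfig,
                       single_sample_date)
from tipdating.io_formats import AnnotationRow, AnnotationTable

ann = AnnotationTable([AnnotationRow("control_region", 1, 2000),
                       AnnotationRow("VNTR", 900, 1000)])
cfg = StudyConfig(n_calibrated=20, n_undated=1, n_outgroup=2,
                  seq_length=2000, annotation=ann)
aln, table, tree, truth = make_study_dataset(cfg, seed=42)

est = single_sample_date(aln, table, "und000",
                         MCMCConfig(n_iterations=30_000, thin=20),
                         seeds=(7, 8))
print(f"true age {truth.tip_ages['und000']:.0f}")
print(f"estimate {est.mean:.0f} [{est.hpd_lo:.0f}, {est.hpd_hi:.0f}]")
```

Output from this exact script:

```
true age 1009705
estimate 849849 [105079, 1701582]
```

The undated tip was simulated at 1.010 Ma; the chain-pair averaged
posterior mean is 0.85 Ma with a 95% HPD of 0.11–1.70 Ma that covers the
truth. Intervals are wide because a 2 kb alignment carries limited clock
information for a single deep tip — exactly the regime in which HPDs, not
point estimates, should be reported.

The same analyses are available from the shell via the `dtd` command
(`dtd simulate`, `dtd consensus`, `dtd msa-filter`, `dtd mask`,
`dtd partition`, `dtd date-single`, `dtd date-multi`, `dtd bias-exam`,
`dtd validate`, `dtd joint-tree`, `dtd diag`); every stochastic subcommand
requires an explicit `--seed`.

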