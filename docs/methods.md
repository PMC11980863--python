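# Methods

This note documents the models, algorithms, numerical choices and
limitations of the package, in the order data flows through the pipeline.

## Consensus calling

A pileup is an L×5 table of counts over (A, C, G, T, deletion) per
reference position. A position is emitted as the majority symbol only if
depth ≥ `min_depth` and majority/depth ≥ `min_agreement`; otherwise `N`.
Two stock policies: the default (3×, 67%) and a strict one (10×, 90%) for
libraries with residual deamination damage. The agreement comparison is
done on exact rationals, so 2 agreeing reads out of 3 (66.67%) fails the
67% rule while exactly 67/100 passes — the float 0.67 would get this edge
case wrong. The agreement denominator includes deletion counts, and a
deletion may itself be the consensus symbol; because any admissible
threshold exceeds 1/2, majority ties can never pass, so no tie-break rule
is needed. Insertions relative to the reference are out of scope (the
pileup is reference-indexed).

## Alignment post-processing

Operating on a gapped multiple sequence alignment with a designated
reference row, in pipeline order:

1. **Singleton-column removal** — a column is dropped iff exactly one
   sequence has a determinate base (A/C/G/T) and *all* others have `-`;
   all-gap columns are dropped too. An `N` elsewhere keeps the column:
   the rule targets single-sequence insertion artifacts, and an `N` is
   evidence of sequence, not of alignment-induced gaps.
2. **Coordinate transfer** — reference interval [start, end] (1-based
   inclusive) maps to the columns holding the k-th non-gap reference
   characters. For masking, reference-gap columns strictly inside the
   mapped span are included (masking is protective); for feature
   assignment they are excluded.
3. **VNTR masking** — the control-region tandem-repeat interval (reference
   positions 16157–16476 on the full-length 16,770 bp layout, 320 columns
   when the reference is ungapped) is labelled `masked` and excluded from
   every likelihood computation. Idempotent.
4. **Partition assignment** — columns are labelled tRNA, rRNA, codon1/2/3
   (cycling by `(refpos − codon_phase_origin) mod 3` from each CDS's own
   anchor) or control_region. Columns outside all features stay
   `unassigned` and are excluded from likelihoods. Annotations are taken on
   the alignment orientation; reverse-strand phase comes from the feature's
   own origin field, never by reverse-complementing.

## Substitution model and likelihood

Each partition evolves under HKY85 with its rate matrix normalised to one
expected substitution per site per unit distance at stationarity.
Among-site rate variation is the discrete-Γ approximation (default 4
equal-weight quantile bins represented by their within-bin mean rates,
computed in closed form from regularised incomplete-gamma differences)
plus an optional invariant class; the whole mixture is renormalised to
mean 1 so that the clock rate keeps its units. The tRNA partition defaults
to HKY+I (no Γ), the others to HKY+Γ+I.

Branch distance = clock rate × partition relative rate × category rate ×
branch duration (years). The strict clock is shared across partitions;
relative rates carry a column-weighted mean-1 constraint and are sampled
with a delta-exchange move. Base frequencies are fixed at their empirical
(per-partition) values during MCMC — a deliberate dimension reduction at
desk scale.

Likelihoods use Felsenstein pruning over site patterns (`N`/`-` fully
ambiguous), with per-node rescaling against underflow. Transition matrices
come from the symmetric eigendecomposition of the reversible generator
(`B = D^{1/2} Q D^{-1/2}`), which enforces detailed balance to machine
precision. The inner loop is compiled with numba when available; a
pure-numpy path computes identical values (asserted in tests) and serves
as fallback.

## Tree priors and calibrations

The genealogy prior is the serially sampled coalescent: going back in
time, k active lineages coalesce with pair hazard `k(k−1)/(2 Ne(t))`;
each coalescence contributes `log(1/Ne(t))`. `Ne(t)` is either constant or
piecewise-constant on a grid ("skygrid" style) with exact piecewise
integration; the grid's log-sizes carry a first-order Gaussian random-walk
prior with precision τ and a Gamma(0.001, 0.001) hyperprior on τ.

Tip-age priors: calibrated tips are fixed; undated tips get
Uniform(1 ka, 2 Ma) — 0 inside, −∞ outside (a rejected state, not an
exception). The ingroup/outgroup divergence carries a log-normal
calibration with real-space median 5.3 Ma and log-sd 0.05 (both
configurable; the σ is a package default, since only the median is
conventionally reported), and ingroup monophyly is required whenever an
outgroup is declared. Remaining parameter priors are vague and
configurable: log κ ~ Normal(1, 1.25²), Γ shape ~ Exponential(mean 0.5),
p_inv ~ Uniform[0,1), clock rate and constant Ne scale-uniform (1/x)
within wide bounds.

## MCMC

Random-scan single-move Metropolis–Hastings. Moves: multiplicative scale
moves on clock rate, κ, Γ shape and Ne; a reflected window on p_inv;
delta exchange on relative rates; uniform-window and scale moves on
undated tip ages; a tip+stem translation that shifts an undated tip and
its parent jointly (this breaks the tip-below-parent squeeze and improved
tip-age mixing by more than an order of magnitude); per-node height slides
within parent/child bounds; root-height scaling; a clock-versus-heights
"up/down" scale and a whole-tree internal-height scale (the rate–height
ridge would otherwise dominate the autocorrelation time); narrow exchange;
and a prune-and-reattach move for undated tips that may also reattach
above the root, using an exponential height density whose scale is the
current Ne (unchanged by the move, so the proposal densities are evaluated
symmetrically). Proposal scales are tuned toward ~23% acceptance during
burn-in only; all acceptance rates are logged.

Initialization: undated tips at their prior midpoints; the starting tree
is a serial-coalescent simulation at the initial Ne, with the outgroup
joined at the calibration median — always a valid state, and random
across chains so a chain pair starts over-dispersed. (A distance-based
seed tree was considered and rejected: the coalescent draw is simpler,
always respects heterochronous tip ages, and randomizes starts.)

Desk-scale defaults are 2 chains × 20k iterations, thinning 10, 10%
burn-in — a scaled-down analogue of the conventional 2 × 100M / 10k / 10%
production setting. Convergence of a chain pair requires ESS > 200 in both
chains (initial-positive-sequence estimator) and split-chain R̂ < 1.05
(chosen as a reproducible substitute for visual trace inspection);
tip-age posteriors are additionally checked for unimodality by counting
KDE modes (Silverman bandwidth, modes under 10% of the maximum ignored).
Chain-pair point estimates average the two means, and the reported HPD
endpoints average the two chains' endpoints — statistically, pooling the
traces would be preferable, but endpoint averaging is the convention this
pipeline reproduces; a pooled alternative is a one-line change via
`summarize_parameter` on concatenated traces.

## Synthetic data generator

The generator defines the study conditions for every recovery experiment:

* ~16.8 kb mitogenome-like alignment, six partitions (or a proportionally
  scaled compact layout for short alignments), VNTR inside the control
  region;
* calibrated tips uniform on 0–50 ka (the radiocarbon window), undated
  tips uniform on 100 ka–1.3 Ma (deep time), a two-tip modern outgroup
  splitting at a log-normal(5.3 Ma, 0.05) draw;
* constant ingroup Ne of 5×10⁵ years (pairwise-coalescence scale — no
  generation-time conversion, deliberately, since mitogenome data
  constrain only the product), strict clock 3×10⁻⁸ subs/site/year,
  mitochondria-flavoured parameters (κ = 20, unequal frequencies, strong
  rate heterogeneity, fast codon3/control region);
* negative-binomial pileup depths with a uniform read error rate.

What it does **not** emulate: post-mortem damage patterns, fragment-length
structure, indel evolution (alignments are simulated gap-free; gaps enter
only through masking operations), reference bias, and real misalignment.
Passing recovery tests therefore demonstrate the correctness and
calibration of the inference machinery under the assumed model — not
robustness to the model violations real ancient-DNA data add.

## Validation experiments and problem sizes

* **Prior sampling** — likelihood disabled; the undated tip-age marginal
  must match Uniform(1 ka, 2 Ma) (mean within 3 Monte-Carlo SEs of
  1.0005 Ma, KS at α = 0.01 after thinning). Because the coalescent is a
  normalised density over genealogies *given* tip dates, the marginal is
  exactly uniform; the validation config disables the root calibration and
  fixes Ne at 2×10⁶ years — sampling Ne too leaves the marginal uniform in
  theory but creates a Ne–heights funnel that mixes orders of magnitude
  more slowly, which is a mixing-efficiency choice, not a change of
  target. This run doubles as a detailed-balance test of every topology
  and Hastings computation.
* **Recovery** — 20 replicates of (20 calibrated + 1 undated + 2 outgroup
  tips, 2 kb unpartitioned), chain pairs of 15k iterations: the true tip
  age and the true clock rate must fall in their 95% HPDs in ≥ 17/20
  replicates.
* **Bias experiment** — 10 replicates of (12 calibrated + 5 undated + 2
  outgroup, 1.5 kb): the five oldest undated tips (by simulated truth)
  dated jointly and individually; the paired (multi − single) difference
  is summarised by a one-sided sign test. The expected reproduction is the
  *direction* (multi-sample older); the magnitude is dataset-dependent.
* **Held-out validation** — calibrated tips re-dated as if undated; known
  ages outside the uniform prior bounds are flagged impossible and
  excluded with a warning.

Problem sizes (alignment lengths, tip counts, chain lengths) were chosen
so the full suite runs on a single CPU in minutes while keeping the
statistical checks meaningful; they are recorded in the tests and in
`scripts/acceptance.py`.

## Numerical notes and edge cases

* Agreement thresholds: exact rational comparison (Fraction), never float.
* Γ bin means: closed form `n·(P(α+1, α·b_{k+1}) − P(α+1, α·b_k))`; at
  extreme α (≥ ~10⁸) the outer-bin means still deviate from 1 by ~1.27
  standard deviations of the underlying Γ — that is a property of the
  quantile-bin-mean discretisation, not numerical error.
* Pruning rescales partials per pattern at every internal node; a
  zero-probability pattern returns −∞ rather than raising.
* HPD: shortest window of ⌈0.95·N⌉ order statistics, ties to the lowest
  lower bound; degenerate samples give a zero-width interval.
* ESS: Geyer initial-positive-sequence truncation of FFT autocovariances;
  a constant series is an error (zero variance), not an ESS of N.
* Trees serialise as plain Newick with branch lengths in years plus a
  sidecar TSV of node annotations keyed by clade; node ages are
  reconstructed from tip ages + branch lengths and cross-checked for
  path consistency.

## Known limitations

* Relaxed clocks, GTR/codon models and ascertainment corrections are out
  of scope by design.
* The sampler is a general-purpose MH implementation: it is validated
  against oracles and on synthetic truth, but no equivalence with any
  specific production tool's output is claimed.
* Skygrid mode is fully supported in the densities and the generator;
  the sampler's default demographic mode is constant-Ne, which is what
  the desk-scale validation experiments exercise.
* Multi-sample mode shares all nuisance parameters across focal tips in
  one joint analysis; per-tip nuisance unlinking is not implemented.
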