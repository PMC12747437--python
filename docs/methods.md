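# Methods

## The problem

Chromatin tracing localizes many identifiable genomic loci in each of many
fixed cells, producing *traces*: per-cell sets of 3D positions, one per
locus, with missing entries where a probe failed to hybridize or a spot
was not detected. Localization errors of 25–100 nm are typical and sit
uncomfortably close to the 100–200 nm distances that matter for
enhancer–promoter biology, inflating pairwise distances and flattening
contact-frequency maps — multi-way contacts most of all.

This package implements a post-processing correction that needs no extra
experiments. It exploits the defining feature of multi-loci data: the loci
are *distinguishable*, so every locus has many partners against which its
error leaves a measurable statistical fingerprint.

## Model

For one imaging dimension, locus α and trace i:

    O_i^α = T_i^α + ε_i^α

with observed position `O`, true position `T`, and independent zero-mean
localization error `ε` whose per-locus, per-dimension STD is the quantity
to be estimated or supplied. Independence of errors across loci and traces
gives the variance decomposition

    Var(O^α − O^β) = Var(T^α − O^β) + Var(ε^α)

over the traces where both loci are localized. Given `Var(ε^α)`, the
**goal variance** `μ_{α,β} ≈ Var(T^α − O^β)` is the empirical displacement
variance minus the error variance. An adjusted column `A^α = O^α + C^α` is
scored by the likelihood

    log l[A^α] = Σ_β log N( Var(A^α − O^β) | μ_{α,β}, σ_{α,β} )

where `σ_{α,β}` is the sampling SE of the variance. All partner positions
stay at their observed values within a round, so each locus (and each
dimension) is an independent optimization problem; runs share no state and
parallelize trivially.

Assumptions worth stating: errors are independent between loci (violated
if neighboring probes share imaging rounds), zero-mean (drift must be
removed upstream), and approximately Gaussian only insofar as the CLT on
the *variance* is invoked — the truth differences themselves need not be
Gaussian, which is why `σ_{α,β}` uses the distribution-free moment
estimator `sqrt((m₄ − m₂²)/n)` rather than the normal-theory `s²√(2/(n−1))`.

## Error estimation

**From repeat imaging.** When a locus is imaged twice in the same cells
(initial copy `a`, repeat copy `r`), the shared truth cancels in the
displacement, and comparison with third loci β separates the two rounds:

    Var(O^a − O^r)                              = Var(ε^a) + Var(ε^r)
    mean_β[ Var(O^a − O^β) − Var(O^r − O^β) ]   = Var(ε^a) − Var(ε^r)

This moment system is solved per pair and dimension; it is the unique
solution using only displacement variances. Negative solutions (possible
at small n) are clamped to zero with a warning. Repeat rounds typically
show *larger* error than initial rounds, so the two are reported
separately and repeat-imaged loci are excluded from correction input by
default (they also carry more off-target spots).

**Worst-case bound.** Without repeats, `Var(O^α − O^β) ≥ Var(ε^α) +
Var(ε^β)` for every pair, so half the smallest displacement variance over
genomically adjacent pairs bounds a homogeneous error variance from above.
The bound is tight only when adjacent loci nearly coincide; on a spread-out
chain it overestimates, which under-corrects goal variances — the
conservative direction.

## Filtering

Off-target localizations are screened by the minimum Euclidean distance to
a localized genomic neighbor (previous/next locus, skipping missing loci
up to a gap of two positions; beyond that the metric is undefined and the
spot is never removed — a distant "neighbor" no longer constrains
plausibility). The default cutoff is the 0.995 quantile of the pooled
metric, since no absolute threshold generalizes across genomic
resolutions; absolute nm cutoffs are supported. A guard refuses thresholds
that would drop more than 20% of localizations unless forced. Filtering at
a fixed absolute threshold is idempotent on data whose surviving neighbor
graph stays below threshold; pathological configurations where removing a
spot lengthens a survivor's neighbor distance past the cutoff can in
principle require a second pass.

Detection-efficiency filtering keeps traces with at least the requested
fraction of loci localized (boundary inclusive; multi-way analyses use
0.95).

## Optimization

The likelihood of one locus column is maximized by greedy stochastic
descent. Per sweep, localized traces are visited in seeded random order;
each visit proposes `C_i += δ`, `δ ~ Normal(0, s)`, and accepts only
strict improvements (ties keep the incumbent), so the likelihood trace is
non-decreasing by construction. A proposal is scored in O(#partners) by
updating the running sums of each pairwise difference
(`S1' = S1 + δ`, `S2' = S2 + 2dδ + δ²`); because the normalization
constants do not depend on the candidate, the acceptance test compares
only the quadratic terms. The hot loop is JIT-compiled with numba.

Numerical choices:

- proposal scale starts at `0.5·σ_α` (floored at 1 nm for zero-error
  loci), anneals ×0.95 per sweep, and is floored at `1e-4` of its start so
  late sweeps retain enough resolution to polish;
- convergence is declared after 5 consecutive sweeps whose accepted
  likelihood gain per visit falls below `tol` (default 1e-6), and only
  once the scale has reached its floor — at large scales rejection-only
  sweeps occur far from the optimum because proposals overshoot the
  acceptance window;
- sweep cap 200 (warning if reached unconverged; best-so-far returned);
- goal means are floored at 1 nm² when the error estimate exceeds the
  empirical variance (possible with overestimated σ; warned);
  uncertainties are floored at 0.1 nm²;
- variances use ddof=1 throughout, pairwise-complete over traces with both
  loci localized; missing localizations are never proposed (no
  imputation);
- pairs need ≥ 50 co-localized traces (`min_n`) to be usable; loci with
  no usable partner pass through unadjusted;
- the likelihood is translation-invariant, so the per-locus mean of `C`
  (over localized traces) is subtracted — zero-mean corrections preserve
  ensemble centroids;
- each (locus, dimension, round) draws its RNG from
  `SeedSequence([seed, round, dim, locus])`, making serial and parallel
  execution bit-identical.

Multi-round refinement (recomputing goal variances against previously
adjusted partners) is implemented but off by default: re-subtracting the
full `σ_α²` from already-corrected variances overstates the remaining
error and drives goals toward the floor, so it over-shrinks; it is kept as
an experimental option only.

## Synthetic data

The generators produce the validation conditions: independent Gaussian
chains (locus 1 at the origin, per-axis Normal(0, step) increments, so
loci k apart have per-axis displacement variance k·step²), optional
rescaling of each trace to the ensemble radius of gyration
(`confined_chain`), i.i.d. dropout, per-axis Gaussian localization noise
with the injected values retained for oracle comparisons, repeat-imaging
rounds with distinct initial/repeat noise, and linear interpolation that
emulates finer genomic resolution (factor f maps L loci to f·(L−1)+1,
relabelling the genomic axis).

Defaults are the benchmark conditions used throughout: per-axis neighbor
displacement STD 30 nm (the compaction scale of kilobase-resolution
tracing, where inter-locus distances are small and the method is most
effective), L = 100 loci, N = 500 traces, noise σ ∈ {25, 50} nm, with
{50, 100} nm used for the coarser-data scenarios.

What the generator does *not* emulate: correlated dropout, off-target
contamination with realistic spatial structure (planted off-targets are
simple large displacements), loop-extrusion loops and TAD structure, and
chromatic aberration between imaging rounds. Passing tests therefore
demonstrate the estimator and optimizer machinery under the stated noise
model, not robustness to every artifact of real microscopes.

## Contact analysis

Contact frequency is the fraction of traces (both/all loci localized)
with all pairwise distances ≤ a threshold; 150 nm and 200 nm are the
conventional settings. Pairs with fewer than 50 co-localized traces are
masked (`min_n`, configurable); k-way tuples (k ∈ {3, 4}) additionally
require ≥ 1000 co-localized traces for *every* pair of the tuple. The
independence baseline for a k-tuple is the product of its C(k,2) pairwise
frequencies — a k-way contact is the conjunction of the pairwise contact
events — and excess of observed over expected measures cooperativity.
Note that the observed k-way frequency is bounded by each of the tuple's
pairwise frequencies whenever the denominators coincide (complete
detection); under dropout the denominators differ per pair and the bound
is only approximate.

Two relative-error metrics are exposed, matching the two conventions in
use: per locus, the ratio of mean Euclidean error after vs before
correction; per trace, the mean over loci of the per-localization ratio
`‖A−T‖/‖O−T‖` (terms with pre-correction error < 1e-6 nm are skipped).
The per-trace formula could also be read with signed 1-D ratios; the
Euclidean-norm reading is used here as the scale-free choice that cannot
cancel sign-wise.

## Benchmark problem sizes

The standard end-to-end benchmark uses L = 100, N = 500, 3 dimensions,
two noise levels, ~185 descent sweeps per locus-dimension; it completes in
about a minute of CPU. Variance-decomposition and repeat-recovery checks
use N = 2000 traces where 4 combined standard errors (or 5% relative
error) is the verification tolerance. These sizes give Monte-Carlo
uncertainties comfortably inside the asserted tolerances while staying
desk-scale.

## Known limitations

- The correction matches second moments; it does not use photon counts or
  per-spot quality weights, and it cannot fix systematic (shared-sign)
  shifts, which are invisible to displacement variances.
- Accuracy of the goal variances is limited by the supplied error model;
  an overestimated σ over-shrinks (goal floors engage), an underestimated
  σ under-corrects.
- Effectiveness scales with `Var(ε)/Var(O^α − O^β)`: coarse-resolution
  data (large inter-locus distances) sees small improvements.
- The worst-case error bound is loose on spread-out chains.
- Idempotency of off-target filtering is guaranteed only for the
  single-pass semantics described above.
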