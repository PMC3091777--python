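# Methods

This note documents the statistical models implemented in `ibmtpath`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions that affect results.

## Study model and contrasts

The unit of input is a log2-scale probes × samples matrix with a per-sample
design record (subject, sex ∈ {M, F}, arm ∈ {exercised, control}, time ∈
{baseline, 4h, 24h}).  Input is assumed pre-summarized on the log2 scale;
`log2_transform` applies log2(x+1) for raw-scale matrices, and
`quantile_normalization` optionally forces all columns onto the common
distribution of across-column mean order statistics.  Missing values are
rejected rather than imputed: the target platform yields complete matrices,
and sample failures are expressed by omitting samples from the design table,
never by masking cells.

A *comparison* is a named two-group contrast defined by predicates on design
columns.  Paired mode computes within-subject differences (case − reference),
so b_g = mean difference, s²_g = variance of differences, d_g = n−1,
u_g = 1/√n; subject-level effects cancel exactly.  Unpaired mode uses the
pooled two-sample variance with d_g = n₁+n₂−2 and u_g = √(1/n₁+1/n₂).  The
default template contains five comparisons: the resting-state male-vs-female
contrast and exercised-vs-control per sex × time.  Whether the resting-state
contrast should use control arms at one biopsy time or pooled across times
is not dictated by the data model; the default pools all control arms (the
selector is explicit in configuration, so either choice is one line).

Quantile normalization uses the average-rank convention for ties: a tie
spanning ranks i..j receives the mean of the target order statistics over
that span.  This makes the map deterministic and, on tie-free (continuous)
input, exactly idempotent with exactly equal column multisets.  With ties
the tied column's multiset deviates from the common target by construction,
and exact idempotence can no longer hold — a property of any deterministic
tie convention, accepted and tested accordingly on continuous data.

## Intensity-based moderated t

Gene-wise variances from 3–4 pairs are unstable; the empirical-Bayes model
places sigma²_g ~ d₀·s₀²(a_g)/chi²(d₀) and tests with the posterior-mean
variance s̃²_g = (d₀·s₀²(a_g) + d_g·s²_g)/(d₀+d_g) on d₀+d_g df.  The
intensity dependence enters through the prior scale s₀²(a): low-intensity
probes are systematically noisier, and ignoring that either over- or
under-shrinks at the intensity extremes.

Estimation is by method of moments on e_g = ln s²_g − ψ(d_g/2) + ln(d_g/2),
which is an unbiased estimate of ln sigma²_g (this bias correction is why
the trend is fitted on e_g rather than raw ln s²_g):

* trend: lowess of e_g on a_g, span 0.75 by default (configurable); the
  `delta` interpolation parameter is set to 1% of the intensity range so the
  fit stays near-linear-time on 50k probes;
* prior df: residuals r_g = e_g − ê(a_g) satisfy
  E[r²]·m/(m−1) − mean ψ′(d_g/2) = ψ′(d₀/2).  ψ′ is strictly decreasing, so
  the root is unique; it is found by Brent's method on d₀ ∈ [0.01, 10⁶] with
  tolerance 1e−8.  A non-positive right-hand side (observed spread no larger
  than chi-square sampling noise) or a root beyond 10⁶ is reported as
  d₀ = +∞ (full pooling, normal reference distribution);
* prior scale: s₀²(a_g) = exp(ê(a_g) + ψ(d₀/2) − ln(d₀/2)), the inverse of
  the same moment identity (s₀² = exp(ê) when d₀ = ∞).

Probes with s²_g = 0 (constant differences) are excluded from trend and d₀
fitting, where their −∞ log variance would be fatal, but still receive
moderated statistics through the interpolated prior — they are tested, not
dropped.  d_g is constant within a comparison here, but all formulas retain
per-gene d_g.  p-values are two-sided; direction is carried separately as
sign(b_g) for the enrichment stage.  BH-FDR is computed over all probes
tested in the comparison (the family size is recorded in the manifest).
Forcing d₀ = 0 reproduces the classical paired/pooled t exactly and is used
as a built-in cross-check.

Neither the local-regression span nor the d₀ search interval is canonical;
both are exposed in configuration, and no low-expression filter is applied
by default (filtering interacts with the intensity trend and is left to the
caller).

## Directional enrichment by logistic regression

For gene g with two-sided p-value p_g and direction sign(b_g), the score is
x_g = sign(b_g)·(−ln p_g), clamped at p ≥ 1e−300 before the log.  Natural
logs are used throughout (the base only rescales β₁ and leaves the Wald test
invariant; odds ratios are therefore per ln-p unit).  For each set S the
model logit P(y_g=1) = β₀ + β₁ x_g is fitted over the entire measured
universe by IRLS: at most 50 iterations, deviance tolerance 1e−8, fitted
probabilities clipped at 1e−10.  |β₁| > 20 is treated as separation; that,
non-convergence, or constant membership (a set equal to, or absent from, the
universe) flags the set "unstable" with no p-value.  The two-sided Wald
p-value uses the normal reference; direction is reported from sign(β₁)
rather than via one-sided testing.  A score vector with zero range is an
error — no fit is identifiable.

Defaults: set-size window [10, 500] measured members (stabilizes the fit,
standard enrichment practice); enrichment at gene level with each gene
represented by its highest-mean-intensity probe (probe-level mode is
available for sensitivity analysis); the FDR family is all sets tested in a
run (ontology and pathway collections jointly when supplied together), per
comparison.  The nondirectional variant uses |x_g| = −ln p_g.

The signed matrix for cross-condition clustering has entries
sign(direction)·(−log10 p_S) with zeros for untested or unstable
term–comparison pairs; the pipeline writes rows for terms enriched in at
least one comparison.

## Ontology redundancy collapse

Annotations propagate from child (specific) to parent (general) terms, so
enriched lists contain near-duplicate ancestors.  "Similar group of genes"
is operationalized as Jaccard ≥ 0.7 on measured-universe memberships
(configurable; no canonical value exists, so the threshold is an explicit,
logged free parameter).  Per pass, parents are visited bottom-up (children
before parents, lexicographic tie-break): a significant parent with exactly
one qualifying significant child is dropped in favor of the child; with two
or more qualifying children, the children are dropped in favor of the
parent.  Only direct edges are examined per pass; passes repeat to a fixed
point, which resolves multi-level chains deterministically.  The procedure
only ever removes terms, every drop is logged with the kept relative and the
Jaccard value, and re-collapsing a collapsed list is a no-op.  Terms outside
the DAG (e.g. pathway collections) are never dropped.  The rule is a
mechanical reduction; it does not reproduce manual curation of which
representative is biologically preferable.

## qPCR quantification and concordance

Relative expression is 2^(−ΔΔCt) with amplification efficiency fixed at
exactly 2 (efficiency estimation is out of scope); duplicate wells are
averaged on the Ct scale before differencing, and the reference-gene
normalization cancels any condition-wide Ct shift exactly.  Cross-platform
concordance compares, per gene × condition, the array fold 2^b of the
gene's representative probe with the qPCR fold averaged over subjects as the
unweighted mean of per-subject log2 folds, then exponentiated — a geometric
mean, consistent with the log-additive effect model; no subject weighting is
applied.  Spearman's rho uses average ranks with the t-approximation on n−2
df for the p-value; an exact permutation p-value is available for n ≤ 9.

## Synthetic-data generator

The generator produces studies with exactly the structure the analysis
assumes: per probe, mean intensity a_g ~ Uniform(4, 14) log2 units;
sigma²_g ~ d₀·s₀²(a_g)/chi²(d₀) with d₀ = 4 and s₀²(a) = 0.05·exp(−0.25·(a−9))
by default (variance halving roughly every 2.8 log2 units, decreasing with
intensity; slope 0 gives a constant prior); subject random effects
N(0, 0.3²); planted exercised-arm effects of |δ| = 1 log2 unit on 5% of
probes (an optional range draws heterogeneous magnitudes, e.g. for
concordance studies where tied fold values would make ranks uninformative);
and Gaussian noise.  sigma²_g is defined on the within-pair-difference
scale — each per-sample draw carries sigma²_g/2 — so the paired residual
variance follows the prior exactly and s²_g/s₀²(a_g) ~ F(d_g, d₀), which is
verified by a KS test.  Group sizes default to 3 male and 4 female subjects
at each of 4 h and 24 h (two arms each), the design the pipeline targets;
with two male groups of 3 and two female groups of 4, the pooled
control-arm baseline contrast is 6 vs 8 samples.

Baseline sex effects are planted as mean shifts on *all* samples of female
subjects.  A shift confined to control arms would leak into the paired
exercised-vs-control contrasts of that sex and contaminate their null; a
subject-level shift is what a resting-state expression difference physically
is — visible to the unpaired baseline contrast and exactly cancelled by
within-subject pairing.

Gene sets are uniform draws from the probe universe (sizes 10–200); 20% of
the flat sets are "loaded": 80% of their members receive coherent effects in
the set's planted direction (first assignment wins for overlapping loaded
sets), and background effects at the configured rate land outside loaded
sets.  Five structured sets form the toy DAG: a parent with one child
covering 90% of it, and a parent with two siblings each covering 75% with
heavy mutual overlap — exercising both branches of the collapse rule.  Ct
panels place target and reference wells in duplicate for both arms, with the
exercised-arm target Ct lowered by the planted log2 fold; technical well
noise and per-subject biological fold variation are separate knobs, both
zero-able, so the 2^−ΔΔCt inversion is exact in the noise-free limit.

Randomness: one root seed; named child streams (intensity, variance,
effects, subjects, noise, sets, sex effects) are spawned from it, so
changing the probe count does not perturb subject effects and changing the
set count does not perturb the expression matrix.  Everything is
reproducible from (config, seed) alone.

What the generator does *not* emulate: probe-level (PM/MM) structure,
spatial array artifacts, batch effects, cross-hybridization, correlated
genes outside the planted sets, or heavy-tailed noise.  Passing tests
demonstrate that the chain is correct and calibrated *under its own model
assumptions*; they do not certify performance on real arrays, where the
variance prior is an approximation rather than the truth.

## Problem sizes used in checks

The automated checks run at sizes chosen to make the statistical assertions
sharp while keeping the suite quick: hyperparameter recovery on 50,000
probes × 20 replicates (d₀ within [3, 5] and median prior scale within 20%
in ≥ 19/20); null calibration on 20,000 probes at 4 pairs (rates within 3
binomial SDs of 0.01 and 0.05); power ordering on 100 replicates of 2,000
probes (moderated ≥ ordinary sensitivity at q < 0.05 in ≥ 90); enrichment
null calibration on 2,000 set-replicates of size 30 over 2,000-gene
universes; direction recovery over 100 small planted studies (≥ 95% "up"
calls among FDR-passing all-up sets); and end-to-end recovery over 25
five-comparison replicates (median ≥ 80% of loaded sets at FDR < 0.01 with
the planted direction).  `scripts/acceptance.py` re-measures the same
quantities from scratch at a single seed.

## Known limitations

* Single-coefficient contrasts only: no covariates, array weights, or
  multi-factor linear models.
* The moderated test assumes exchangeable gene variances around a smooth
  intensity trend; sharp variance subpopulations would be over-shrunk.
* The Wald set p-value relies on the large-universe normal approximation;
  for universes of a few hundred genes with tiny sets the calibration test
  is the guardrail, not a guarantee.
* The collapse rule considers direct parent–child edges only; cousins or
  terms linked through an unmeasured intermediate are never merged.
* The enrichment matrix is the clustering input; no clustering or rendering
  is performed.
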