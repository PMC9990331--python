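# Methods

## Cohort construction

A phenotype table (subject id, age, HbA1c) is reduced to a confounded
case-control cohort deterministically. Age and HbA1c are z-scored over the
complete-case table (sample SD, `ddof=1`); each subject receives a selection
probability

    p_i = expit(b0 + ln(OR_age)·z_age,i + ln(OR_HbA1c)·z_HbA1c,i)

with defaults `b0 = 2.5`, `OR_age = OR_HbA1c = 1.5` per covariate SD.
Subjects are ranked by descending probability, the top `n_drop_top`
(default 5) are discarded to avoid covariate outliers, the next `n_select`
(default 60) form the cohort, and the `n_cases` (default 30) with the
lowest probability become cases. Because only ranks matter, the intercept
has no effect on who is selected. Probability ties break by ascending
subject id so the procedure is reproducible across platforms. Under odds
ratios > 1 the cases are systematically younger with lower HbA1c — the
deliberate confounding the allocation strategies are evaluated against.

## Propensity-score screening

All block/batch screening reduces to logistic regressions of a membership
indicator on the covariates. These are solved by iteratively reweighted
least squares, batched across candidate blocks (one shared design matrix,
one coefficient row per block), with

* max 25 iterations, convergence when the max coefficient change < 1e-8;
* Newton steps backtracked (step-halving) whenever they fail to improve the
  penalized likelihood — essential because small blocks are frequently
  perfectly separable in two covariates, and an unguarded IRLS overflows
  there in a way that corrupts the fitted probabilities (saturating *both*
  classes at 1), silently inverting the ranking;
* on non-convergence or a rank-deficient design, a ridge penalty of 1e-6 on
  the slopes and a refit, flagged on the result. Separable blocks end with
  fitted probabilities saturated toward their indicator, hence a
  propensity-score gap near 1 — correctly ranked as maximally imbalanced.

Gaps are absolute differences of class-mean fitted probabilities
(imbalance is directionless). Batch-pairing candidates are ranked on the
between-batch and within-batch gaps with midranks on ties; gaps are rounded
to 10 decimals before ranking because mathematically tied pairings (a batch
and its complement, blocks with mirrored membership) otherwise differ only
in rounding noise and would be ranked arbitrarily. All sorts carry a final
lexicographic tie-break on membership, which also makes the optimal
allocation invariant to input row order.

Full enumeration is capped at 1e6 candidate blocks per stratum by default.
C(30,10) ≈ 3.0e7 — the full 60-subject, 3-batch design — exceeds the cap;
such runs either raise the cap explicitly (documented as long-running:
~3e7 batched logistic fits) or use the constrained randomization variant,
which draws R stratified allocations and keeps the one minimizing the
summed between- plus within-batch gaps from one all-cohort propensity fit
per candidate batch.

## Batch-effect simulation

The contaminated matrix is `Y_s = Y_T + Σ_b μ_b·B_b + ω`. By default each
batch receives one scalar shift `μ_b ~ N(0, sd_batch²)` applied to all its
samples and genes (the literal reading of a shift times an indicator
vector); a per-gene mode (`μ_{b,g}` independent per gene) is provided as
the common alternative. `sd_batch` defaults to 0.57 = 2 x the median
per-gene SD the framework emulates (0.285 on the RMA log2 scale), and is
derived from the data when a multiplier is given. `ω` is i.i.d.
`N(0, 0.05²)` — under a fifth of the biological SD. The "(mean, SD)"
reading of these parameters is the only one consistent with both anchors
(0.57 ≈ 2 x 0.285 and 0.05 < 0.285/5). Draws are recorded so tests can
verify the exact decomposition. Fresh independent draws are taken per
scenario and iteration.

## ComBat

The correction module re-implements parametric empirical-Bayes ComBat:
per-gene standardization by a batch-means (plus optional protected
covariates) fit and pooled SD; method-of-moments normal priors on the
per-batch location effects and inverse-gamma priors on the scale effects;
the coupled posterior equations iterated until the max relative change
< 1e-4 (cap 100); back-transformation. The protected-covariate matrix
defaults to intercept-only, matching a plain ComBat call. Zero-variance
genes (pooled variance below 1e-20, i.e. numerically constant) pass through
unadjusted with a warning. The implementation is cross-checked in the test
suite against `sva::ComBat` (agreement ~1e-6 on the adjusted matrix) and
against an independently coded fixed-point iteration of the posterior
equations.

Two properties of ComBat itself matter for interpreting results at small n:
its back-transform pins each batch's per-gene variance to the pooled
variance, which is computed without a degrees-of-freedom correction, so a
ComBat pass on *clean* data deflates downstream standard errors by roughly
`sqrt((n−k)/n · (n−k−p+1)/(n−p))` (~6% at n=36, k=3) and perturbs
per-gene coefficients by up to about half a standard error (it removes
observed per-gene batch means even when no batch effect exists, shrinkage
notwithstanding). Both effects are reproduced bit-for-bit by the reference
R implementation; they are properties of the method, not of this port.
Consequently the minimum average SE after ComBat sits a few percent *below*
the true-data average SE in this framework, for every allocation strategy.

Fixed-effects ("regression") adjustment is not a matrix transformation: it
is realized as batch indicator columns in the per-gene analysis design.

## Per-gene models and metrics

Each gene is fit by OLS against intercept + case + age + HbA1c (+ batch
indicators in the regression-adjustment arm), all genes solved through one
factorization, classical SEs with `dof = n − p`. Per iteration and
coefficient the framework records the maximum absolute bias across genes
(against the no-batch fit on the uncontaminated matrix), the average SE
across genes, and the absolute bias at one designated signal gene; the
summaries are the mean and sample SD over iterations of the maximum
("average max" and "RMS"), the mean and minimum over iterations of the
average SE, and mean/max/SD over iterations at the single gene. "RMS" is
implemented as the sample SD, following the convention of the evaluation
design it reproduces. Exact absorption holds by construction: with scalar
shifts and zero noise, the batch-dummy model on contaminated data equals
the same model on clean data to machine precision (the shift lies in the
span of the batch columns); note this is exactness *relative to the same
design* — adding batch columns changes finite-sample estimates relative to
the no-batch truth regardless of shifts.

The signal gene is chosen as the gene minimizing the larger of the two
two-sided t-test p-values for age and HbA1c in the true fit (tie-break by
gene id) — the in-framework analogue of picking a transcript significantly
associated with both covariates.

The experiment driver fixes the optimal allocation across iterations (it is
a deterministic function of the covariates) while the randomized strategies
redraw each iteration; this is why the optimal arm's RMS is an order of
magnitude smaller. Per-iteration randomness derives from the base seed
through counter-based `SeedSequence(entropy=seed, spawn_key=(iteration,
scenario, role))` streams, so arms are independent yet the whole grid is
bit-reproducible.

## Synthetic data

The generator emulates the statistical shape of an RMA-normalized islet
microarray study without simulating probes or gene-gene correlation:

* phenotypes: bivariate normal, age 56 ± 11 years, HbA1c 5.5 ± 0.45 %,
  correlation 0.3 — chosen to straddle the case/control means the selection
  model should produce (≈49/63 years, ≈5.2/5.8 %), and verified to do so;
* genes: baseline `N(7, 1.5²)` per gene; residual SDs log-normal
  (log-scale SD 0.5) rescaled so the realized median equals 0.285 exactly,
  pinning the shift-to-biology ratio of the simulation;
* signal genes: `min(50, n_genes/10)` genes carry linear covariate effects,
  split between age-only (0.03 log2 units/year) and HbA1c-only (0.8 log2
  units per %), with one designated gene carrying both; the designated gene
  gets the median residual SD so its joint association is unambiguous.
  Because the selection model induces strong case-age collinearity, the
  designated gene is recovered by the p-value criterion with high
  probability but not certainty (~90% over seeds at 500 genes).

What passing tests on this generator show: the ordering and magnitude
relations between allocation strategies and adjustment methods, the exact
algebraic properties, and the correctness of each component against
independent oracles. What they cannot show: behavior under gene-gene
correlation, heavy-tailed or skewed expression, non-scalar batch effects,
or covariate distributions unlike the emulated study.

## Problem sizes

The default evaluation study runs 36 subjects (18/18) in 3 batches — full
enumeration C(18,6) = 18,564 blocks per stratum — with 500 genes and 200
iterations, sizes at which the whole grid completes in seconds while every
qualitative contrast between strategies is already decisive. The full
60-subject design is supported but requires raising the enumeration cap
(~3.0e7 block fits) or the constrained variant.

## Known limitations

* Balanced designs only (equal cases and controls per batch); unbalanced
  batch correction is a different problem and out of scope.
* Two continuous covariates by contract of the cohort model; the allocation
  machinery itself accepts any covariate matrix.
* Additive location shifts only; no scale, position or plate effects, no
  missing data.
* Non-parametric ComBat, surrogate-variable estimation and other correction
  families are out of scope.
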