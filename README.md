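# psbatch

Propensity-score-guided assignment of samples to batches for balanced
case-control omics experiments, with a full simulation framework to measure
what the design choice buys you.

## The problem

Batch effects — non-biological variation shared by samples processed on the
same chip, run or day — can dwarf the biological signal in high-throughput
experiments. Correction methods (ComBat, fixed-effects regression) work well
*on average*, but a single unlucky randomization that correlates batch with a
biological covariate leaves bias that no downstream correction fully
removes. When all subject-level covariates are known before the samples are
run — the usual situation in omics — the allocation itself can be optimized
instead of randomized.

`psbatch` implements an optimal allocation algorithm for a balanced
case-control design with continuous confounders (here: age in years and
HbA1c in %):

1. Within each stratum (cases, controls), enumerate every possible block of
   `group size / n_batches` subjects.
2. For each block, fit a logistic regression of block membership on the
   covariates; the fitted probabilities are propensity scores
   `e(x) = Pr(in block | age, HbA1c)`. Score the block by the gap
   `|mean e(x) in block − mean e(x) outside|` — zero gap means the block is
   indistinguishable from the rest of the stratum, i.e. perfectly balanced.
3. Greedily keep the `n_batches` lowest-gap disjoint blocks per stratum.
4. Pair case blocks with control blocks into batches: each pairing is
   scored over the whole cohort by a between-batch gap (batch vs everyone
   else) and a within-batch gap (its cases vs its controls); pairings are
   ranked on both gaps and the best disjoint pairings become batches 1..k.

Everything is deterministic: no seed, same answer every run.

The surrounding framework reproduces the evaluation design: a confounded
cohort is built from a phenotype table by a logistic selection model
(`expit(2.5 + ln 1.5·z_age + ln 1.5·z_HbA1c)`, extremes dropped, the
lowest-probability subjects become cases), additive batch effects
`Y_s = Y_T + μ₁B₁ + μ₂B₂ + μ₃B₃ + ω` with `μ_b ~ N(0, sd²_batch)` and
`ω ~ N(0, 0.05²)` are simulated on a "true" expression matrix, and per-gene
OLS models `y ~ case + age + HbA1c` quantify, against the fit on the
uncontaminated matrix, the absolute coefficient bias and standard errors
under every allocation strategy (optimal / simple randomization / stratified
randomization) × adjustment (none / ComBat / batch fixed effects) cell.
ComBat — the parametric empirical-Bayes location/scale model — is
re-implemented here and cross-checked against `sva::ComBat` in the tests.
A best-of-R constrained randomization is included for designs too large to
enumerate.

## Worked example

```python
from psbatch import SelectionParams, SyntheticConfig, make_demo_dataset, optimal_allocate
from psbatch.evaluation import ExperimentConfig, run_experiment

selection = SelectionParams(n_drop_top=2, n_select=36, n_cases=18)
cohort, expr = make_demo_dataset(
    seed=1, config=SyntheticConfig(n_subjects=40, n_genes=500), selection=selection
)
assignment = optimal_allocate(cohort, n_batches=3)

config = ExperimentConfig(n_iterations=50, n_batches=3, seed=1)
result = run_experiment(expr, cohort, config)
for strategy in ("optimal", "random", "stratified"):
    s = result.bias[(strategy, "none")]
    print(f"{strategy:11s} avg={s.loc['case', 'avg_max_abs_bias']:.4f} "
          f"rms={s.loc['case', 'rms_max_abs_bias']:.4f}")
```

prints

```
optimal     avg=0.0936 rms=0.0103
random      avg=0.2363 rms=0.1184
stratified  avg=0.2631 rms=0.1368
```

i.e. before any correction, the worst-gene absolute bias of the case
coefficient averages 2.5x smaller under the optimal allocation than under
either randomization, and its iteration-to-iteration spread ("RMS", the SD
of the per-iteration maximum) is an order of magnitude smaller — the
optimal allocation is fixed by the covariates, so only the shift draws vary.

A command-line interface mirrors the library
(`psbatch synth | allocate | simulate | correct | run`); see
`psbatch --help`.

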