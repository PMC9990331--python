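"""Per-gene linear models, bias/standard-error metrics and the scenario grid.

Every gene is fit by ordinary least squares against a shared design of an
intercept, a case indicator, age and HbA1c (plus batch indicator columns
when batches are adjusted for as fixed effects). Bias of a coefficient, for
a gene and simulation iteration, is the absolute difference from the
coefficient fitted on the uncontaminated ("true") matrix. The experiment
driver crosses allocation strategies with adjustment methods and
accumulates, per cell of that grid:

* average and SD over iterations of the per-iteration maximum absolute
  bias across genes (the SD is reported as "RMS", following the source
  framework's usage);
* mean and minimum over iterations of the per-iteration average standard
  error across genes, against the true-data average SE;
* bias statistics at one designated signal gene associated with both
  covariates (the alternative-hypothesis probe).

The optimal allocation is deterministic and therefore computed once and
held fixed across iterations, while the randomized strategies redraw every
iteration — this is why its between-iteration variability ("RMS") is so
much smaller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allocation import (
    BatchAssignment,
    DEFAULT_CAP,
    optimal_allocate,
    random_allocate,
    stratified_allocate,
)
from .batchsim import BatchEffectConfig, median_gene_sd, simulate_batch_effects
from .cohort import Cohort
from .correction import combat_adjust

__all__ = [
    "COEFFICIENTS",
    "GeneFitResult",
    "ExperimentConfig",
    "ExperimentResult",
    "build_design",
    "fit_gene_models",
    "true_fit",
    "summarize_bias",
    "summarize_se",
    "single_gene_summary",
    "find_signal_gene",
    "run_experiment",
]

#: Coefficients whose bias and SE the framework tracks.
COEFFICIENTS = ("case", "age", "hba1c")

STRATEGIES = ("optimal", "random", "stratified")
ADJUSTMENTS = ("none", "combat", "regression")


def build_design(cohort: Cohort, assignment: BatchAssignment | None = None) -> pd.DataFrame:
    """Design matrix: intercept, case indicator, age, HbA1c [, batch dummies].

    Rows follow ascending subject id. With an assignment, batches 2..k get
    indicator columns (batch 1 is the reference), realizing fixed-effects
    regression adjustment for batch.
    """
    frame = cohort.frame.sort_index()
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "case": (frame["group"] == "case").astype(float),
            "age": frame["age"].astype(float),
            "hba1c": frame["hba1c"].astype(float),
        },
        index=frame.index,
    )
    if assignment is not None:
        batches = assignment.batches.reindex(design.index)
        if batches.isna().any():
            raise ValueError("assignment does not cover the cohort")
        for b in sorted(batches.unique())[1:]:
            design[f"batch_{int(b)}"] = (batches == b).astype(float)
    return design


@dataclass
class GeneFitResult:
    """OLS results for all genes against one design.

    ``betas`` and ``ses`` are genes x coefficients DataFrames; ``dof`` is
    the residual degrees of freedom n - p shared by all genes.
    """

    betas: pd.DataFrame = field(repr=False)
    ses: pd.DataFrame = field(repr=False)
    dof: int = 0


def fit_gene_models(expr: pd.DataFrame, design: pd.DataFrame) -> GeneFitResult:
    """Fit every gene by OLS against the shared design, with classical SEs.

    All genes are solved simultaneously through one factorization of the
    design; standard errors use the per-gene residual variance with
    ``dof = n - p``.
    """
    if set(expr.index) != set(design.index):
        raise ValueError("expression samples and design rows must match")
    expr = expr.reindex(design.index)
    X = design.to_numpy(dtype=float)
    Y = expr.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    XtX = X.T @ X
    XtXi = np.linalg.inv(XtX)
    B = XtXi @ (X.T @ Y)  # p x genes
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / (n - p)
    se = np.sqrt(np.outer(np.diag(XtXi), sigma2))

    genes = expr.columns
    return GeneFitResult(
        betas=pd.DataFrame(B.T, index=genes, columns=design.columns),
        ses=pd.DataFrame(se.T, index=genes, columns=design.columns),
        dof=n - p,
    )


def true_fit(expr_true: pd.DataFrame, cohort: Cohort) -> GeneFitResult:
    """Reference fit: the batch-free design on the uncontaminated matrix."""
    return fit_gene_models(expr_true, build_design(cohort))


# ---------------------------------------------------------------------------
# Per-iteration reductions and their summaries
# ---------------------------------------------------------------------------


def _abs_bias(fit: GeneFitResult, truth: GeneFitResult) -> pd.DataFrame:
    """Genes x coefficients |beta* - beta| against the true fit."""
    if not fit.betas.index.equals(truth.betas.index):
        raise ValueError("fits and truth must cover the same genes")
    return (fit.betas[list(COEFFICIENTS)] - truth.betas[list(COEFFICIENTS)]).abs()


def iteration_max_abs_bias(fit: GeneFitResult, truth: GeneFitResult) -> pd.Series:
    """Per coefficient, the maximum absolute bias across genes (one iteration)."""
    return _abs_bias(fit, truth).max(axis=0)


def iteration_avg_se(fit: GeneFitResult) -> pd.Series:
    """Per coefficient, the average standard error across genes (one iteration)."""
    return fit.ses[list(COEFFICIENTS)].mean(axis=0)


def _sample_sd(arr: np.ndarray) -> np.ndarray:
    # "RMS": the sample SD across iterations; zero (not NaN) for a single one.
    if arr.shape[0] < 2:
        return np.zeros(arr.shape[1:])
    return arr.std(axis=0, ddof=1)


def summarize_bias(fits: Iterable[GeneFitResult], truth: GeneFitResult) -> pd.DataFrame:
    """Average and SD over iterations of the per-iteration max absolute bias.

    Returns a coefficients x {avg_max_abs_bias, rms_max_abs_bias} DataFrame.
    """
    maxima = np.array([iteration_max_abs_bias(f, truth).to_numpy() for f in fits])
    if maxima.size == 0:
        raise ValueError("no iterations to summarize")
    return pd.DataFrame(
        {
            "avg_max_abs_bias": maxima.mean(axis=0),
            "rms_max_abs_bias": _sample_sd(maxima),
        },
        index=pd.Index(COEFFICIENTS, name="coefficient"),
    )


def summarize_se(fits: Iterable[GeneFitResult], truth: GeneFitResult) -> pd.DataFrame:
    """Mean and minimum over iterations of the per-iteration average SE.

    ``true_avg_se`` is the average SE in the true (uncontaminated) fit.
    """
    avg = np.array([iteration_avg_se(f).to_numpy() for f in fits])
    if avg.size == 0:
        raise ValueError("no iterations to summarize")
    return pd.DataFrame(
        {
            "mean_avg_se": avg.mean(axis=0),
            "min_avg_se": avg.min(axis=0),
            "true_avg_se": iteration_avg_se(truth).to_numpy(),
        },
        index=pd.Index(COEFFICIENTS, name="coefficient"),
    )


def single_gene_summary(gene_id, fits: Iterable[GeneFitResult],
                        truth: GeneFitResult) -> pd.DataFrame:
    """Mean, max and SD of absolute bias across iterations at one gene."""
    if gene_id not in truth.betas.index:
        raise KeyError(f"unknown gene {gene_id!r}")
    biases = np.array([_abs_bias(f, truth).loc[gene_id].to_numpy() for f in fits])
    if biases.size == 0:
        raise ValueError("no iterations to summarize")
    return pd.DataFrame(
        {
            "mean_abs_bias": biases.mean(axis=0),
            "max_abs_bias": biases.max(axis=0),
            "rms_abs_bias": _sample_sd(biases),
        },
        index=pd.Index(COEFFICIENTS, name="coefficient"),
    )


def find_signal_gene(expr_true: pd.DataFrame, cohort: Cohort) -> str:
    """The gene most strongly associated with BOTH age and HbA1c in the true data.

    Two-sided t-test p-values are computed for the age and HbA1c
    coefficients of the true fit; the gene minimizing the larger of the two
    p-values wins (ties break by gene id). Emulates picking a single
    covariate-associated transcript as the alternative-hypothesis probe.
    """
    truth = true_fit(expr_true, cohort)
    pvals = {}
    for coef in ("age", "hba1c"):
        t = truth.betas[coef] / truth.ses[coef]
        pvals[coef] = 2.0 * stats.t.sf(np.abs(t), df=truth.dof)
    worst = np.maximum(pvals["age"], pvals["hba1c"])
    order = sorted(range(len(worst)), key=lambda i: (worst[i], truth.betas.index[i]))
    return truth.betas.index[order[0]]


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of the allocation-strategy x adjustment-method grid.

    ``sd_batch`` overrides the derived value ``batch_sd_multiplier`` x
    median per-gene SD of the true matrix. ``signal_gene`` defaults to the
    gene chosen by :func:`find_signal_gene`.
    """

    strategies: Sequence[str] = STRATEGIES
    adjustments: Sequence[str] = ADJUSTMENTS
    n_iterations: int = 1000
    n_batches: int = 3
    batch_sd_multiplier: float = 2.0
    sd_batch: float | None = None
    sd_noise: float = 0.05
    mode: str = "scalar_per_batch"
    seed: int = 0
    cap: int = DEFAULT_CAP
    signal_gene: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies: {sorted(unknown)}")
        unknown = set(self.adjustments) - set(ADJUSTMENTS)
        if unknown:
            raise ValueError(f"unknown adjustments: {sorted(unknown)}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")


@dataclass
class ExperimentResult:
    """Results of one experiment run.

    ``bias``, ``se`` and ``single_gene`` map (strategy, adjustment) cells to
    the summary DataFrames; ``table`` is everything in long format with
    columns scenario, adjustment, coefficient, metric, value.
    """

    bias: dict = field(repr=False)
    se: dict = field(repr=False)
    single_gene: dict = field(repr=False)
    signal_gene: str = ""
    truth: GeneFitResult = None
    config: ExperimentConfig = None

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for name, summaries in (("bias", self.bias), ("se", self.se),
                                ("single_gene", self.single_gene)):
            for (strategy, adjustment), summary in summaries.items():
                long = summary.reset_index().melt(
                    id_vars="coefficient", var_name="metric", value_name="value"
                )
                if name == "single_gene":
                    long["metric"] = "sg_" + long["metric"]
                long.insert(0, "adjustment", adjustment)
                long.insert(0, "scenario", strategy)
                rows.append(long)
        return pd.concat(rows, ignore_index=True)


def _iteration_seed(base_seed: int, iteration: int, strategy_index: int,
                    role: int) -> np.random.SeedSequence:
    # Counter-based derivation: every (iteration, scenario, role) gets an
    # independent stream, reproducible from the base seed alone.
    return np.random.SeedSequence(entropy=base_seed,
                                  spawn_key=(iteration, strategy_index, role))


def run_experiment(expr_true: pd.DataFrame, cohort: Cohort,
                   config: ExperimentConfig | None = None) -> ExperimentResult:
    """Run the full allocation x adjustment simulation grid.

    Per iteration and allocation strategy: draw the allocation (the optimal
    one is deterministic, computed once up front, and held fixed), add
    fresh batch shifts and noise, then evaluate each adjustment arm — no
    adjustment, ComBat followed by the batch-free model, or the model with
    batch fixed effects. Accumulates max-absolute-bias, average-SE and
    single-gene bias per iteration and returns their summaries per grid
    cell. Bit-reproducible from ``config.seed``.
    """
    if config is None:
        config = ExperimentConfig()
    sd_batch = config.sd_batch
    if sd_batch is None:
        sd_batch = config.batch_sd_multiplier * median_gene_sd(expr_true)
    batch_cfg = BatchEffectConfig(sd_batch=sd_batch, sd_noise=config.sd_noise,
                                  mode=config.mode)

    truth = true_fit(expr_true, cohort)
    signal_gene = config.signal_gene or find_signal_gene(expr_true, cohort)
    if signal_gene not in expr_true.columns:
        raise KeyError(f"signal gene {signal_gene!r} not in the matrix")
    design_plain = build_design(cohort)
    sg_pos = truth.betas.index.get_loc(signal_gene)
    coef_cols = list(COEFFICIENTS)
    truth_beta = truth.betas[coef_cols].to_numpy()

    fixed_optimal = None
    if "optimal" in config.strategies:
        fixed_optimal = optimal_allocate(cohort, config.n_batches, cap=config.cap)

    cells = [(s, a) for s in config.strategies for a in config.adjustments]
    max_bias = {cell: [] for cell in cells}
    avg_se = {cell: [] for cell in cells}
    sg_bias = {cell: [] for cell in cells}

    for it in range(config.n_iterations):
        for s_idx, strategy in enumerate(config.strategies):
            if strategy == "optimal":
                assignment = fixed_optimal
            elif strategy == "random":
                assignment = random_allocate(
                    cohort, config.n_batches,
                    seed=_iteration_seed(config.seed, it, s_idx, 0))
            else:
                assignment = stratified_allocate(
                    cohort, config.n_batches,
                    seed=_iteration_seed(config.seed, it, s_idx, 0))
            sim = simulate_batch_effects(
                expr_true, assignment, batch_cfg,
                seed=_iteration_seed(config.seed, it, s_idx, 1))
            for adjustment in config.adjustments:
                if adjustment == "none":
                    fit = fit_gene_models(sim.values, design_plain)
                elif adjustment == "combat":
                    corrected, _ = combat_adjust(sim.values, assignment.batches)
                    fit = fit_gene_models(corrected, design_plain)
                else:
                    fit = fit_gene_models(sim.values, build_design(cohort, assignment))
                bias = np.abs(fit.betas[coef_cols].to_numpy() - truth_beta)
                cell = (strategy, adjustment)
                max_bias[cell].append(bias.max(axis=0))
                avg_se[cell].append(fit.ses[coef_cols].to_numpy().mean(axis=0))
                sg_bias[cell].append(bias[sg_pos])

    index = pd.Index(COEFFICIENTS, name="coefficient")
    bias_out, se_out, sg_out = {}, {}, {}
    true_avg = truth.ses[coef_cols].to_numpy().mean(axis=0)
    for cell in cells:
        maxima = np.array(max_bias[cell])
        bias_out[cell] = pd.DataFrame(
            {"avg_max_abs_bias": maxima.mean(axis=0),
             "rms_max_abs_bias": _sample_sd(maxima)}, index=index)
        ses = np.array(avg_se[cell])
        se_out[cell] = pd.DataFrame(
            {"mean_avg_se": ses.mean(axis=0), "min_avg_se": ses.min(axis=0),
             "true_avg_se": true_avg}, index=index)
        sg = np.array(sg_bias[cell])
        sg_out[cell] = pd.DataFrame(
            {"mean_abs_bias": sg.mean(axis=0), "max_abs_bias": sg.max(axis=0),
             "rms_abs_bias": _sample_sd(sg)}, index=index)

    return ExperimentResult(bias=bias_out, se=se_out, single_gene=sg_out,
                            signal_gene=signal_gene, truth=truth, config=config)
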