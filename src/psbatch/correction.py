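"""Parametric empirical-Bayes batch correction (ComBat-style location/scale model).

Known batch effects are removed in four steps: (1) each gene is standardized
by the fit of a grand mean (plus optional protected covariates) and batch
means, divided by the pooled residual SD; (2) per-batch per-gene location
(gamma) and scale (delta^2) effects are estimated on the standardized data
and parametric priors — normal for gamma, inverse-gamma for delta^2 — are
fitted across genes by method of moments; (3) the coupled posterior
equations for the shrunk effects gamma*, delta2* are iterated to
convergence; (4) the shrunk effects are removed and the data back-
transformed. Shrinkage borrows strength across genes, so a location shift
shared by all genes in a batch is removed almost exactly while per-gene
noise in the batch-effect estimates is damped.

Regression (fixed-effects) adjustment for known batches is not a matrix
transformation here: it is realized as batch indicator columns in the
per-gene analysis design (see :mod:`psbatch.evaluation`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CombatEstimates", "combat_adjust"]


@dataclass
class CombatEstimates:
    """Intermediate estimates of a ComBat adjustment.

    Location effects ``gamma_hat`` (raw) and ``gamma_star`` (EB-shrunk) and
    scale effects ``delta2_hat`` / ``delta2_star`` are batches x genes
    DataFrames on the standardized scale. ``gamma_bar``/``t2`` are the
    normal-prior moments and ``a_prior``/``b_prior`` the inverse-gamma
    parameters, one per batch. ``var_pooled`` is the per-gene pooled
    residual variance used for standardization.
    """

    gamma_hat: pd.DataFrame = field(repr=False)
    gamma_star: pd.DataFrame = field(repr=False)
    delta2_hat: pd.DataFrame = field(repr=False)
    delta2_star: pd.DataFrame = field(repr=False)
    gamma_bar: pd.Series = field(repr=False)
    t2: pd.Series = field(repr=False)
    a_prior: pd.Series = field(repr=False)
    b_prior: pd.Series = field(repr=False)
    var_pooled: pd.Series = field(repr=False)
    n_iterations: dict = field(default_factory=dict)


def _aprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m = delta_hat.mean()
    s2 = delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(sdat: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterate the coupled EB posterior equations for one batch.

    ``sdat`` is genes x (samples in batch) standardized data. Returns the
    shrunk location/scale vectors and the iteration count.
    """
    n = sdat.shape[1]
    g_old = g_hat.copy()
    d_old = d_hat.copy()
    count = 0
    while count < max_iter:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            (np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)).max(),
            (np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)).max(),
        )
        g_old, d_old = g_new, d_new
        count += 1
        if change < tol:
            break
    return g_old, d_old, count


def combat_adjust(expr: pd.DataFrame, batch, covariates: pd.DataFrame | None = None,
                  max_iter: int = 100, tol: float = 1e-4
                  ) -> tuple[pd.DataFrame, CombatEstimates]:
    """Remove known batch effects with the parametric EB location/scale model.

    Parameters
    ----------
    expr
        Samples x genes matrix (RMA-style log2 values).
    batch
        Per-sample batch labels aligned with ``expr`` rows (a Series indexed
        by sample id, or an array in row order).
    covariates
        Optional protected design columns (e.g. a case indicator); default
        is intercept-only, matching a plain ComBat call.
    max_iter, tol
        Convergence control of the posterior iteration (max relative change
        of the location and scale effects).

    Returns the adjusted matrix (same shape, ids and sample order) and the
    :class:`CombatEstimates`. Genes with zero pooled variance pass through
    unadjusted with a warning.
    """
    if isinstance(batch, pd.Series):
        batch = batch.reindex(expr.index)
        if batch.isna().any():
            raise ValueError("batch labels missing for some samples")
    batch = np.asarray(batch)
    if len(batch) != expr.shape[0]:
        raise ValueError("batch labels must align with samples")
    labels, batch_idx = np.unique(batch, return_inverse=True)
    n_batch = len(labels)
    if n_batch < 2:
        raise ValueError("need at least two batches")
    counts = np.bincount(batch_idx)
    if counts.min() < 2:
        raise ValueError("every batch needs at least two samples")

    dat = expr.to_numpy(dtype=float).T  # genes x samples, as in the original model
    n_genes, n_samples = dat.shape

    batchmod = np.zeros((n_samples, n_batch))
    batchmod[np.arange(n_samples), batch_idx] = 1.0
    if covariates is not None:
        mod = np.asarray(covariates, dtype=float)
        if mod.ndim == 1:
            mod = mod[:, None]
        if mod.shape[0] != n_samples:
            raise ValueError("covariates must align with samples")
        design = np.column_stack([batchmod, mod])
    else:
        design = batchmod
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("batch + covariate design is rank deficient")

    # Standardization: batch-mean fit, pooled variance, grand mean.
    B_hat = np.linalg.solve(design.T @ design, design.T @ dat.T)  # p x genes
    grand_mean = (counts / n_samples) @ B_hat[:n_batch, :]  # genes
    resid = dat - (design @ B_hat).T
    var_pooled = (resid**2).mean(axis=1)

    # Numerically flat genes: a truly constant gene leaves only rounding
    # error (~1e-30 on the variance scale) after the batch-means fit.
    degenerate = var_pooled <= 1e-20
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance genes pass through unadjusted",
            RuntimeWarning,
        )

    stand_mean = np.tile(grand_mean[:, None], (1, n_samples))
    if covariates is not None:
        tmp = design.copy()
        tmp[:, :n_batch] = 0.0
        stand_mean = stand_mean + (tmp @ B_hat).T

    ok = ~degenerate
    sd_pooled = np.sqrt(var_pooled[ok])
    s_data = (dat[ok] - stand_mean[ok]) / sd_pooled[:, None]

    gamma_hat = np.stack([s_data[:, batch_idx == i].mean(axis=1) for i in range(n_batch)])
    delta2_hat = np.stack([s_data[:, batch_idx == i].var(axis=1, ddof=1)
                           for i in range(n_batch)])

    gamma_bar = gamma_hat.mean(axis=1)
    t2 = gamma_hat.var(axis=1, ddof=1)
    a_prior = np.array([_aprior(delta2_hat[i]) for i in range(n_batch)])
    b_prior = np.array([_bprior(delta2_hat[i]) for i in range(n_batch)])

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    n_iterations = {}
    for i in range(n_batch):
        g, d, it = _it_sol(s_data[:, batch_idx == i], gamma_hat[i], delta2_hat[i],
                           gamma_bar[i], t2[i], a_prior[i], b_prior[i], tol, max_iter)
        gamma_star[i], delta2_star[i] = g, d
        n_iterations[labels[i]] = it

    bayes = s_data.copy()
    for i in range(n_batch):
        cols = batch_idx == i
        bayes[:, cols] = (s_data[:, cols] - gamma_star[i][:, None]) / np.sqrt(
            delta2_star[i][:, None]
        )
    bayes = bayes * sd_pooled[:, None] + stand_mean[ok]

    adjusted = dat.copy()
    adjusted[ok] = bayes

    genes_ok = expr.columns[ok]
    index = pd.Index(labels, name="batch")

    def _frame(arr: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(arr, index=index, columns=genes_ok)

    estimates = CombatEstimates(
        gamma_hat=_frame(gamma_hat),
        gamma_star=_frame(gamma_star),
        delta2_hat=_frame(delta2_hat),
        delta2_star=_frame(delta2_star),
        gamma_bar=pd.Series(gamma_bar, index=index),
        t2=pd.Series(t2, index=index),
        a_prior=pd.Series(a_prior, index=index),
        b_prior=pd.Series(b_prior, index=index),
        var_pooled=pd.Series(var_pooled, index=expr.columns),
        n_iterations=n_iterations,
    )
    out = pd.DataFrame(adjusted.T, index=expr.index, columns=expr.columns)
    return out, estimates
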