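"""Synthetic phenotype and expression generators.

Emulates the statistical structure of an RMA-normalized islet microarray
study: a table of subjects with correlated age and HbA1c, and a log2
expression matrix whose per-gene SDs have a controlled median, with a small
set of genes linearly associated with the covariates (one designated gene
carries both an age and an HbA1c effect — the stand-in for a
covariate-associated transcript such as CAPN13). No probe structure or
gene-gene correlation is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import Cohort, SelectionParams, select_cohort

__all__ = ["SyntheticConfig", "generate_phenotypes", "generate_true_expression",
           "make_demo_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Phenotype moments straddle the case/control means the selection model
    is meant to produce (ages around the mid-50s with SD ~11 years, HbA1c
    around 5.5% with SD ~0.45). Gene SDs are drawn log-normal and rescaled
    so their realized median equals ``median_gene_sd`` exactly, pinning the
    batch-shift-to-biological-variability ratio. Signal genes split evenly
    into age-only, HbA1c-only and one both-covariate gene.
    """

    n_subjects: int = 65
    age_mean: float = 56.0
    age_sd: float = 11.0
    hba1c_mean: float = 5.5
    hba1c_sd: float = 0.45
    correlation: float = 0.3
    n_genes: int = 10_000
    median_gene_sd: float = 0.285
    gene_sd_log_sigma: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    n_signal_genes: int | None = None  # default: min(50, n_genes // 10), at least 1
    age_effect: float = 0.03
    hba1c_effect: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age_sd <= 0 or self.hba1c_sd <= 0 or self.median_gene_sd <= 0:
            raise ValueError("scale parameters must be positive")
        if not -1 < self.correlation < 1:
            raise ValueError("correlation must lie strictly in (-1, 1)")
        if self.n_signal_genes is not None and self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes cannot exceed n_genes")

    @property
    def effective_n_signal_genes(self) -> int:
        if self.n_signal_genes is not None:
            return self.n_signal_genes
        return min(50, max(1, self.n_genes // 10))


def generate_phenotypes(config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Draw a bivariate-normal (age, HbA1c) phenotype table.

    Returns columns ``subject_id`` (S001, S002, ...), ``age``, ``hba1c``;
    reproducible from ``config.seed``.
    """
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    cov = config.correlation * config.age_sd * config.hba1c_sd
    sigma = np.array([[config.age_sd**2, cov], [cov, config.hba1c_sd**2]])
    draws = rng.multivariate_normal([config.age_mean, config.hba1c_mean], sigma,
                                    size=config.n_subjects)
    width = max(3, len(str(config.n_subjects)))
    ids = [f"S{i + 1:0{width}d}" for i in range(config.n_subjects)]
    return pd.DataFrame({"subject_id": ids, "age": draws[:, 0], "hba1c": draws[:, 1]})


def generate_true_expression(phenotypes: pd.DataFrame,
                             config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Simulate the true (batch-free) expression matrix for a phenotype table.

    Gene g of subject s is ``baseline_g + a_g*age_s + h_g*hba1c_s + eps``
    with ``eps ~ N(0, sigma_g^2)``; the slopes are zero except for the
    signal genes. The returned samples x genes DataFrame carries the planted
    truth in ``.attrs``: ``age_effects``, ``hba1c_effects`` (Series over
    genes) and ``signal_gene`` (the gene with both effects).
    """
    if config is None:
        config = SyntheticConfig()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed,
                                                       spawn_key=(1,)))
    n = len(phenotypes)
    g = config.n_genes
    width = max(4, len(str(g)))
    genes = [f"G{i + 1:0{width}d}" for i in range(g)]

    sds = rng.lognormal(mean=np.log(config.median_gene_sd),
                        sigma=config.gene_sd_log_sigma, size=g)
    sds *= config.median_gene_sd / np.median(sds)  # pin the realized median exactly

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=g)
    age_eff = np.zeros(g)
    hba1c_eff = np.zeros(g)
    n_signal = config.effective_n_signal_genes
    signal_gene = None
    if n_signal > 0:
        signal_idx = rng.choice(g, size=n_signal, replace=False)
        signal_idx.sort()
        both = signal_idx[0]
        half = (n_signal - 1) // 2
        age_only = signal_idx[1 : 1 + half]
        hba1c_only = signal_idx[1 + half :]
        age_eff[age_only] = config.age_effect
        hba1c_eff[hba1c_only] = config.hba1c_effect
        age_eff[both] = config.age_effect
        hba1c_eff[both] = config.hba1c_effect
        # The designated gene gets a typical (median) noise SD so its
        # association with both covariates is unambiguous, mirroring how a
        # clearly covariate-associated transcript is picked from real data.
        sds[both] = config.median_gene_sd
        signal_gene = genes[both]

    age = phenotypes["age"].to_numpy()
    hba1c = phenotypes["hba1c"].to_numpy()
    mean = baseline[None, :] + np.outer(age, age_eff) + np.outer(hba1c, hba1c_eff)
    values = mean + rng.normal(0.0, 1.0, size=(n, g)) * sds[None, :]

    out = pd.DataFrame(values, index=pd.Index(phenotypes["subject_id"], name="subject_id"),
                       columns=genes)
    out.attrs["age_effects"] = pd.Series(age_eff, index=genes)
    out.attrs["hba1c_effects"] = pd.Series(hba1c_eff, index=genes)
    out.attrs["gene_sds"] = pd.Series(sds, index=genes)
    out.attrs["signal_gene"] = signal_gene
    return out


def make_demo_dataset(seed: int = 0, config: SyntheticConfig | None = None,
                      selection: SelectionParams | None = None
                      ) -> tuple[Cohort, pd.DataFrame]:
    """Phenotypes -> cohort selection -> true expression for the cohort.

    The standard fixture: 65 synthetic subjects reduced to a 30/30
    case-control cohort (under the default selection parameters) with its
    true expression matrix. ``.attrs`` of the matrix carry the planted
    signal structure.
    """
    if config is None:
        config = SyntheticConfig(seed=seed)
    else:
        config = replace(config, seed=seed)
    phenotypes = generate_phenotypes(config)
    cohort = select_cohort(phenotypes, selection)
    expr = generate_true_expression(phenotypes, config)
    attrs = expr.attrs
    expr = expr.loc[sorted(cohort.subject_ids)]
    expr.attrs.update(attrs)
    return cohort, expr
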