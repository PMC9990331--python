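"""Construction of a confounded case-control cohort from phenotype records.

A logistic selection-probability model turns a table of subjects with two
continuous covariates (age in years, HbA1c in percent) into a case-control
study in which both covariates are deliberately imbalanced between groups:
subjects are ranked by their fitted probability of selection, the extreme
top of the ranking is discarded, and within the retained set the
lowest-probability subjects (younger, lower HbA1c) become cases. The whole
procedure is deterministic, so a given phenotype table always yields the
same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "DegenerateInputError",
    "SelectionParams",
    "Cohort",
    "zscore",
    "selection_probability",
    "select_cohort",
]

CASE = "case"
CONTROL = "control"


class DegenerateInputError(ValueError):
    """Raised when an input admits no meaningful answer (e.g. zero variance)."""


@dataclass(frozen=True)
class SelectionParams:
    """Parameters of the logistic selection-probability model.

    ``intercept`` is on the log-odds scale; ``or_age`` and ``or_hba1c`` are
    odds ratios per one standard deviation of the covariate. ``n_drop_top``
    highest-probability subjects are discarded before ``n_select`` subjects
    are retained, of whom the ``n_cases`` with the lowest probability become
    cases. Because selection operates on ranks, the intercept has no effect
    on which subjects are chosen, only on the probability values themselves.
    """

    intercept: float = 2.5
    or_age: float = 1.5
    or_hba1c: float = 1.5
    n_drop_top: int = 5
    n_select: int = 60
    n_cases: int = 30

    def __post_init__(self) -> None:
        if not (self.or_age > 0 and self.or_hba1c > 0):
            raise ValueError("odds ratios must be positive")
        if self.n_cases > self.n_select:
            raise ValueError("n_cases cannot exceed n_select")
        if self.n_drop_top < 0 or self.n_select <= 0:
            raise ValueError("counts must be non-negative (n_select positive)")


@dataclass
class Cohort:
    """A selected case-control cohort.

    ``frame`` is indexed by subject id (ascending) with columns ``age``,
    ``hba1c``, ``group`` (``"case"``/``"control"``) and ``selection_prob``.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"age", "hba1c", "group", "selection_prob"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"cohort frame missing columns: {sorted(missing)}")
        if not self.frame.index.is_unique:
            raise ValueError("duplicate subject ids in cohort")
        probs = self.frame["selection_prob"].to_numpy()
        if not ((probs > 0) & (probs < 1)).all():
            raise ValueError("selection probabilities must lie strictly in (0, 1)")

    @property
    def subject_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def cases(self) -> pd.Index:
        return self.frame.index[self.frame["group"] == CASE]

    @property
    def controls(self) -> pd.Index:
        return self.frame.index[self.frame["group"] == CONTROL]

    @property
    def n(self) -> int:
        return len(self.frame)

    def covariates(self) -> pd.DataFrame:
        """Age and HbA1c, indexed like the cohort."""
        return self.frame[["age", "hba1c"]]

    def stratum(self, group: str) -> pd.DataFrame:
        """Covariates of one stratum (``"case"`` or ``"control"``)."""
        if group not in (CASE, CONTROL):
            raise ValueError(f"unknown group {group!r}")
        return self.frame.loc[self.frame["group"] == group, ["age", "hba1c"]]

    def to_frame(self) -> pd.DataFrame:
        """Copy of the cohort table with ``subject_id`` as a column."""
        out = self.frame.copy()
        out.index.name = "subject_id"
        return out.reset_index()


def zscore(values) -> np.ndarray:
    """Standardize to mean 0 and sample SD 1 (``ddof=1``).

    Raises :class:`DegenerateInputError` if the sample SD is zero.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("zscore expects a 1-d vector")
    if x.size < 2:
        raise ValueError("zscore needs at least two values")
    if not np.all(np.isfinite(x)):
        raise ValueError("zscore requires finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero-variance input has no z-scores")
    return (x - x.mean()) / sd


def selection_probability(z_age, z_hba1c, params: SelectionParams | None = None):
    """Fitted selection probability expit(b0 + ln(OR_age)*z_age + ln(OR_hba1c)*z_hba1c).

    Vectorized over the z-score arguments; strictly within (0, 1) and
    monotone increasing in each z-score whose odds ratio exceeds 1.
    """
    if params is None:
        params = SelectionParams()
    z_age = np.asarray(z_age, dtype=float)
    z_hba1c = np.asarray(z_hba1c, dtype=float)
    if not (np.all(np.isfinite(z_age)) and np.all(np.isfinite(z_hba1c))):
        raise ValueError("z-scores must be finite")
    eta = params.intercept + np.log(params.or_age) * z_age + np.log(params.or_hba1c) * z_hba1c
    return expit(eta)


def _validate_phenotypes(phenotypes: pd.DataFrame) -> pd.DataFrame:
    required = {"subject_id", "age", "hba1c"}
    missing = required - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    tab = phenotypes[["subject_id", "age", "hba1c"]].copy()
    if tab["subject_id"].duplicated().any():
        dupes = tab.loc[tab["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    vals = tab[["age", "hba1c"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("phenotypes must be complete cases with finite age and hba1c")
    return tab


def select_cohort(phenotypes: pd.DataFrame, params: SelectionParams | None = None) -> Cohort:
    """Select a confounded case-control cohort from a complete-case phenotype table.

    Age and HbA1c are z-scored over the table, each subject gets a logistic
    selection probability, subjects are ranked by descending probability,
    the top ``n_drop_top`` ranks are discarded (avoiding covariate outliers),
    the next ``n_select`` subjects form the cohort, and the ``n_cases`` of
    them with the lowest probability become cases. Probability ties break by
    ascending subject id. Deterministic: no randomness anywhere.
    """
    if params is None:
        params = SelectionParams()
    tab = _validate_phenotypes(phenotypes)
    if len(tab) < params.n_drop_top + params.n_select:
        raise ValueError(
            f"need at least {params.n_drop_top + params.n_select} complete records, "
            f"got {len(tab)}"
        )

    z_age = zscore(tab["age"].to_numpy())
    z_hba1c = zscore(tab["hba1c"].to_numpy())
    tab = tab.assign(selection_prob=selection_probability(z_age, z_hba1c, params))

    # Rank 1..N by descending probability, ties by ascending subject_id.
    ranked = tab.sort_values(["selection_prob", "subject_id"], ascending=[False, True])
    kept = ranked.iloc[params.n_drop_top : params.n_drop_top + params.n_select]

    by_prob = kept.sort_values(["selection_prob", "subject_id"], ascending=[True, True])
    case_ids = set(by_prob["subject_id"].iloc[: params.n_cases])

    frame = kept.set_index("subject_id").sort_index()
    frame["group"] = [CASE if sid in case_ids else CONTROL for sid in frame.index]
    return Cohort(frame=frame[["age", "hba1c", "group", "selection_prob"]])
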