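import numpy as np
import pandas as pd
import pytest

from psbatch.cohort import SelectionParams
from psbatch.synthetic import SyntheticConfig, make_demo_dataset


@pytest.fixture(scope="session")
def cohort36():
    """36-subject (18/18) cohort with a 500-gene true matrix, 3-batch scale."""
    selection = SelectionParams(n_drop_top=2, n_select=36, n_cases=18)
    cohort, expr = make_demo_dataset(
        seed=3, config=SyntheticConfig(n_subjects=40, n_genes=500), selection=selection
    )
    return cohort, expr


@pytest.fixture(scope="session")
def cohort12():
    """12-subject (6/6) cohort for exhaustive-enumeration cross-checks (2 batches)."""
    selection = SelectionParams(n_drop_top=1, n_select=12, n_cases=6)
    cohort, expr = make_demo_dataset(
        seed=5, config=SyntheticConfig(n_subjects=16, n_genes=40), selection=selection
    )
    return cohort, expr


@pytest.fixture()
def toy_phenotypes():
    rng = np.random.default_rng(2024)
    n = 20
    return pd.DataFrame(
        {
            "subject_id": [f"P{i:02d}" for i in range(n)],
            "age": rng.normal(55, 10, n),
            "hba1c": rng.normal(5.5, 0.4, n),
        }
    )
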