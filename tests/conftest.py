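import numpy as np
import pandas as pd
import pytest

from avrecal import synthetic as syn


@pytest.fixture(scope="session")
def behavioral_cohort() -> pd.DataFrame:
    """Pooled trial table of a mid-sized cohort (behavior only, no epochs)."""
    params = syn.GenParams(n_subjects=12, n_per_discrepancy=12, n_v_trials=8, seed=101)
    return syn.cohort_trials(syn.generate_cohort(params, include_epochs=False))


@pytest.fixture(scope="session")
def neural_params() -> syn.GenParams:
    return syn.GenParams(
        n_subjects=1, n_per_discrepancy=12, n_v_trials=0, grid_shape=(6, 6, 6), snr=1.0, seed=33
    )


@pytest.fixture(scope="session")
def neural_subject(neural_params) -> syn.SubjectDataset:
    """One subject with source epochs on a 6^3 grid."""
    return syn.generate_cohort(neural_params)[0]


@pytest.fixture()
def tiny_trials() -> pd.DataFrame:
    """Hand-written four-pair trial table (one subject) for arithmetic checks."""
    rows = [
        # trial, type, A_loc, V_loc, response, pair_id
        (0, "AV", 0.0, -17.0, -4.0, 0),
        (1, "A", -17.0, np.nan, -15.0, 0),
        (2, "AV", 8.5, 8.5, 8.0, 2),
        (3, "A", 8.5, np.nan, 9.0, 2),
        (4, "AV", 0.0, 17.0, 5.0, 4),
        (5, "A", 17.0, np.nan, 16.0, 4),
        (6, "AV", -8.5, 8.5, -3.0, 6),
        (7, "A", -17.0, np.nan, -13.0, 6),
    ]
    table = pd.DataFrame(rows, columns=["trial", "type", "A_loc", "V_loc", "response", "pair_id"])
    table.insert(0, "subject", 0)
    return table
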