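import numpy as np
import pandas as pd
import pytest

from psyflex import (PopulationModel, compute_indices, preprocess,
                     simulate_study)


@pytest.fixture(scope="session")
def small_study():
    """40 simulated subjects under study defaults (shared across tests)."""
    model = PopulationModel(n_subjects=40, seed=11)
    log, params = simulate_study(model, seed=11, return_params=True)
    return log, params


@pytest.fixture(scope="session")
def small_pre(small_study):
    log, _ = small_study
    return preprocess(log)


@pytest.fixture(scope="session")
def small_indices(small_pre):
    return compute_indices(small_pre)


@pytest.fixture(scope="session")
def big_study():
    """2,000 noiseless-lapse subjects for recovery and calibration checks."""
    model = PopulationModel(n_subjects=2000, seed=29)
    log, params = simulate_study(model, seed=29, return_params=True)
    return log, params


def toy_log(rows):
    """Build a trial log from (subject, paradigm, condition, rule,
    correct_hand, response_hand, accuracy, rt) tuples."""
    df = pd.DataFrame(rows, columns=["subject", "paradigm", "condition",
                                     "rule", "correct_hand", "response_hand",
                                     "accuracy", "rt"])
    df["run"] = 0
    df["trial"] = np.arange(len(df))
    df["feedback"] = "none"
    return df[["subject", "paradigm", "run", "trial", "condition", "rule",
               "correct_hand", "response_hand", "accuracy", "rt", "feedback"]]
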