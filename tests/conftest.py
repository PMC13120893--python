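"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from dynconn import (
    SimulationConfig,
    WindowEstimatorConfig,
    build_taper,
    compute_dynamic_connectome,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six-subject Markov-switching cohort (P=10, T=400)."""
    cfg = SimulationConfig(n_subjects=6, n_nodes=10, n_timepoints=400, seed=2)
    subjects, truth = simulate_cohort(cfg)
    return cfg, subjects, truth


@pytest.fixture(scope="session")
def tiny_connectomes(tiny_cohort):
    """Windowed glasso stacks for the tiny cohort (step 8 for speed)."""
    cfg, subjects, truth = tiny_cohort
    taper = build_taper(70, 3.0)
    est = WindowEstimatorConfig(step=8)
    dcs = [compute_dynamic_connectome(s, taper, est) for s in subjects]
    return cfg, dcs, truth


@pytest.fixture()
def cohort_table():
    return pd.DataFrame(
        {
            "subject_id": ["s1", "s2", "s3", "s4", "s5"],
            "bmi": [22.0, np.nan, 31.2, 27.5, np.nan],
            "age": [25, 30, 35, 28, 24],
            "gender": ["male", "female", "female", "male", "female"],
            "mean_fd": [0.10, 0.12, 0.30, 0.08, 0.05],
        }
    )
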