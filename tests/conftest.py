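import logging

import numpy as np
import pandas as pd
import pytest

from setsim.config import CohortConfig
from setsim.synthetic_data import generate_cohort, impose_missingness

logging.getLogger("setsim").setLevel(logging.INFO)


@pytest.fixture(scope="session")
def default_cohort():
    """The calibrated default pool: 23 studies, 261 subjects, 409 sessions."""
    return generate_cohort(CohortConfig(seed=123))


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort with missingness limited to a few instruments."""
    return CohortConfig(
        n_studies=8,
        n_subjects=120,
        n_sessions=220,
        instrument_missing_rates={"tas": 0.3, "zkpq": 0.4, "ewl": 0.35, "pasi": 0.2, "fpi": 0.25},
        seed=42,
    )


@pytest.fixture(scope="session")
def small_complete(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_missing(small_config, small_complete):
    return impose_missingness(small_complete, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def clustered_frame(rng, n_subj=150, spp=2, beta=(0.3, 0.6, 0.0, 0.25), tau=0.5, sigma=0.8):
    """A completed random-intercept model frame with known coefficients."""
    n = n_subj * spp
    groups = np.repeat(np.arange(n_subj), spp)
    X = rng.standard_normal((n, len(beta) - 1))
    b = rng.normal(0.0, tau, n_subj)
    y = beta[0] + X @ np.asarray(beta[1:]) + b[groups] + rng.normal(0.0, sigma, n)
    df = pd.DataFrame(X, columns=[f"x{i+1}" for i in range(X.shape[1])])
    df["y"] = y
    df["subject_id"] = groups
    return df


@pytest.fixture()
def lmm_frame(rng):
    return clustered_frame(rng)
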