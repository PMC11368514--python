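import dataclasses

import numpy as np
import pandas as pd
import pytest

from airwayhet import (
    SimulationConfig,
    fit_reference_models,
    generate_cohort,
    generate_normative_sample,
)
from airwayhet.pipeline import _summaries_with_covariates, analysis_view
from airwayhet.sites import AIRWAY_SITES


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(n_subjects=400, n_normative=300)


@pytest.fixture(scope="session")
def normative_sample(small_cfg):
    return generate_normative_sample(small_cfg, rng=12345)


@pytest.fixture(scope="session")
def models(normative_sample):
    return fit_reference_models(normative_sample)


@pytest.fixture(scope="session")
def cohort(small_cfg, models):
    return generate_cohort(small_cfg, models, rng=99)


@pytest.fixture(scope="session")
def analysis_table(cohort, models):
    return _summaries_with_covariates(analysis_view(cohort.subjects), models)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_linear_truth_normative(n: int = 120, seed: int = 7) -> pd.DataFrame:
    """Noiseless normative sample with diameter = 5 + 0.8 * tlv everywhere."""
    cfg = SimulationConfig(n_normative=n, diam_noise_sd=0.0)
    df = generate_normative_sample(cfg, rng=seed)
    for site in AIRWAY_SITES:
        df[site] = 5.0 + 0.8 * df["tlv"]
    return df


@pytest.fixture(scope="session")
def linear_truth_models():
    norm = make_linear_truth_normative()
    return fit_reference_models(norm, min_cell_n=25), norm


def replace_cfg(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
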