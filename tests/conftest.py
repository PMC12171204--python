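"""Shared fixtures: the synthetic cohort and its feature table are expensive
(EMD per window), so they are built once per session and reused."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from bioharkit import evaluation, pipeline
from bioharkit.config import synthetic_pipeline_config
from bioharkit.synthetic_fixtures import SyntheticConfig, generate_dataset

COHORT_SEED = 7


@pytest.fixture(scope="session")
def synthetic_cfg():
    return synthetic_pipeline_config()


@pytest.fixture(scope="session")
def synthetic_recordings():
    return generate_dataset(SyntheticConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def synthetic_features(synthetic_recordings, synthetic_cfg):
    """(X, y, subjects, names) for the default 10-subject, 6-class cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.features_from_recordings(synthetic_recordings, synthetic_cfg)


@pytest.fixture(scope="session")
def cv_report(synthetic_features, synthetic_cfg):
    """Subject-wise 5-fold cross-validation of the full pipeline."""
    X, y, subjects, _ = synthetic_features
    return evaluation.cross_validate(
        X,
        y,
        subjects,
        config={"lda": synthetic_cfg["lda"], "classifier": synthetic_cfg["classifier"]},
        k=5,
        seed=COHORT_SEED,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
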