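import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from astpredict import (
    CANDIDATES_NO_ACTH,
    development_config,
    generate_cohort,
    prepare_analysis_frame,
    published_models,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def models():
    return published_models()


@pytest.fixture(scope="session")
def dev_cohort():
    """A development-like synthetic cohort (258 pairs, default noise)."""
    return generate_cohort(development_config(seed=42))


@pytest.fixture(scope="session")
def dev_frame(dev_cohort):
    return prepare_analysis_frame(dev_cohort)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Zero-noise cohort: the outcome is exactly the generating linear predictor."""
    cfg = development_config(seed=5).with_overrides(
        outcome_noise_sd=0.0, acth_missing_rate=0.0
    )
    return generate_cohort(cfg)


@pytest.fixture(autouse=True)
def _quiet_small_sample_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="only .* rows for .* candidates")
        yield
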