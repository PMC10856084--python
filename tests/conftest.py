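import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spequant as sq

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_factors():
    return sq.example_factor_definitions()


@pytest.fixture(scope="session")
def study_plan():
    return sq.example_screening_plan()


@pytest.fixture()
def noise_free_config():
    cfg = sq.GeneratorConfig(seed=42)
    for model in cfg.screening.values():
        model.noise_sd = 0.0
    for model in cfg.calibration.values():
        model.cv_pct = 0.0
    for model in cfg.sets.values():
        model.cv_pct = 0.0
    cfg.batch.cv_pct = 0.0
    return cfg


@pytest.fixture()
def iphosphamide_curve():
    """Study-like calibration line with populated detection limits."""
    return sq.CalibrationCurve(
        analyte="iphosphamide",
        slope=0.019,
        intercept=0.055,
        r_squared=0.996,
        sd_intercept=0.016523,
        residual_sd=0.018,
        n_points=6,
        lod=2.87,
        loq=8.6,
    )
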