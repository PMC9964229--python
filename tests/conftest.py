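import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from climflav.assay import CalibrationCurve, ExtractionSpec  # noqa: E402
from climflav.synthetic import gen_climate  # noqa: E402


@pytest.fixture(scope="session")
def rutin_curve() -> CalibrationCurve:
    """The rutin standard curve used throughout (OD = 10.655 c - 0.0076)."""
    return CalibrationCurve(slope=10.655, intercept=-0.0076, r_squared=0.99869)


@pytest.fixture(scope="session")
def extraction() -> ExtractionSpec:
    """1 g sample, 50 mL extract, 10/2 aliquot basis, 10x dilution."""
    return ExtractionSpec(sample_mass_g=1.0, extract_volume_ml=50.0,
                          aliquot_factor=5.0, dilution_factor=10.0)


@pytest.fixture(scope="session")
def nine_sites():
    return gen_climate(9, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
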