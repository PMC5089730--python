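import pytest

from ssbsim import (
    SyntheticConfig,
    calibrate,
    generate_model_inputs,
)


@pytest.fixture(scope="session")
def small_bundle():
    """Synthetic bundle at 1/1000 population scale (rates preserved)."""
    return generate_model_inputs(SyntheticConfig(seed=42, population_scale=0.001))


@pytest.fixture(scope="session")
def calibrated_bundle(small_bundle):
    b = small_bundle.copy()
    b.risks = calibrate(b.baseline, b.risks, b.targets, b.demography)
    return b
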