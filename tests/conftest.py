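import numpy as np
import pytest

from cushingsr import ExtendedParams, HarmonicCycle, SyntheticConfig


@pytest.fixture
def study_truth() -> ExtendedParams:
    """Generating parameters at the scale of the published headline fit."""
    return ExtendedParams(a=264.299, gamma0=0.999, gamma1=-0.615, sigma=50.65)


@pytest.fixture
def study_config(study_truth) -> SyntheticConfig:
    """Default 37-year study-scale synthetic configuration."""
    return SyntheticConfig(seed=20230127, true_params=study_truth)


@pytest.fixture
def cycle26() -> HarmonicCycle:
    return HarmonicCycle(period=26.0, amplitude=0.2, phase=1995.5, offset=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
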