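import numpy as np
import pytest

from spheromech.synthetic import FusionSimConfig, IndentSimConfig, simulate_indentation_curve

#: fixed master seed for every stochastic calibration test in the suite
MASTER_SEED = 20260928


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)


@pytest.fixture
def noiseless_fusion_config():
    return FusionSimConfig(tau=10.0, radius_a=100.0, radius_b=100.0, noise_cv=0.0)


@pytest.fixture
def plr_curve():
    """Noiseless indentation cycle of a soft PLR sample (experimental-protocol shape)."""
    return simulate_indentation_curve(IndentSimConfig(E1=3940.0, alpha=0.17))


@pytest.fixture
def elastic_curve():
    """Noiseless purely elastic (alpha = 0) indentation cycle."""
    return simulate_indentation_curve(IndentSimConfig(E1=3920.0, alpha=0.0))
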