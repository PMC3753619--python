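import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def duplex_params():
    """Benchmark duplex thermodynamics (kJ/mol, J/K/mol, 6 µM total)."""
    from quadmelt import ThermoParams

    return ThermoParams(-336.4, -902.0, "bimolecular_hetero", 6e-6)


@pytest.fixture
def sloped_spec(duplex_params):
    """Noise-free single heating ramp with gently sloping baselines."""
    from quadmelt import SimSpec

    return SimSpec(
        params=duplex_params,
        ramp_pattern=("heating",),
        lower_baseline=(0.0005, 0.30),
        upper_baseline=(0.0003, 0.45),
    )
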