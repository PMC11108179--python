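import numpy as np
import pytest

from phenox import etc_model, synthetic_data


@pytest.fixture(scope="session")
def t_grid():
    """Default plate-reader grid: 15-min cadence over 48 h."""
    return synthetic_data.default_t_grid()


@pytest.fixture(scope="session")
def fast_params():
    """Wild-type-like archetype: short lag, brisk biphasic decay."""
    return synthetic_data.CurveParams()


@pytest.fixture(scope="session")
def slow_params():
    """Impaired-strain archetype: long lag, slow decay."""
    return synthetic_data.CurveParams(
        lag_h=6.0, k_fast=0.12, k_slow=0.03, fast_weight=0.6)


@pytest.fixture(scope="session")
def recovery_design(fast_params, slow_params):
    """Two sample strains for the parameter-recovery harness."""
    return [
        synthetic_data.PlateEntry("fast", fast_params),
        synthetic_data.PlateEntry("slow", slow_params),
    ]


@pytest.fixture(scope="session")
def presets():
    return etc_model.preset_genotypes()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
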