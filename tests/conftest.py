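import numpy as np
import pytest

from radstab.synthetic import (
    HeterogeneityModel,
    default_phantom_spec,
    make_phantom,
    simulate_signal,
)

#: fixed lesion parameters used by the closed-form / round-trip fixtures
UNIFORM_PARAMS = {
    "S0": 200.0, "D": 1.0e-3, "Dstar": 10.0e-3, "f": 0.10,
    "MD": 1.2e-3, "MK": 0.8,
}


def small_spec(**overrides):
    """A fast 24x24x12 phantom spec for unit tests."""
    base = dict(
        grid_shape=(24, 24, 12),
        lesion_center=(12.0, 12.0, 6.0),
        lesion_radii=(5.0, 5.0, 2.5),
        seed=7,
    )
    base.update(overrides)
    return default_phantom_spec(**base)


@pytest.fixture(scope="session")
def uniform_ivim_truth():
    """Noiseless-texture IVIM phantom with exactly known lesion parameters."""
    spec = small_spec(
        signal_model="ivim",
        heterogeneity=HeterogeneityModel(amplitude=0.0),
        lesion_params=dict(UNIFORM_PARAMS),
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def uniform_ivim_series(uniform_ivim_truth):
    return simulate_signal(uniform_ivim_truth)


@pytest.fixture(scope="session")
def uniform_dki_truth():
    spec = small_spec(
        signal_model="dki",
        heterogeneity=HeterogeneityModel(amplitude=0.0),
        lesion_params=dict(UNIFORM_PARAMS),
    )
    return make_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
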