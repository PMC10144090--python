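import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blink_small():
    """A desk-scale blink dataset (ranks are scale-invariant)."""
    import warnings

    from dynshape import BlinkConfig, TimeGrid, assemble_dataset, simulate_blink

    trajs = simulate_blink(BlinkConfig(n_per_group=120, T=31, seed=7))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return assemble_dataset(trajs, TimeGrid(31))


@pytest.fixture
def sine_small():
    from dynshape import SineWaveConfig, TimeGrid, assemble_dataset, simulate_sine

    trajs = simulate_sine(SineWaveConfig(n_per_group=200, seed=3))
    return assemble_dataset(trajs, TimeGrid(101))
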