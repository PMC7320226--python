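import dataclasses

import numpy as np
import pytest

from nirhsi import PhantomConfig, WavelengthGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid168():
    return WavelengthGrid.linspace(900.0, 1700.0, 168)


@pytest.fixture
def small_grid():
    return WavelengthGrid(np.array([1000.0, 1100.0, 1200.0, 1300.0, 1400.0]))


@pytest.fixture
def small_phantom_config():
    """A scaled-down phantom for fast spatial tests."""
    return PhantomConfig(rows=48, cols=48, n_lesions=(1, 2), lesion_axes=(4.0, 8.0))


@pytest.fixture
def noiseless_small_config(small_phantom_config):
    return small_phantom_config.noiseless()


def make_noiseless_scene(seed=0, rows=48, cols=48):
    from nirhsi import simulate_scene

    config = PhantomConfig(
        rows=rows, cols=cols, n_lesions=(1, 2), lesion_axes=(4.0, 8.0), seed=seed
    ).noiseless()
    return simulate_scene(config)


@pytest.fixture
def noiseless_scene():
    return make_noiseless_scene()
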