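import numpy as np
import pytest

from matirf import (
    AngleSet,
    GridSpec,
    OpticalConfig,
    build_excitation,
)


@pytest.fixture
def config():
    return OpticalConfig()  # 491 nm, glass/water, NA 1.49, 107 nm pixels


@pytest.fixture
def excitation(config):
    """Four supercritical angles spanning the accessible range."""
    return build_excitation(config, AngleSet((63.0, 68.0, 73.0, 78.0)))


@pytest.fixture
def excitation10(config):
    from matirf import default_angle_set

    return build_excitation(config, default_angle_set(config, 10))


@pytest.fixture
def small_grid():
    return GridSpec(nx=4, ny=4, nz=3, dz_nm=20.0, pixel_size_nm=100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
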