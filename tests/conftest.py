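import numpy as np
import pytest

from usdenoise import NoiseSpec, PhantomSpec, add_noise, generate_phantom
from usdenoise.experiments import benchmark_grids, desk_scale_training

DESK_SEED = 7


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def speckle_sample(phantom):
    return add_noise(phantom, NoiseSpec(sigma=1.0, seed=5))


@pytest.fixture(scope="session")
def gaussian_sample(phantom):
    return add_noise(phantom, NoiseSpec(model="additive_gaussian",
                                        sigma=1.0, seed=5))


@pytest.fixture(scope="session")
def desk_run():
    """The pinned desk-scale training run (shared across the suite: this
    is the expensive fixture, several minutes on one CPU)."""
    return desk_scale_training(seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_grids(desk_run):
    """Benchmark PSNR/SSIM grids computed from the pinned run."""
    return benchmark_grids(desk_run)


def rng(seed=0):
    return np.random.default_rng(seed)
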