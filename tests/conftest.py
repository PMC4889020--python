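import numpy as np
import pytest

from foci3d.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_discrete_phantom():
    """A small, fast discrete-mode phantom shared across tests (seed 11)."""
    cfg = PhantomConfig(shape=(64, 96, 96), focus_density=10.0,
                        focus_volume_range=(1.6e4, 3e5), seed=11)
    gray, labels, truth = generate_phantom(cfg)
    return cfg, gray, labels, truth


@pytest.fixture(scope="session")
def small_reticulum_phantom():
    """A small reticulum-mode phantom with one extra loop (seed 4)."""
    cfg = PhantomConfig(shape=(64, 96, 96), focus_density=10.0,
                        focus_volume_range=(1.6e4, 2e5),
                        topology_mode="reticulum", n_extra_edges=1, seed=4)
    gray, labels, truth = generate_phantom(cfg)
    return cfg, gray, labels, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
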