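import numpy as np
import pytest

from neholo import ArrayGeometry, MediumModel


@pytest.fixture
def geometry() -> ArrayGeometry:
    """The standard 10 x 10, 0.4 mm-pitch array."""
    return ArrayGeometry(10, 10, 0.4)


@pytest.fixture
def medium() -> MediumModel:
    return MediumModel.uniform(sigma=0.3, eps_rel=1.0e5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def lattice_mode(geometry, i: int, j: int, amplitude: complex = 1.0) -> np.ndarray:
    """Complex exponential exactly on lattice node (kx[i], ky[j])."""
    from neholo import build_frequency_lattice

    kx, ky = build_frequency_lattice(geometry)
    x = geometry.node_x()[None, :]
    y = geometry.node_y()[:, None]
    return amplitude * np.exp(1j * (kx[i] * x + ky[j] * y))
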