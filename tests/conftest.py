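import numpy as np
import pytest

from polseg import MuellerImage, PhantomSpec, generate


def rotator(phi: float) -> np.ndarray:
    """Mueller matrix of a coordinate rotation by phi."""
    c, s = np.cos(2 * phi), np.sin(2 * phi)
    return np.array([[1, 0, 0, 0],
                     [0, c, -s, 0],
                     [0, s, c, 0],
                     [0, 0, 0, 1.0]])


def linear_retarder(delta: float, phi: float = 0.0) -> np.ndarray:
    """Mueller matrix of a linear retarder (retardance delta, fast axis phi)."""
    c, s = np.cos(delta), np.sin(delta)
    m = np.array([[1, 0, 0, 0],
                  [0, 1, 0, 0],
                  [0, 0, c, -s],
                  [0, 0, s, c]])
    return rotator(phi) @ m @ rotator(-phi)


def diattenuator(q: float, phi: float = 0.0) -> np.ndarray:
    """Horizontal partial polarizer with transmittances 1 and q, rotated."""
    a = (1 + q) / 2
    b = (1 - q) / 2
    c = np.sqrt(q)
    m = np.array([[a, b, 0, 0],
                  [b, a, 0, 0],
                  [0, 0, c, 0],
                  [0, 0, 0, c]])
    return rotator(phi) @ m @ rotator(-phi)


def depolarizer(a: float, b: float | None = None, c: float | None = None) -> np.ndarray:
    return np.diag([1.0, a, a if b is None else b, a if c is None else c])


def random_physical_mueller(rng: np.random.Generator) -> np.ndarray:
    """Random product of depolarizer, retarder and diattenuator factors."""
    m = depolarizer(*rng.uniform(0.1, 0.95, size=3))
    m = m @ linear_retarder(rng.uniform(0, np.pi), rng.uniform(0, np.pi))
    m = m @ diattenuator(rng.uniform(0.3, 1.0), rng.uniform(0, np.pi))
    return m


def uniform_mueller_image(matrix: np.ndarray, shape=(3, 4)) -> MuellerImage:
    return MuellerImage(np.broadcast_to(matrix, shape + (4, 4)).copy())


@pytest.fixture(scope="session")
def default_phantom():
    """The default 256x256 three-zone phantom, seed 42."""
    return generate(PhantomSpec())


@pytest.fixture(scope="session")
def default_fuzzy_labels(default_phantom):
    from polseg import segment_local_fuzzy
    return segment_local_fuzzy(default_phantom.delta)
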