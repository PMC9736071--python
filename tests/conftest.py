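import numpy as np
import pytest

from tapspath.geometry import Conformation
from tapspath.pcv import Path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def straight_path_1d():
    """Straight, equally spaced 1D path with nodes at 0..5 (N=6)."""
    return Path([Conformation.from_vector([float(i)]) for i in range(6)])


def make_straight_path(n, dim=1, spacing=1.0):
    nodes = []
    for i in range(n):
        v = np.zeros(dim)
        v[0] = i * spacing
        nodes.append(Conformation.from_vector(v))
    return Path(nodes)
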