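import numpy as np
import pytest

from hnpmd.forcefield import ChainState, ForceField
from hnpmd.sequence import build_sequence, initial_configuration


@pytest.fixture(scope="session")
def ff():
    return ForceField()


@pytest.fixture(scope="session")
def seq20():
    return build_sequence("H3N1P1", 20)


@pytest.fixture(scope="session")
def seq50():
    return build_sequence("H3N1P1", 50)


@pytest.fixture
def random_state20(seq20):
    """A random coil state of 20 beads (deterministic)."""
    return initial_configuration(seq20, seed=11)


def zigzag_positions(n, l0=0.153, theta0=1.231):
    """Planar all-trans zigzag with bond length l0 and deflection angle
    theta0 between consecutive bond vectors (every dihedral exactly trans)."""
    half = theta0 / 2.0
    step = np.array([np.cos(half), np.sin(half), 0.0]) * l0
    pos = np.zeros((n, 3))
    for i in range(1, n):
        s = step.copy()
        s[1] *= (-1.0) ** (i - 1)
        pos[i] = pos[i - 1] + s
    return pos


def make_state(positions, sequence, mass=110.0):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return ChainState(positions, np.zeros((n, 3)), np.full(n, mass), sequence)


@pytest.fixture
def zigzag_state20(seq20):
    return make_state(zigzag_positions(20), seq20)
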