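import numpy as np
import pytest

from fibrocell.adhesions import FAParams
from fibrocell.lattice import CPMParams
from fibrocell.network import FiberNetwork, NetworkParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fa_params():
    return FAParams()


@pytest.fixture
def cpm_params():
    return CPMParams()


@pytest.fixture
def toy_cpm_params():
    """Unit coefficients, no substrate adhesion: energy counts are integers."""
    return CPMParams(lambda_area=1.0, j=1.0, lambda_c=0.0, t=50.0)


def make_network(positions, bonds=(), angles=(), clamped=None, fiber_id=None,
                 k=31.0, rest=0.4, kbend=3.88, theta0=np.pi, domain=(50.0, 50.0)):
    """Hand-built network helper for mechanics tests."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    bonds = list(bonds)
    bi = np.array([b[0] for b in bonds], dtype=int)
    bj = np.array([b[1] for b in bonds], dtype=int)
    bk = np.array([b[2] if len(b) > 2 else k for b in bonds], dtype=float)
    br = np.array([b[3] if len(b) > 3 else rest for b in bonds], dtype=float)
    angles = list(angles)
    ai = np.array([a[0] for a in angles], dtype=int)
    aj = np.array([a[1] for a in angles], dtype=int)
    ak = np.array([a[2] for a in angles], dtype=int)
    return FiberNetwork(
        positions=positions, bond_i=bi, bond_j=bj, bond_k=bk, bond_rest=br,
        is_crosslink=np.zeros(len(bi), dtype=bool),
        angle_i=ai, angle_j=aj, angle_k=ak,
        angle_kbend=np.full(len(ai), kbend),
        angle_theta0=np.full(len(ai), theta0),
        clamped=(np.zeros(n, dtype=bool) if clamped is None
                 else np.asarray(clamped, dtype=bool)),
        fiber_id=(np.zeros(n, dtype=int) if fiber_id is None
                  else np.asarray(fiber_id, dtype=int)),
        domain=domain)


@pytest.fixture
def make_net():
    return make_network


@pytest.fixture
def small_random_network(rng):
    """A perturbed random gel with nonzero forces, for gradient oracles."""
    from fibrocell.network import generate_random_network
    params = NetworkParams(domain=(8.0, 8.0), crosslink_density=1.0, n_beads=5)
    net = generate_random_network(params, rng)
    net.positions = net.positions + rng.normal(0.0, 0.05, net.positions.shape)
    return net
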