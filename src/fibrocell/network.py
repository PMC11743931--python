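"""Cross-linked bead-spring fiber networks.

A fiber is a straight chain of beads joined by harmonic springs; consecutive
bead triples carry a harmonic angle potential that penalizes bending, so
unforced fibers stay straight.  Cross-links are short, stiff springs joining
beads that belong to two different fibers; their areal density controls
network connectivity and, through it, long-range force transmission
(percolation).

Three constructors are provided:

* :func:`generate_random_network` -- fibers dropped uniformly in the domain
  with von Mises orientations (kappa = 0 gives an isotropic gel, large kappa
  an aligned one), cross-linked by randomly accepting close bead pairs.
* :func:`generate_grid_network` -- axis-aligned spanning strands cross-linked
  at every intersection; a regular, homogeneous reference substrate.
* :func:`sample_fiber` -- a single fiber, exposed for testing and custom
  network construction.

Beads whose initial position falls outside the rectangular domain are
clamped: they anchor the gel at the boundary and never move.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)


@dataclass
class NetworkParams:
    """Geometry and stiffness of a fiber network.

    Stiffnesses are in internal units (nN/um for springs, fJ/rad^2 for the
    bending rigidity), lengths in um.  Defaults describe the collagen-like
    gel used throughout: segment rest length 0.4 um, 31 beads per fiber
    (contour length 12 um, roughly one cell length), stretch stiffness
    equivalent to 3.1e-2 N/m and bending rigidity 3.88e-15 N m/rad^2.
    """

    domain: tuple[float, float] = (50.0, 50.0)   # [um]
    fiber_density: float = 0.48                  # fibers per um^2
    n_beads: int = 31
    r_polymer: float = 0.4                       # spring rest length [um]
    k_polymer: float = 31.0                      # stretch stiffness [nN/um]
    k_bend: float = 3.88                         # bending rigidity [fJ/rad^2]
    theta_0: float = np.pi                       # preferred interior angle [rad]
    k_cross: float | None = None                 # cross-link stiffness; None -> k_polymer
    crosslink_density: float = 1.2               # cross-links per um^2
    crosslink_rest_length: float = 0.1           # [um]
    capture_radius: float = 0.5                  # cross-link candidate radius [um]
    mu: float = 0.0                              # von Mises mean angle [rad]
    kappa: float = 0.0                           # von Mises concentration
    grid_spacing: float = 2.0                    # strand spacing for grid networks [um]

    def __post_init__(self) -> None:
        if self.n_beads < 3:
            raise ValueError("a fiber needs at least 3 beads")
        if min(self.r_polymer, self.k_polymer) <= 0 or self.k_bend < 0:
            raise ValueError("fiber stiffness/geometry must be positive")
        if self.kappa < 0 or self.crosslink_density < 0:
            raise ValueError("kappa and crosslink_density must be >= 0")
        if self.k_cross is None:
            self.k_cross = self.k_polymer

    @property
    def n_strands(self) -> int:
        """Fiber count implied by the areal density and the domain size."""
        return int(round(self.fiber_density * self.domain[0] * self.domain[1]))


@dataclass
class FiberNetwork:
    """Bead positions plus the spring/angle topology of a fiber gel.

    ``bond_*`` arrays hold both intra-fiber springs and cross-links;
    ``is_crosslink`` distinguishes them.  ``angle_*`` triples are consecutive
    beads of one fiber with the middle bead listed second.
    """

    positions: np.ndarray                 # (n, 2) float [um]
    bond_i: np.ndarray                    # (m,) int
    bond_j: np.ndarray
    bond_k: np.ndarray                    # (m,) float, stiffness [nN/um]
    bond_rest: np.ndarray                 # (m,) float [um]
    is_crosslink: np.ndarray              # (m,) bool
    angle_i: np.ndarray                   # (p,) int
    angle_j: np.ndarray                   # middle bead
    angle_k: np.ndarray
    angle_kbend: np.ndarray               # (p,) float [fJ/rad^2]
    angle_theta0: np.ndarray              # (p,) float [rad]
    clamped: np.ndarray                   # (n,) bool
    fiber_id: np.ndarray                  # (n,) int
    fa_bound: np.ndarray = field(default=None)  # (n,) bool, set by adhesion module
    domain: tuple[float, float] = (50.0, 50.0)

    def __post_init__(self) -> None:
        if self.fa_bound is None:
            self.fa_bound = np.zeros(self.n_beads, dtype=bool)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_bonds(self) -> int:
        return len(self.bond_i)

    @property
    def n_crosslinks(self) -> int:
        return int(self.is_crosslink.sum())

    def copy(self) -> "FiberNetwork":
        return replace(
            self,
            positions=self.positions.copy(),
            fa_bound=self.fa_bound.copy(),
            clamped=self.clamped.copy(),
        )

    def fiber_segments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Midpoints, orientations and lengths of intra-fiber segments.

        Returns (midpoints (s,2), angles (s,), lengths (s,)) for every
        non-cross-link bond; angles are in [0, pi) since segments are apolar.
        """
        sel = ~self.is_crosslink
        a = self.positions[self.bond_i[sel]]
        b = self.positions[self.bond_j[sel]]
        d = b - a
        lengths = np.hypot(d[:, 0], d[:, 1])
        angles = np.mod(np.arctan2(d[:, 1], d[:, 0]), np.pi)
        return (a + b) / 2.0, angles, lengths

    def validate(self) -> None:
        """Structural audit; raises AssertionError on an inconsistent state."""
        n = self.n_beads
        for arr in (self.bond_i, self.bond_j, self.angle_i, self.angle_j, self.angle_k):
            assert arr.min(initial=0) >= 0 and arr.max(initial=-1) < n
        # angle triples must be consecutive beads of one fiber
        fid = self.fiber_id
        assert np.all(fid[self.angle_i] == fid[self.angle_j])
        assert np.all(fid[self.angle_j] == fid[self.angle_k])
        assert np.all(self.angle_j - self.angle_i == 1)
        assert np.all(self.angle_k - self.angle_j == 1)
        # cross-links join distinct fibers
        xl = self.is_crosslink
        assert np.all(fid[self.bond_i[xl]] != fid[self.bond_j[xl]])
        assert not np.any(self.fa_bound & self.clamped)


def sample_fiber(rng: np.random.Generator, params: NetworkParams) -> np.ndarray:
    """Sample one straight fiber; returns its (n_beads, 2) bead positions.

    The middle bead (index floor(n_beads/2)) is uniform in the domain, the
    orientation is von Mises(mu, kappa), and bead ``i`` sits at
    ``middle + (i - k) * r_polymer * (cos t, sin t)``.  The middle bead is
    therefore always inside the domain while the endpoints may stick out.
    """
    lx, ly = params.domain
    mid = rng.uniform((0.0, 0.0), (lx, ly))
    theta = rng.vonmises(params.mu, params.kappa) if params.kappa > 0 else rng.uniform(0.0, 2 * np.pi)
    k = params.n_beads // 2
    offsets = (np.arange(params.n_beads) - k)[:, None] * params.r_polymer
    direction = np.array([np.cos(theta), np.sin(theta)])
    return mid[None, :] + offsets * direction[None, :]


def _chain_topology(n_fibers: int, n_beads: int, params: NetworkParams):
    """Bond and angle index arrays for ``n_fibers`` chains laid out contiguously."""
    empty = np.array([], dtype=np.int64)
    if n_fibers == 0:
        return empty, empty, empty, empty, empty
    base = np.arange(n_beads - 1)
    bi, bj, ai, aj, ak = [], [], [], [], []
    for f in range(n_fibers):
        off = f * n_beads
        bi.append(base + off)
        bj.append(base + 1 + off)
        tri = np.arange(n_beads - 2) + off
        ai.append(tri)
        aj.append(tri + 1)
        ak.append(tri + 2)
    bond_i = np.concatenate(bi)
    bond_j = np.concatenate(bj)
    angle_i = np.concatenate(ai)
    angle_j = np.concatenate(aj)
    angle_k = np.concatenate(ak)
    return bond_i, bond_j, angle_i, angle_j, angle_k


def generate_random_network(params: NetworkParams,
                            rng: np.random.Generator) -> FiberNetwork:
    """Random fiber gel: von Mises orientations plus random cross-linking.

    Cross-link candidates are bead pairs on different fibers closer than the
    capture radius; candidates are shuffled and accepted (at most one link
    per bead pair) until ``crosslink_density * domain_area`` links exist or
    the candidates run out, in which case a warning is logged.
    """
    n_fibers = params.n_strands
    nb = params.n_beads
    pos = np.empty((n_fibers * nb, 2))
    for f in range(n_fibers):
        pos[f * nb:(f + 1) * nb] = sample_fiber(rng, params)
    fiber_id = np.repeat(np.arange(n_fibers), nb)

    bond_i, bond_j, angle_i, angle_j, angle_k = _chain_topology(n_fibers, nb, params)
    bond_k = np.full(len(bond_i), params.k_polymer)
    bond_rest = np.full(len(bond_i), params.r_polymer)
    is_crosslink = np.zeros(len(bond_i), dtype=bool)

    # cross-linking: close pairs on distinct fibers, random order, up to target
    lx, ly = params.domain
    target = int(round(params.crosslink_density * lx * ly))
    if target > 0 and n_fibers > 1:
        tree = cKDTree(pos)
        pairs = tree.query_pairs(params.capture_radius, output_type="ndarray")
        if len(pairs):
            pairs = pairs[fiber_id[pairs[:, 0]] != fiber_id[pairs[:, 1]]]
        if len(pairs) < target:
            logger.warning(
                "cross-link candidates exhausted: %d available, %d requested",
                len(pairs), target)
        if len(pairs):
            order = rng.permutation(len(pairs))
            chosen = pairs[order[:target]]
            # born unstrained: rest = initial separation (<= capture radius),
            # so cross-linking adds connectivity without contracting the gel
            rest = np.linalg.norm(pos[chosen[:, 0]] - pos[chosen[:, 1]], axis=1)
            bond_i = np.concatenate([bond_i, chosen[:, 0]])
            bond_j = np.concatenate([bond_j, chosen[:, 1]])
            bond_k = np.concatenate([bond_k, np.full(len(chosen), params.k_cross)])
            bond_rest = np.concatenate([bond_rest, rest])
            is_crosslink = np.concatenate([is_crosslink, np.ones(len(chosen), dtype=bool)])

    clamped = ((pos[:, 0] < 0) | (pos[:, 0] > lx) |
               (pos[:, 1] < 0) | (pos[:, 1] > ly))
    return FiberNetwork(pos, bond_i, bond_j, bond_k, bond_rest, is_crosslink,
                        angle_i, angle_j, angle_k,
                        np.full(len(angle_i), params.k_bend),
                        np.full(len(angle_i), params.theta_0),
                        clamped, fiber_id, domain=params.domain)


def generate_grid_network(params: NetworkParams) -> FiberNetwork:
    """Regular substrate: spanning horizontal/vertical strands cross-linked
    at every intersection.

    Strands run boundary to boundary at ``grid_spacing`` intervals with bead
    spacing ``r_polymer``; one extra bead past each end lies outside the
    domain and is clamped.  Every crossing of a horizontal and a vertical
    strand is joined by one cross-link between the nearest bead pair, with
    rest length equal to their initial separation so the lattice starts
    unstrained.
    """
    lx, ly = params.domain
    s, r = params.grid_spacing, params.r_polymer
    coords = np.arange(-r, lx + 1.5 * r, r)        # clamped bead past each end
    nb = len(coords)
    lines = np.arange(s / 2.0, lx, s)              # strand offsets

    chunks, fiber_ids = [], []
    fid = 0
    for y in lines:                                # horizontal strands
        chunks.append(np.column_stack([coords, np.full(nb, y)]))
        fiber_ids.append(np.full(nb, fid))
        fid += 1
    n_horiz = fid
    for x in lines:                                # vertical strands
        chunks.append(np.column_stack([np.full(nb, x), coords]))
        fiber_ids.append(np.full(nb, fid))
        fid += 1
    pos = np.concatenate(chunks)
    fiber_id = np.concatenate(fiber_ids)

    bond_i, bond_j, angle_i, angle_j, angle_k = _chain_topology(fid, nb, params)
    bond_k = np.full(len(bond_i), params.k_polymer)
    bond_rest = np.full(len(bond_i), params.r_polymer)
    is_crosslink = np.zeros(len(bond_i), dtype=bool)

    # nearest bead pair at each strand crossing
    xi, xj = [], []
    for h in range(n_horiz):
        for v in range(len(lines)):
            bead_h = h * nb + int(round((lines[v] - coords[0]) / r))
            bead_v = (n_horiz + v) * nb + int(round((lines[h] - coords[0]) / r))
            xi.append(min(bead_h, nb * fid - 1))
            xj.append(min(bead_v, nb * fid - 1))
    xi, xj = np.array(xi, dtype=int), np.array(xj, dtype=int)
    rest = np.linalg.norm(pos[xi] - pos[xj], axis=1)
    bond_i = np.concatenate([bond_i, xi])
    bond_j = np.concatenate([bond_j, xj])
    bond_k = np.concatenate([bond_k, np.full(len(xi), params.k_cross)])
    bond_rest = np.concatenate([bond_rest, rest])
    is_crosslink = np.concatenate([is_crosslink, np.ones(len(xi), dtype=bool)])

    clamped = ((pos[:, 0] < 0) | (pos[:, 0] > lx) |
               (pos[:, 1] < 0) | (pos[:, 1] > ly))
    return FiberNetwork(pos, bond_i, bond_j, bond_k, bond_rest, is_crosslink,
                        angle_i, angle_j, angle_k,
                        np.full(len(angle_i), params.k_bend),
                        np.full(len(angle_i), params.theta_0),
                        clamped, fiber_id, domain=params.domain)


def is_percolated(network: FiberNetwork, tol: float = 1e-9) -> tuple[bool, bool, bool]:
    """Spanning-cluster test on the bead graph (fiber springs + cross-links).

    Returns ``(either, x_axis, y_axis)``: whether some connected component
    contains beads touching (or beyond) both opposite domain boundaries
    along the respective axis.
    """
    n = network.n_beads
    m = coo_matrix((np.ones(network.n_bonds), (network.bond_i, network.bond_j)),
                   shape=(n, n))
    _, labels = connected_components(m, directed=False)
    lx, ly = network.domain
    x, y = network.positions[:, 0], network.positions[:, 1]

    def spans(lo_mask: np.ndarray, hi_mask: np.ndarray) -> bool:
        lo = np.unique(labels[lo_mask])
        hi = np.unique(labels[hi_mask])
        return bool(np.intersect1d(lo, hi, assume_unique=True).size)

    px = spans(x <= tol, x >= lx - tol)
    py = spans(y <= tol, y >= ly - tol)
    return px or py, px, py


def percolation_fraction(crosslink_density: float,
                         n_seeds: int,
                         seed: int,
                         params: NetworkParams | None = None) -> float:
    """Fraction of random isotropic networks that percolate at one density."""
    base = params if params is not None else NetworkParams()
    hits = 0
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_seeds):
        p = replace(base, crosslink_density=crosslink_density, kappa=0.0)
        net = generate_random_network(p, np.random.default_rng(child))
        if is_percolated(net)[0]:
            hits += 1
    return hits / n_seeds


def percolation_threshold(densities,
                          n_seeds: int = 20,
                          seed: int = 0,
                          params: NetworkParams | None = None) -> tuple[float, dict[float, float]]:
    """Smallest cross-link density at which >= 50% of replicates percolate.

    Returns (threshold, {density: percolated_fraction}).  The threshold is
    ``nan`` if no density on the grid reaches 50%.
    """
    fractions: dict[float, float] = {}
    threshold = float("nan")
    for k, rho in enumerate(sorted(densities)):
        frac = percolation_fraction(rho, n_seeds, seed + k * 1009, params)
        fractions[float(rho)] = frac
        if np.isnan(threshold) and frac >= 0.5:
            threshold = float(rho)
    return threshold, fractions
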