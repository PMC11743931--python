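"""Cellular Potts lattice: energy function and Metropolis dynamics.

A single contractile cell is the set of spin-1 sites of a square lattice
(spin 0 = medium).  Its energy is

    H = lambda * A^2  +  J * #{ordered neighbor pairs with unequal spin}
        - lambda_c * A_um / (A_um + A_h),

i.e. quadratic contractility, interfacial line tension over the Moore
stencil (each unordered mismatched pair counts twice, following the double
sum), and a saturating non-integrin substrate adhesion with the cell area
measured in um^2.  The lattice evolves by random copy attempts accepted
with the Metropolis rule P = 1 for dH <= 0 and exp(-dH/T) otherwise.

Retraction attempts over a site holding focal adhesions pay the additional
penalty dH_FA (see :mod:`fibrocell.adhesions`); accepted retractions remove
the adhesions left outside the cell, and accepted extensions over a lattice
site containing a free fiber bead create a nascent adhesion there.  One
Monte Carlo step is one sweep of ``lattice size`` elementary attempts;
copies into the outermost lattice ring are rejected, so the cell stays away
from the clamped gel boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .adhesions import FAParams, FARegistry
from .network import FiberNetwork
from .units import LATTICE_SPACING_UM

_SITE_AREA_UM2 = LATTICE_SPACING_UM**2

# Moore stencil (second-order neighborhood), used for both the interface
# energy and the copy-attempt directions.
_MOORE_DX = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
_MOORE_DY = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)


@dataclass
class CPMParams:
    """Dimensionless cell-energy coefficients.

    The defaults are calibrated so that, without any fiber gel, a cell of
    the standard initial radius (20 sites, 5 um) is stationary on average:
    the marginal contractility cost of one extra site equals the marginal
    substrate-adhesion gain there.  All spreading beyond that baseline is
    then attributable to the focal-adhesion feedback.
    """

    lambda_area: float = 0.01      # contractility
    j: float = 5.0                 # interfacial energy per ordered pair
    lambda_c: float = 1.33e5       # substrate adhesion strength
    a_h: float = 50.0              # adhesion saturation area [um^2]
    t: float = 50.0                # motility temperature
    neighborhood_order: str = "moore"

    def __post_init__(self) -> None:
        if min(self.lambda_area, self.j, self.lambda_c) < 0 or self.t <= 0:
            raise ValueError("coefficients must be >= 0 and T > 0")
        if self.neighborhood_order != "moore":
            raise ValueError("only the Moore stencil is supported")


@dataclass
class CopyEvent:
    """One resolved copy attempt that targeted a cell/medium interface."""

    source: tuple[int, int]
    target: tuple[int, int]
    accepted: bool
    kind: str                      # "extension" | "retraction"
    delta_h: float
    fa_created: int | None = None  # id of the adhesion created at the target
    fa_removed: list[int] = field(default_factory=list)


class SpinField:
    """Lattice spin state sigma: a (L, L) array indexed [x, y] with spins {0, 1}."""

    def __init__(self, grid: np.ndarray):
        grid = np.asarray(grid, dtype=np.int8)
        if grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        self.grid = grid

    @classmethod
    def empty(cls, size: int) -> "SpinField":
        return cls(np.zeros((size, size), dtype=np.int8))

    @classmethod
    def from_disc(cls, size: int, radius: float,
                  center: tuple[float, float] | None = None) -> "SpinField":
        """Centered disc of the given radius (in lattice sites)."""
        if center is None:
            center = ((size - 1) / 2.0, (size - 1) / 2.0)
        x, y = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        grid = (((x - center[0]) ** 2 + (y - center[1]) ** 2) <= radius**2)
        return cls(grid.astype(np.int8))

    @property
    def area(self) -> int:
        return int(np.count_nonzero(self.grid))

    def center_of_mass(self) -> np.ndarray:
        """Centroid of the cell's site centers [um]."""
        xs, ys = np.nonzero(self.grid)
        if len(xs) == 0:
            raise ValueError("empty cell has no center of mass")
        return (np.array([xs.mean(), ys.mean()]) + 0.5) * LATTICE_SPACING_UM

    def mask(self) -> np.ndarray:
        return self.grid > 0

    def copy(self) -> "SpinField":
        return SpinField(self.grid.copy())


def interface_pairs(grid: np.ndarray) -> int:
    """Ordered mismatched Moore-neighbor pairs; outside the grid is medium."""
    padded = np.zeros((grid.shape[0] + 2, grid.shape[1] + 2), dtype=grid.dtype)
    padded[1:-1, 1:-1] = grid
    total = 0
    for dx, dy in zip(_MOORE_DX, _MOORE_DY):
        shifted = padded[1 + dx:padded.shape[0] - 1 + dx,
                         1 + dy:padded.shape[1] - 1 + dy]
        total += int(np.count_nonzero(grid != shifted))
    return total


def total_energy(spin_field: SpinField, params: CPMParams) -> float:
    """Full Hamiltonian of the lattice state."""
    a = spin_field.area
    h = params.lambda_area * a**2 + params.j * interface_pairs(spin_field.grid)
    a_um = a * _SITE_AREA_UM2
    if a_um > 0:
        h -= params.lambda_c * a_um / (a_um + params.a_h)
    return h


def _adhesion_delta(area: int, new_area: int, params: CPMParams) -> float:
    a0 = area * _SITE_AREA_UM2
    a1 = new_area * _SITE_AREA_UM2
    return -params.lambda_c * (a1 / (a1 + params.a_h) - a0 / (a0 + params.a_h))


def copy_attempt_delta(spin_field: SpinField,
                       source: tuple[int, int],
                       target: tuple[int, int],
                       fa_registry: FARegistry | None,
                       params: CPMParams,
                       fa_params: FAParams | None = None) -> float:
    """Energy change of copying sigma(source) onto target, incl. dH_FA.

    Reference implementation used to validate the sweep kernel; the FA
    penalty applies only to retractions over a site holding adhesions.
    """
    sx, sy = source
    tx, ty = target
    if (sx, sy) == (tx, ty) or max(abs(sx - tx), abs(sy - ty)) != 1:
        raise ValueError("source and target must be distinct Moore neighbors")
    grid = spin_field.grid
    ss, st = int(grid[sx, sy]), int(grid[tx, ty])
    if ss == st:
        raise ValueError("copy attempt requires unequal spins")
    delta_pairs = 0
    for dx, dy in zip(_MOORE_DX, _MOORE_DY):
        nx, ny = tx + dx, ty + dy
        inside = 0 <= nx < grid.shape[0] and 0 <= ny < grid.shape[1]
        sn = int(grid[nx, ny]) if inside else 0
        # in-grid pairs appear twice in the ordered double sum, pairs with
        # the medium beyond the grid only once (from the in-grid side)
        w = 2 if inside else 1
        delta_pairs += w * (int(ss != sn) - int(st != sn))
    area = spin_field.area
    d_area = 1 if ss > 0 else -1
    new_area = area + d_area
    dh = (params.lambda_area * (new_area**2 - area**2)
          + params.j * delta_pairs
          + _adhesion_delta(area, new_area, params))
    if ss == 0 and fa_registry is not None:   # retraction over the target site
        dh += fa_registry.penalty((tx, ty))
    return dh


def metropolis_accept(delta_h: float, t: float, rng: np.random.Generator) -> bool:
    """Standard acceptance: certain for dH <= 0, else with probability e^(-dH/T)."""
    if t <= 0:
        raise ValueError("T must be positive")
    if delta_h <= 0:
        return True
    return bool(rng.random() < math.exp(-delta_h / t))


@njit(cache=True)
def _sweep(grid, area, lam, j, lamc, ah, t_motility, lam_fa, nh,
           fa_count, fa_xsum,
           free_off, free_beads, bead_bound,
           fa_site, fa_bead, fa_removed,
           new_site, new_bead, new_removed,
           ev_kind, ev_sx, ev_sy, ev_tx, ev_ty, ev_dh, ev_bead, ev_removed_site,
           n_attempts, seed):
    lx, ly = grid.shape
    site_area = _SITE_AREA_UM2
    np.random.seed(seed)
    n_ev = 0
    n_new = 0
    n_live = len(fa_site)
    for _ in range(n_attempts):
        sx = np.random.randint(0, lx)
        sy = np.random.randint(0, ly)
        d = np.random.randint(0, 8)
        tx = sx + _MOORE_DX[d]
        ty = sy + _MOORE_DY[d]
        if tx < 0 or tx >= lx or ty < 0 or ty >= ly:
            continue
        if tx == 0 or tx == lx - 1 or ty == 0 or ty == ly - 1:
            continue                       # fixed outer ring
        ss = grid[sx, sy]
        st = grid[tx, ty]
        if ss == st:
            continue
        delta_pairs = 0
        for k in range(8):
            nx = tx + _MOORE_DX[k]
            ny = ty + _MOORE_DY[k]
            if 0 <= nx < lx and 0 <= ny < ly:
                sn = grid[nx, ny]
            else:
                sn = 0
            delta_pairs += (1 if ss != sn else 0) - (1 if st != sn else 0)
        d_area = 1 if ss > 0 else -1
        new_area = area + d_area
        a0 = area * site_area
        a1 = new_area * site_area
        dh = (lam * (new_area * new_area - area * area)
              + j * 2.0 * delta_pairs
              - lamc * (a1 / (a1 + ah) - a0 / (a0 + ah)))
        tlin = tx * ly + ty
        retraction = ss == 0
        if retraction and fa_count[tlin] > 0:
            x = fa_xsum[tlin]
            if x > 0.0:
                dh += lam_fa * x / (x + nh)
        accepted = dh <= 0.0 or np.random.random() < np.exp(-dh / t_motility)
        ev_kind[n_ev] = 2 if retraction else 1
        ev_sx[n_ev] = sx
        ev_sy[n_ev] = sy
        ev_tx[n_ev] = tx
        ev_ty[n_ev] = ty
        ev_dh[n_ev] = dh
        ev_bead[n_ev] = -1
        ev_removed_site[n_ev] = 0
        if not accepted:
            n_ev += 1
            continue
        ev_kind[n_ev] += 2                # 3 = accepted ext, 4 = accepted retr
        grid[tx, ty] = ss
        area = new_area
        if retraction:
            if fa_count[tlin] > 0:
                ev_removed_site[n_ev] = 1
                for f in range(n_live):
                    if fa_site[f] == tlin and fa_removed[f] == 0:
                        fa_removed[f] = 1
                        bead_bound[fa_bead[f]] = False
                for c in range(n_new):
                    if new_site[c] == tlin and new_removed[c] == 0:
                        new_removed[c] = 1
                        bead_bound[new_bead[c]] = False
                fa_count[tlin] = 0
                fa_xsum[tlin] = 0.0
        else:
            for idx in range(free_off[tlin], free_off[tlin + 1]):
                b = free_beads[idx]
                if not bead_bound[b]:
                    bead_bound[b] = True
                    new_site[n_new] = tlin
                    new_bead[n_new] = b
                    new_removed[n_new] = 0
                    n_new += 1
                    fa_count[tlin] += 1
                    ev_bead[n_ev] = b
                    break
        n_ev += 1
    return area, n_ev


def _site_index_csr(network: FiberNetwork, shape: tuple[int, int]):
    """CSR map: lattice site -> candidate bead ids, nearest-to-center first.

    Candidates are all unclamped beads whose position falls on the lattice;
    the live ``fa_bound`` flag decides availability at attempt time.
    """
    lx, ly = shape
    pos = network.positions
    sx = np.floor(pos[:, 0] / LATTICE_SPACING_UM).astype(np.int64)
    sy = np.floor(pos[:, 1] / LATTICE_SPACING_UM).astype(np.int64)
    ok = (~network.clamped & (sx >= 0) & (sx < lx) & (sy >= 0) & (sy < ly))
    ids = np.flatnonzero(ok)
    lin = sx[ids] * ly + sy[ids]
    centers = (np.column_stack([sx[ids], sy[ids]]) + 0.5) * LATTICE_SPACING_UM
    dist = np.linalg.norm(pos[ids] - centers, axis=1)
    order = np.lexsort((ids, np.round(dist, 9), lin))
    ids, lin = ids[order], lin[order]
    off = np.zeros(lx * ly + 1, dtype=np.int64)
    np.add.at(off, lin + 1, 1)
    np.cumsum(off, out=off)
    return off, ids.astype(np.int64)


def monte_carlo_step(spin_field: SpinField,
                     network: FiberNetwork,
                     registry: FARegistry,
                     params: CPMParams,
                     fa_params: FAParams,
                     rng: np.random.Generator,
                     n_attempts: int | None = None,
                     collect_events: bool = True):
    """One Monte Carlo step: ``lattice size`` elementary copy attempts.

    Mutates the spin field, the adhesion registry and the network's bound
    flags; returns ``(area, events)`` where events lists the resolved
    interface attempts (empty if ``collect_events`` is False).
    """
    grid = spin_field.grid
    lx, ly = grid.shape
    if n_attempts is None:
        n_attempts = lx * ly

    fa_count = np.zeros(lx * ly, dtype=np.int64)
    fa_xsum = np.zeros(lx * ly)
    live = list(registry)
    fa_site = np.array([fa.site[0] * ly + fa.site[1] for fa in live], dtype=np.int64)
    fa_bead = np.array([fa.bead_id for fa in live], dtype=np.int64)
    fa_removed = np.zeros(len(live), dtype=np.int64)
    for fa, s in zip(live, fa_site):
        fa_count[s] += 1
        fa_xsum[s] += fa.n - fa_params.n_0
    np.maximum(fa_xsum, 0.0, out=fa_xsum)   # shrunken FAs never reward retraction

    free_off, free_beads = _site_index_csr(network, (lx, ly))
    bead_bound = network.fa_bound.copy()    # kernel scratch; replay mutates truth

    cap = n_attempts
    new_site = np.empty(cap, dtype=np.int64)
    new_bead = np.empty(cap, dtype=np.int64)
    new_removed = np.empty(cap, dtype=np.int64)
    ev_kind = np.zeros(cap, dtype=np.int64)
    ev_sx = np.empty(cap, dtype=np.int64)
    ev_sy = np.empty(cap, dtype=np.int64)
    ev_tx = np.empty(cap, dtype=np.int64)
    ev_ty = np.empty(cap, dtype=np.int64)
    ev_dh = np.empty(cap)
    ev_bead = np.empty(cap, dtype=np.int64)
    ev_removed_site = np.empty(cap, dtype=np.int64)

    seed = int(rng.integers(2**31 - 1))
    area, n_ev = _sweep(grid, spin_field.area, params.lambda_area, params.j,
                        params.lambda_c, params.a_h, params.t,
                        fa_params.lambda_fa, fa_params.n_h,
                        fa_count, fa_xsum, free_off, free_beads, bead_bound,
                        fa_site, fa_bead, fa_removed,
                        new_site, new_bead, new_removed,
                        ev_kind, ev_sx, ev_sy, ev_tx, ev_ty, ev_dh, ev_bead,
                        ev_removed_site, n_attempts, seed)

    events: list[CopyEvent] = []
    for e in range(n_ev):
        kind_code = ev_kind[e]
        accepted = kind_code >= 3
        kind = "retraction" if kind_code in (2, 4) else "extension"
        target = (int(ev_tx[e]), int(ev_ty[e]))
        removed_ids: list[int] = []
        created_id = None
        if accepted and ev_removed_site[e]:
            removed_ids = registry.remove_site(target, network)
        if accepted and ev_bead[e] >= 0:
            fa = registry.create(target, int(ev_bead[e]), network)
            created_id = fa.id
        if collect_events:
            events.append(CopyEvent(
                source=(int(ev_sx[e]), int(ev_sy[e])), target=target,
                accepted=bool(accepted), kind=kind, delta_h=float(ev_dh[e]),
                fa_created=created_id, fa_removed=removed_ids))
    assert area == spin_field.area
    return area, events
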