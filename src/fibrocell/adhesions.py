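"""Focal adhesions: mechanosensitive integrin clusters coupling cell and gel.

A focal adhesion (FA) binds one lattice site of the cell to one bead of the
fiber network.  Its state is a continuous bound-integrin count N under a
tension Phi, evolving by

    dN/dt = gamma * (N_tot - N) - d0 * d(f_star * Phi / N) * N,

where the per-integrin unbinding response is the catch-slip law

    d(phi) = exp(phi - phi_s) + exp(phi_c - phi).

d is large at zero load (catch bonds are unstable when slack), minimal at
phi = (phi_s + phi_c)/2, and diverges again in the slip regime -- the
mechanosensing kernel of the model: FAs mature only in a band of tension
per integrin.

The cell loads its FAs through a cytoskeletal spring to the cell centroid
(tension K_cyto * distance, the two-spring picture); each coupling step
every FA makes one greedy attempt to step one lattice site toward the
centroid, accepted iff cytoskeletal plus local-spring energy decreases.
Mature FAs feed back on the cell through a retraction penalty

    dH_FA = lambda_FA * X / (X + N_h),   X = max(0, sum_site (N - N0)),

added to the energy change of any retraction copy-attempt over the site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import count

import numpy as np

from .network import FiberNetwork
from .units import LATTICE_SPACING_UM

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class FAParams:
    """Integrin kinetics and coupling constants (s, nN, um internally)."""

    gamma: float = 2.88            # integrin binding rate [1/s]
    d0: float = 0.0288             # base detachment rate [1/s]
    f_star: float = 12.9           # force scale [1/nN] (= 1.29e10 1/N)
    phi_s: float = 4.02            # slip threshold
    phi_c: float = 7.76            # catch threshold
    n_tot: float = 390.0           # max integrins per FA
    n_0: float = 25.0              # nascent FA size
    n_h: float = 100.0             # retraction-penalty saturation
    lambda_fa: float = 800.0       # retraction penalty scale [CPM energy]
    k_cyto: float = 0.31           # cytoskeletal spring [nN/um] (= 3.1e-4 N/m)
    n_min: float = 1.0             # lower clamp for N
    tau: float = 2.88              # ODE duration per coupling step [s]
    #: "ecm": |net elastic force on the pinned bead| -- tension reflects gel
    #: stiffness, the two-spring picture (stiff gels load adhesions fast,
    #: soft ones slowly; slip on stiff gels).  "cytoskeletal": K_cyto times
    #: the distance to the cell center; both coincide at greedy-stall.
    tension_source: str = "ecm"

    def __post_init__(self) -> None:
        if not (0 < self.n_0 <= self.n_tot):
            raise ValueError("require 0 < n_0 <= n_tot")
        if not (self.phi_c > self.phi_s > 0):
            raise ValueError("require phi_c > phi_s > 0")
        if min(self.gamma, self.d0, self.f_star) <= 0:
            raise ValueError("rates must be positive")
        if self.tension_source not in ("cytoskeletal", "ecm"):
            raise ValueError("tension_source must be 'cytoskeletal' or 'ecm'")


@dataclass
class FocalAdhesion:
    """One adhesion: lattice site <-> network bead, N integrins under tension Phi."""

    id: int
    site: tuple[int, int]
    bead_id: int
    n: float
    phi: float = 0.0               # current tension [nN]


def catch_slip_rate(phi: float, params: FAParams) -> float:
    """Dimensionless unbinding response d(phi) = e^(phi-phi_s) + e^(phi_c-phi).

    Exponents are capped at 700 to keep the rate finite (and the integrator
    well-defined) for the extreme per-integrin tensions a nearly empty
    cluster can report; 1e304 is already "instant unbinding".
    """
    return (math.exp(min(phi - params.phi_s, 700.0))
            + math.exp(min(params.phi_c - phi, 700.0)))


def fa_tension(fa: FocalAdhesion, cell_center: np.ndarray, params: FAParams,
               network: FiberNetwork | None = None) -> float:
    """Tension on an FA [nN].

    Default: the cytoskeletal spring tension K_cyto * |x_FA - x_center|.
    With ``tension_source='ecm'`` the magnitude of the net elastic force the
    gel exerts on the pinned bead is used instead; the two coincide when the
    greedy displacement has stalled (two-spring balance) but differ out of
    equilibrium.
    """
    if params.tension_source == "ecm":
        if network is None:
            raise ValueError("ecm tension source needs the network")
        from .mechanics import forces
        f = forces(network)[fa.bead_id]
        return float(np.hypot(f[0], f[1]))
    pos = _site_center(fa.site)
    return params.k_cyto * float(np.hypot(pos[0] - cell_center[0],
                                          pos[1] - cell_center[1]))


def steady_state_n(phi_per_integrin: float, params: FAParams) -> float:
    """Closed-form fixed point of the integrin ODE at constant d(phi).

    Valid when the per-integrin tension (hence d) is held fixed:
    N* = gamma * N_tot / (gamma + d0 * d(phi)).
    """
    d = catch_slip_rate(phi_per_integrin, params)
    return params.gamma * params.n_tot / (params.gamma + params.d0 * d)


def integrate_integrins(n: float, phi: float, params: FAParams,
                        tau: float | None = None,
                        phi_per_integrin: float | None = None) -> float:
    """Advance dN/dt over duration tau; result clamped to (n_min, n_tot].

    Within each sub-step the unbinding response d(f_star*phi/N) is frozen,
    which makes the ODE linear and admits the exact update
    N' = N_ss + (N - N_ss) * exp(-(gamma + d0*d) dt); the scheme is
    unconditionally stable in the stiff catch regime (d(0) ~ 2.3e3) and
    recovers the analytic fixed point exactly when the per-integrin tension
    is constant.  Sub-steps are halved adaptively until one step changes N
    by less than 10%, so the frozen-d approximation stays accurate while
    phi/N drifts.

    ``phi_per_integrin`` (test mode) holds the per-integrin tension fixed
    instead of deriving it as f_star * phi / N.
    """
    if tau is None:
        tau = params.tau
    t = 0.0
    dt = tau
    while t < tau - 1e-12:
        dt = min(dt, tau - t)
        phi_i = params.f_star * phi / n if phi_per_integrin is None else phi_per_integrin
        d = catch_slip_rate(phi_i, params)
        decay = params.gamma + params.d0 * d
        n_ss = params.gamma * params.n_tot / decay
        n_new = n_ss + (n - n_ss) * math.exp(-max(min(decay * dt, 700.0), 0.0))
        # refine only while the proposal is off the clamp: a cluster
        # collapsing onto n_min needs no sub-step resolution
        if (abs(n_new - n) > 0.1 * n and dt > tau * 2.0**-40
                and n_new > params.n_min):
            dt *= 0.5
            continue
        n = min(max(n_new, params.n_min), params.n_tot)
        t += dt
        dt *= 2.0
    return n


def retraction_penalty(fa_list, params: FAParams) -> float:
    """Energy penalty dH_FA for retracting over the given FAs' shared site."""
    x = max(0.0, sum(fa.n - params.n_0 for fa in fa_list))
    if x == 0.0:
        return 0.0
    return params.lambda_fa * x / (x + params.n_h)


def _site_center(site: tuple[int, int]) -> np.ndarray:
    """Physical center [um] of a lattice site given as (col, row) = (x, y)."""
    return (np.asarray(site, dtype=float) + 0.5) * LATTICE_SPACING_UM


class FARegistry:
    """Live focal adhesions, indexed by id and by lattice site.

    Maintains the bijection between ``fa_bound`` beads of the network and
    registered adhesions; ``audit`` verifies it.
    """

    def __init__(self, params: FAParams):
        self.params = params
        self.by_id: dict[int, FocalAdhesion] = {}
        self.by_site: dict[tuple[int, int], list[int]] = {}
        self._ids = count()

    def __len__(self) -> int:
        return len(self.by_id)

    def __iter__(self):
        return iter(self.by_id.values())

    def fas_at(self, site: tuple[int, int]) -> list[FocalAdhesion]:
        return [self.by_id[i] for i in self.by_site.get(tuple(site), [])]

    def create(self, site: tuple[int, int], bead_id: int,
               network: FiberNetwork) -> FocalAdhesion:
        """Nascent FA with N = N0; pins the bead to the site center."""
        site = tuple(site)
        if network.fa_bound[bead_id]:
            raise ValueError(f"bead {bead_id} is already bound to an FA")
        if network.clamped[bead_id]:
            raise ValueError(f"bead {bead_id} is clamped and cannot adhere")
        fa = FocalAdhesion(next(self._ids), site, bead_id, self.params.n_0)
        network.fa_bound[bead_id] = True
        network.positions[bead_id] = _site_center(site)
        self.by_id[fa.id] = fa
        self.by_site.setdefault(site, []).append(fa.id)
        return fa

    def remove(self, fa: FocalAdhesion, network: FiberNetwork) -> None:
        """Delete an FA; its bead becomes mobile and re-adhesible."""
        network.fa_bound[fa.bead_id] = False
        del self.by_id[fa.id]
        sids = self.by_site[fa.site]
        sids.remove(fa.id)
        if not sids:
            del self.by_site[fa.site]

    def remove_site(self, site: tuple[int, int], network: FiberNetwork) -> list[int]:
        """Remove every FA at a site (retraction left them outside the cell)."""
        removed = []
        for fa in list(self.fas_at(site)):
            self.remove(fa, network)
            removed.append(fa.id)
        return removed

    def site_excess(self, site: tuple[int, int]) -> float:
        """Sum of (N - N0) over FAs at the site (may be negative)."""
        return sum(fa.n - self.params.n_0 for fa in self.fas_at(site))

    def penalty(self, site: tuple[int, int]) -> float:
        return retraction_penalty(self.fas_at(site), self.params)

    def audit(self, network: FiberNetwork) -> None:
        bound = set(np.flatnonzero(network.fa_bound))
        beads = [fa.bead_id for fa in self]
        if len(beads) != len(set(beads)) or set(beads) != bound:
            raise RuntimeError("FA registry <-> fa_bound bead bijection broken")
        for site, ids in self.by_site.items():
            for i in ids:
                if self.by_id[i].site != site:
                    raise RuntimeError("FA site index inconsistent")


def displace_fa(fa: FocalAdhesion,
                network: FiberNetwork,
                cell_center: np.ndarray,
                params: FAParams,
                registry: FARegistry | None = None,
                attached: np.ndarray | None = None,
                cell_mask: np.ndarray | None = None) -> bool:
    """One greedy displacement attempt of an FA toward the cell center.

    The candidate is the Moore-neighbor lattice site whose direction best
    matches the center direction; the move is accepted iff the sum of the
    cytoskeletal spring energy and the energy of the springs directly
    attached to the FA bead strictly decreases.  When a cell mask is given
    the candidate must be a cell site (an adhesion sits under the cell body;
    around a concave boundary the straight path may leave it).  Returns
    whether the FA (and its pinned bead) moved.
    """
    pos = _site_center(fa.site)
    to_center = np.asarray(cell_center) - pos
    dist = np.hypot(to_center[0], to_center[1])
    if dist < LATTICE_SPACING_UM / 2.0:
        return False   # already at the central site
    best, best_dot = None, -np.inf
    ux, uy = to_center / dist
    for dx, dy in _MOORE:
        cand = (fa.site[0] + dx, fa.site[1] + dy)
        if cell_mask is not None:
            if not (0 <= cand[0] < cell_mask.shape[0] and
                    0 <= cand[1] < cell_mask.shape[1] and cell_mask[cand]):
                continue
        norm = math.hypot(dx, dy)
        dot = (dx * ux + dy * uy) / norm
        if dot > best_dot:
            best_dot = dot
            best = cand
    if best is None:
        return False
    new_pos = _site_center(best)

    bead = fa.bead_id
    if attached is None:   # callers in the hot loop pass a precomputed adjacency
        attached = np.flatnonzero((network.bond_i == bead) | (network.bond_j == bead))

    def local_energy(p: np.ndarray) -> float:
        e = 0.5 * params.k_cyto * float((p[0] - cell_center[0]) ** 2 +
                                        (p[1] - cell_center[1]) ** 2)
        for b in attached:
            other = network.bond_j[b] if network.bond_i[b] == bead else network.bond_i[b]
            q = network.positions[other]
            r = math.hypot(p[0] - q[0], p[1] - q[1])
            e += 0.5 * network.bond_k[b] * (network.bond_rest[b] - r) ** 2
        return e

    if local_energy(new_pos) - local_energy(network.positions[bead]) >= 0.0:
        return False
    network.positions[bead] = new_pos
    if registry is not None:
        sids = registry.by_site[fa.site]
        sids.remove(fa.id)
        if not sids:
            del registry.by_site[fa.site]
        registry.by_site.setdefault(best, []).append(fa.id)
    fa.site = best
    return True
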