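"""Potential energy, forces, and overdamped relaxation of the fiber gel.

Stretch springs contribute (k/2)(r0 - |b_i - b_j|)^2 and angle triples
(K_bend/2)(theta - theta0)^2, with theta the interior angle at the middle
bead.  Free beads follow the overdamped Langevin update

    b_i <- b_i + (dt/gamma) * (F_i + W_i),

with isotropic Gaussian noise of variance <W^2> = 2*gamma*T_ecm/dt per
component.  Clamped beads (outside the domain) and beads pinned by a focal
adhesion are excluded from the motion; the gel is integrated until the
maximum free-bead force drops below ``force_tol`` or ``max_steps`` runs out.
Non-convergence is logged, not raised: within the operator-splitting loop
each relaxation only needs to track the quasi-steady state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .network import FiberNetwork

logger = logging.getLogger(__name__)

_SIN_FLOOR = 1e-8  # angle-gradient guard near collinearity


@dataclass
class MechanicsParams:
    """Integration parameters for gel relaxation (internal units: um, nN, s)."""

    gamma_drag: float = 1.0      # drag coefficient [nN s/um]
    t_ecm: float = 0.001         # noise level [fJ]
    dt: float | None = None      # timestep [s]; None -> automatic (stable_dt)
    max_steps: int = 10_000
    force_tol: float = 1e-4      # convergence threshold on max free-bead force [nN]
    noise_every: int = 8         # sub-steps between thermal kicks (variance-scaled)

    def __post_init__(self) -> None:
        if self.gamma_drag <= 0 or self.t_ecm < 0 or self.force_tol <= 0:
            raise ValueError("invalid mechanics parameters")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")

    def stable_dt(self, network: FiberNetwork) -> float:
        """Automatic timestep 0.4 * gamma / k_bead for the stiffest bead.

        The effective stiffness of a bead is the sum of its attached spring
        constants plus ~4*K_bend/r^2 per angle it participates in; summing
        (rather than taking the stiffest single bond) keeps the explicit
        update stable at highly cross-linked junctions.  ``dt`` caps the
        result when set.
        """
        n = network.n_beads
        if n == 0:
            return self.dt or 1e-3
        k_bead = np.zeros(n)
        np.add.at(k_bead, network.bond_i, network.bond_k)
        np.add.at(k_bead, network.bond_j, network.bond_k)
        if len(network.angle_i):
            r_min = max(float(network.bond_rest[~network.is_crosslink].min()), 1e-3)
            k_ang = 4.0 * network.angle_kbend / r_min**2
            for idx in (network.angle_i, network.angle_j, network.angle_k):
                np.add.at(k_bead, idx, k_ang)
        k_max = max(float(k_bead.max()), 1e-9)
        dt = 0.4 * self.gamma_drag / k_max
        if self.dt is not None:
            dt = min(dt, self.dt)
        return dt


@njit(cache=True, fastmath=True)
def _accumulate_forces(pos, bond_i, bond_j, bond_k, bond_rest,
                       ang_i, ang_j, ang_k, kbend, theta0, out):
    out[:] = 0.0
    for b in range(len(bond_i)):
        i, j = bond_i[b], bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        r = np.sqrt(dx * dx + dy * dy)
        if r < 1e-12:
            continue  # coincident beads: zero-rest-length link at equilibrium
        f = -bond_k[b] * (r - bond_rest[b]) / r
        out[i, 0] += f * dx
        out[i, 1] += f * dy
        out[j, 0] -= f * dx
        out[j, 1] -= f * dy
    for a in range(len(ang_i)):
        i, j, k = ang_i[a], ang_j[a], ang_k[a]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        nu = np.sqrt(ux * ux + uy * uy)
        nv = np.sqrt(vx * vx + vy * vy)
        if nu < 1e-12 or nv < 1e-12:
            continue
        c = (ux * vx + uy * vy) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        s = np.sqrt(1.0 - c * c)
        if s < _SIN_FLOOR:
            s = _SIN_FLOOR
        coeff = kbend[a] * (theta - theta0[a]) / s
        # dtheta/d(pos_i) = -(v/nv - c*u/nu)/(nu*s); force = -dU/dpos
        gix = coeff * (vx / nv - c * ux / nu) / nu
        giy = coeff * (vy / nv - c * uy / nu) / nu
        gkx = coeff * (ux / nu - c * vx / nv) / nv
        gky = coeff * (uy / nu - c * vy / nv) / nv
        out[i, 0] += gix
        out[i, 1] += giy
        out[k, 0] += gkx
        out[k, 1] += gky
        out[j, 0] -= gix + gkx
        out[j, 1] -= giy + gky


@njit(cache=True, fastmath=True)
def _relax_loop(pos, bond_i, bond_j, bond_k, bond_rest,
                ang_i, ang_j, ang_k, kbend, theta0,
                mobile, gamma, dt, max_steps, force_tol, noise_std,
                noise_every, seed):
    # thermal kicks are applied every ``noise_every`` sub-steps with variance
    # scaled accordingly: identical diffusion, far fewer Gaussian draws
    n = pos.shape[0]
    forces = np.zeros((n, 2))
    np.random.seed(seed)
    steps = 0
    converged = False
    max_f = 0.0
    kick = noise_std * np.sqrt(noise_every)
    for step in range(max_steps):
        _accumulate_forces(pos, bond_i, bond_j, bond_k, bond_rest,
                           ang_i, ang_j, ang_k, kbend, theta0, forces)
        max_f = 0.0
        for i in range(n):
            if mobile[i]:
                f = np.sqrt(forces[i, 0] ** 2 + forces[i, 1] ** 2)
                if f > max_f:
                    max_f = f
        if max_f < force_tol:
            converged = True
            break
        scale = dt / gamma
        noisy = noise_std > 0 and step % noise_every == 0
        for i in range(n):
            if mobile[i]:
                if noisy:
                    pos[i, 0] += scale * (forces[i, 0] + kick * np.random.standard_normal())
                    pos[i, 1] += scale * (forces[i, 1] + kick * np.random.standard_normal())
                else:
                    pos[i, 0] += scale * forces[i, 0]
                    pos[i, 1] += scale * forces[i, 1]
        steps += 1
    return steps, converged, max_f


def potential_energy(network: FiberNetwork) -> float:
    """Total elastic energy of the gel [fJ]."""
    pos = network.positions
    d = pos[network.bond_i] - pos[network.bond_j]
    r = np.hypot(d[:, 0], d[:, 1])
    u = 0.5 * network.bond_k * (network.bond_rest - r) ** 2
    energy = float(u.sum())
    if len(network.angle_i):
        a = pos[network.angle_i] - pos[network.angle_j]
        b = pos[network.angle_k] - pos[network.angle_j]
        na = np.hypot(a[:, 0], a[:, 1])
        nb = np.hypot(b[:, 0], b[:, 1])
        if np.any(na < 1e-12) or np.any(nb < 1e-12):
            raise ValueError("degenerate angle triple: coincident beads")
        c = np.clip((a * b).sum(axis=1) / (na * nb), -1.0, 1.0)
        theta = np.arccos(c)
        energy += float((0.5 * network.angle_kbend * (theta - network.angle_theta0) ** 2).sum())
    return energy


def forces(network: FiberNetwork) -> np.ndarray:
    """Per-bead force -dU/db [nN]; reported for all beads, clamped included."""
    out = np.zeros_like(network.positions)
    _accumulate_forces(network.positions, network.bond_i, network.bond_j,
                       network.bond_k, network.bond_rest,
                       network.angle_i, network.angle_j, network.angle_k,
                       network.angle_kbend, network.angle_theta0, out)
    return out


def relax(network: FiberNetwork,
          params: MechanicsParams,
          pinned: np.ndarray | None = None,
          rng: np.random.Generator | None = None,
          in_place: bool = False) -> tuple[FiberNetwork, bool, int]:
    """Overdamped relaxation toward mechanical quasi-equilibrium.

    Parameters
    ----------
    pinned
        Boolean mask of beads held fixed in addition to the clamped ones
        (typically the focal-adhesion beads gripped by the cell).
    rng
        Source for the thermal noise seed; with ``t_ecm = 0`` it is unused.

    Returns ``(network, converged, steps_used)``.
    """
    net = network if in_place else network.copy()
    mobile = ~net.clamped
    if pinned is not None:
        mobile = mobile & ~np.asarray(pinned, dtype=bool)
    dt = params.stable_dt(net)
    noise_std = (np.sqrt(2.0 * params.gamma_drag * params.t_ecm / dt)
                 if params.t_ecm > 0 else 0.0)
    seed = int(rng.integers(2**31 - 1)) if rng is not None else 0
    steps, converged, max_f = _relax_loop(
        net.positions, net.bond_i, net.bond_j, net.bond_k, net.bond_rest,
        net.angle_i, net.angle_j, net.angle_k, net.angle_kbend, net.angle_theta0,
        mobile, params.gamma_drag, dt, params.max_steps, params.force_tol,
        noise_std, params.noise_every, seed)
    if not converged:
        logger.debug("relaxation hit max_steps=%d (max force %.3g nN)",
                     params.max_steps, max_f)
    return net, converged, steps
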