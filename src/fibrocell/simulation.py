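"""Operator-splitting master loop coupling cell, gel and adhesions.

Each coupled step advances the three submodels in sequence, every one
treating the others as frozen:

1. one cellular-Potts Monte Carlo step (shape update; adhesions created
   under accepted extensions, destroyed by accepted retractions);
2. refresh of the cell's center of mass;
3. one greedy displacement attempt per focal adhesion, in ascending id
   order (adhesions move independently and may share a site);
4. relaxation of the fiber gel with adhesion beads pinned (every
   ``relax_every`` steps);
5. recomputation of every adhesion's tension;
6. the integrin ODE advanced by one step duration (2.88 s) per adhesion.

A consistency audit (adhesion <-> bead bijection, clamped beads immobile)
runs after every step and raises on violation.  All randomness flows from
one master seed through separate streams per submodel, so runs are
bit-reproducible and toggling gel noise does not perturb the cell's draw
sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace as dc_replace

import numpy as np
import pandas as pd
import yaml

from .adhesions import FAParams, FARegistry, displace_fa, fa_tension, integrate_integrins
from .lattice import CPMParams, SpinField, monte_carlo_step
from .mechanics import MechanicsParams, forces, relax
from .network import (FiberNetwork, NetworkParams, generate_grid_network,
                      generate_random_network)
from .units import (LATTICE_SPACING_UM, N_PER_M_TO_NN_PER_UM, J_TO_FJ,
                    PER_N_TO_PER_NN, modulus_to_spring_constant,
                    sites_to_um, steps_to_seconds)

logger = logging.getLogger(__name__)

__all__ = [
    "Schedule", "SimulationConfig", "SimulationState", "Trajectory",
    "initialize", "simulation_step", "run_simulation",
    "modulus_to_spring_constant", "sites_to_um", "steps_to_seconds",
]


@dataclass
class Schedule:
    n_steps: int = 10_000
    relax_every: int = 1
    output_every: int = 100
    audit_every: int = 1
    initial_relax_steps: int = 2_000     # settle the freshly generated gel

    def __post_init__(self) -> None:
        if self.n_steps < 0 or self.relax_every < 1 or self.output_every < 1:
            raise ValueError("invalid schedule")


@dataclass
class SimulationConfig:
    """Everything needed to reproduce a run from a file plus a seed."""

    cpm: CPMParams = field(default_factory=CPMParams)
    network: NetworkParams = field(default_factory=NetworkParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    fa: FAParams = field(default_factory=FAParams)
    schedule: Schedule = field(default_factory=Schedule)
    lattice_size: int = 200
    cell_radius: float = 20.0            # initial disc radius [sites]
    scenario: str = "isotropic"          # grid | isotropic | anisotropic
    seed: int = 0
    store_masks: bool = True
    store_beads: bool = True

    def __post_init__(self) -> None:
        if self.scenario not in ("grid", "isotropic", "anisotropic"):
            raise ValueError("scenario must be grid, isotropic or anisotropic")
        extent = self.lattice_size * LATTICE_SPACING_UM
        self.network.domain = (extent, extent)

    # --- serialization, mirroring the published parameter names (SI units) ---

    _SI = {  # (section, yaml key) -> (attr, factor from SI to internal)
        ("fa", "f_star"): ("f_star", PER_N_TO_PER_NN),
        ("fa", "K_cyto"): ("k_cyto", N_PER_M_TO_NN_PER_UM),
        ("network", "K"): ("k_polymer", N_PER_M_TO_NN_PER_UM),
        ("network", "K_bend"): ("k_bend", J_TO_FJ),
    }

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed, "scenario": self.scenario,
            "lattice_size": self.lattice_size, "cell_radius": self.cell_radius,
            "cpm": {"lambda": self.cpm.lambda_area, "J": self.cpm.j,
                    "lambda_c": self.cpm.lambda_c, "A_h": self.cpm.a_h,
                    "T": self.cpm.t, "neighborhood": self.cpm.neighborhood_order},
            "fa": {"gamma": self.fa.gamma, "d0": self.fa.d0,
                   "f_star": self.fa.f_star / PER_N_TO_PER_NN,
                   "phi_s": self.fa.phi_s, "phi_c": self.fa.phi_c,
                   "N_tot": self.fa.n_tot, "N_0": self.fa.n_0,
                   "N_h": self.fa.n_h, "lambda_FA": self.fa.lambda_fa,
                   "K_cyto": self.fa.k_cyto / N_PER_M_TO_NN_PER_UM,
                   "tension_source": self.fa.tension_source},
            "network": {"K": self.network.k_polymer / N_PER_M_TO_NN_PER_UM,
                        "K_bend": self.network.k_bend / J_TO_FJ,
                        "theta_0": self.network.theta_0,
                        "fiber_density": self.network.fiber_density,
                        "kappa": self.network.kappa, "mu": self.network.mu,
                        "n_beads": self.network.n_beads,
                        "r_polymer": self.network.r_polymer,
                        "crosslink_density": self.network.crosslink_density,
                        "grid_spacing": self.network.grid_spacing},
            "mechanics": {"T_ECM": self.mechanics.t_ecm,
                          "gamma_drag": self.mechanics.gamma_drag,
                          "max_steps": self.mechanics.max_steps,
                          "force_tol": self.mechanics.force_tol},
            "schedule": {k: v for k, v in asdict(self.schedule).items()},
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls()
        cfg.seed = int(d.get("seed", 0))
        cfg.scenario = d.get("scenario", "isotropic")
        cfg.lattice_size = int(d.get("lattice_size", 200))
        cfg.cell_radius = float(d.get("cell_radius", 20.0))
        c = d.get("cpm", {})
        cfg.cpm = CPMParams(lambda_area=c.get("lambda", 0.01), j=c.get("J", 5.0),
                            lambda_c=c.get("lambda_c", 1.33e5), a_h=c.get("A_h", 50.0),
                            t=c.get("T", 50.0),
                            neighborhood_order=c.get("neighborhood", "moore"))
        f = d.get("fa", {})
        cfg.fa = FAParams(gamma=f.get("gamma", 2.88), d0=f.get("d0", 0.0288),
                          f_star=f.get("f_star", 1.29e10) * PER_N_TO_PER_NN,
                          phi_s=f.get("phi_s", 4.02), phi_c=f.get("phi_c", 7.76),
                          n_tot=f.get("N_tot", 390.0), n_0=f.get("N_0", 25.0),
                          n_h=f.get("N_h", 100.0), lambda_fa=f.get("lambda_FA", 800.0),
                          k_cyto=f.get("K_cyto", 3.1e-4) * N_PER_M_TO_NN_PER_UM,
                          tension_source=f.get("tension_source", "ecm"))
        n = d.get("network", {})
        cfg.network = NetworkParams(
            k_polymer=n.get("K", 3.1e-2) * N_PER_M_TO_NN_PER_UM,
            k_bend=n.get("K_bend", 3.88e-15) * J_TO_FJ,
            theta_0=n.get("theta_0", np.pi),
            fiber_density=n.get("fiber_density", 0.48),
            kappa=n.get("kappa", 0.0), mu=n.get("mu", 0.0),
            n_beads=n.get("n_beads", 31), r_polymer=n.get("r_polymer", 0.4),
            crosslink_density=n.get("crosslink_density", 1.2),
            grid_spacing=n.get("grid_spacing", 2.0))
        m = d.get("mechanics", {})
        cfg.mechanics = MechanicsParams(t_ecm=m.get("T_ECM", 0.001),
                                        gamma_drag=m.get("gamma_drag", 1.0),
                                        max_steps=m.get("max_steps", 10_000),
                                        force_tol=m.get("force_tol", 1e-4))
        s = d.get("schedule", {})
        cfg.schedule = Schedule(**{k: s[k] for k in
                                   ("n_steps", "relax_every", "output_every",
                                    "audit_every", "initial_relax_steps") if k in s})
        cfg.__post_init__()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimulationState:
    spin: SpinField
    network: FiberNetwork
    registry: FARegistry
    center: np.ndarray                   # cell centroid [um]
    step: int = 0
    _adjacency: dict[int, np.ndarray] = field(default_factory=dict)

    def attached_bonds(self, bead: int) -> np.ndarray:
        adj = self._adjacency.get(bead)
        if adj is None:
            adj = np.flatnonzero((self.network.bond_i == bead) |
                                 (self.network.bond_j == bead))
            self._adjacency[bead] = adj
        return adj

    def audit(self) -> None:
        self.registry.audit(self.network)
        mask = self.spin.mask()
        for fa in self.registry:
            if not mask[fa.site]:
                raise RuntimeError(f"FA {fa.id} site {fa.site} outside the cell")


class Trajectory:
    """Time-indexed record of a run: masks, adhesion tables, bead positions,
    and scalar metrics (one row per recorded step)."""

    def __init__(self) -> None:
        self.times: list[int] = []
        self.masks: list[np.ndarray] = []
        self.bead_positions: list[np.ndarray] = []
        self.fa_tables: list[pd.DataFrame] = []
        self._metrics: list[dict] = []
        self.final_state: SimulationState | None = None

    def record(self, state: SimulationState, config: SimulationConfig) -> None:
        self.times.append(state.step)
        if config.store_masks:
            self.masks.append(state.spin.mask().copy())
        if config.store_beads:
            self.bead_positions.append(state.network.positions.copy())
        fas = list(state.registry)
        self.fa_tables.append(pd.DataFrame({
            "id": [fa.id for fa in fas],
            "site_x": [fa.site[0] for fa in fas],
            "site_y": [fa.site[1] for fa in fas],
            "bead_id": [fa.bead_id for fa in fas],
            "N": [fa.n for fa in fas],
            "Phi_nN": [fa.phi for fa in fas],
        }))
        phis = np.array([fa.phi for fa in fas])
        ns = np.array([fa.n for fa in fas])
        self._metrics.append({
            "step": state.step,
            "area_sites": state.spin.area,
            "n_fa": len(fas),
            "mean_phi_nN": float(phis.mean()) if len(fas) else 0.0,
            "median_phi_nN": float(np.median(phis)) if len(fas) else 0.0,
            "mean_n": float(ns.mean()) if len(fas) else 0.0,
        })

    @property
    def metrics(self) -> pd.DataFrame:
        return pd.DataFrame(self._metrics)

    def __len__(self) -> int:
        return len(self.times)


def build_network(config: SimulationConfig, rng: np.random.Generator) -> FiberNetwork:
    params = config.network
    if config.scenario == "grid":
        return generate_grid_network(params)
    if config.scenario == "anisotropic" and params.kappa == 0.0:
        params = dc_replace(params, kappa=10.0)
    elif config.scenario == "isotropic":
        params = dc_replace(params, kappa=0.0)
    return generate_random_network(params, rng)


def initialize(config: SimulationConfig,
               network: FiberNetwork | None = None) -> tuple[SimulationState, dict]:
    """Build the coupled initial state and the per-submodel RNG streams."""
    ss = np.random.SeedSequence(config.seed)
    kids = ss.spawn(3)
    rngs = {"cpm": np.random.default_rng(kids[0]),
            "network": np.random.default_rng(kids[1]),
            "ecm": np.random.default_rng(kids[2])}
    if network is None:
        network = build_network(config, rngs["network"])
        if config.schedule.initial_relax_steps > 0:
            settle = dc_replace(config.mechanics,
                                max_steps=config.schedule.initial_relax_steps)
            relax(network, settle, rng=rngs["ecm"], in_place=True)
    spin = SpinField.from_disc(config.lattice_size, config.cell_radius)
    state = SimulationState(spin=spin, network=network,
                            registry=FARegistry(config.fa),
                            center=spin.center_of_mass())
    _update_tensions(state, config)
    return state, rngs


def _update_tensions(state: SimulationState, config: SimulationConfig) -> None:
    fas = list(state.registry)
    if not fas:
        return
    if config.fa.tension_source == "ecm":
        f = forces(state.network)
        for fa in fas:
            fa.phi = float(np.hypot(*f[fa.bead_id]))
    else:
        for fa in fas:
            fa.phi = fa_tension(fa, state.center, config.fa)


def simulation_step(state: SimulationState,
                    config: SimulationConfig,
                    rngs: dict,
                    collect_events: bool = False):
    """Advance the coupled model by one Monte Carlo step (2.88 s)."""
    _, events = monte_carlo_step(state.spin, state.network, state.registry,
                                 config.cpm, config.fa, rngs["cpm"],
                                 collect_events=collect_events)
    if state.spin.area > 0:
        state.center = state.spin.center_of_mass()
    mask = state.spin.mask()
    for fa in sorted(state.registry, key=lambda f: f.id):
        displace_fa(fa, state.network, state.center, config.fa,
                    registry=state.registry,
                    attached=state.attached_bonds(fa.bead_id),
                    cell_mask=mask)
    state.step += 1
    if state.step % config.schedule.relax_every == 0:
        relax(state.network, config.mechanics,
              pinned=state.network.fa_bound, rng=rngs["ecm"], in_place=True)
    _update_tensions(state, config)
    for fa in state.registry:
        fa.n = integrate_integrins(fa.n, fa.phi, config.fa)
    if config.schedule.audit_every and state.step % config.schedule.audit_every == 0:
        state.audit()
    return state, events


def run_simulation(config: SimulationConfig,
                   network: FiberNetwork | None = None) -> Trajectory:
    """Initialize a scenario and iterate the coupled loop, recording outputs."""
    state, rngs = initialize(config, network=network)
    traj = Trajectory()
    traj.record(state, config)
    for step in range(config.schedule.n_steps):
        simulation_step(state, config, rngs)
        if state.step % config.schedule.output_every == 0 or \
                state.step == config.schedule.n_steps:
            traj.record(state, config)
        if state.step % max(1, config.schedule.n_steps // 10) == 0:
            logger.info("step %d/%d area=%d FAs=%d", state.step,
                        config.schedule.n_steps, state.spin.area,
                        len(state.registry))
    traj.final_state = state
    return traj
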