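"""Preconfigured experiment designs: stiffness sweeps, isotropy comparison,
remodeling-onset runs and displacement-vs-cross-linking sweeps.

Two problem scales are provided.  ``full`` mirrors the study conditions
(200x200 lattice = 50x50 um, 1e4 steps ~ 8 h); ``desk`` shrinks the arena
to 120x120 sites (30x30 um) around the same 5-um cell, runs 400 steps and
caps each gel relaxation at 150 sub-steps, which preserves every mechanism
(adhesion maturation needs only the ~1 nN tensions reached at this size)
while a single run completes in seconds.  All sweeps return tidy pandas
DataFrames with one row per run.
"""

from __future__ import annotations

from dataclasses import replace as dc_replace

import numpy as np
import pandas as pd

from .analysis import cell_eccentricity, fa_angle_histogram, mean_displacement
from .mechanics import MechanicsParams
from .network import NetworkParams
from .simulation import Schedule, SimulationConfig, run_simulation
from .units import N_PER_M_TO_NN_PER_UM

#: ECM spring stiffness values [N/m] spanning soft to stiff collagen.
STIFFNESS_SWEEP_N_PER_M = (0.002, 0.008, 0.031, 0.124, 0.496)

#: Cross-link densities [um^-2] spanning sparse to dense gels.
CROSSLINK_SWEEP_PER_UM2 = (0.24, 1.2, 4.8)


def desk_config(scenario: str = "isotropic", seed: int = 0,
                n_steps: int = 400, **overrides) -> SimulationConfig:
    """Scaled-down configuration: 30x30 um arena, 5-um cell, short run."""
    cfg = SimulationConfig(
        lattice_size=100, cell_radius=20.0, scenario=scenario, seed=seed,
        mechanics=MechanicsParams(force_tol=0.05, max_steps=300),
        schedule=Schedule(n_steps=n_steps, relax_every=1, output_every=5,
                          audit_every=10, initial_relax_steps=1_500),
        store_masks=True, store_beads=True)
    cfg.network = dc_replace(cfg.network, grid_spacing=2.5)  # divides 25 um
    for key, val in overrides.items():
        setattr(cfg, key, val)
    cfg.__post_init__()
    return cfg


def full_config(scenario: str = "isotropic", seed: int = 0,
                **overrides) -> SimulationConfig:
    """Study-scale configuration: 50x50 um arena, 1e4 steps."""
    cfg = SimulationConfig(lattice_size=200, cell_radius=20.0,
                           scenario=scenario, seed=seed)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    cfg.__post_init__()
    return cfg


def _with_stiffness(cfg: SimulationConfig, k_n_per_m: float) -> SimulationConfig:
    cfg.network = dc_replace(cfg.network,
                             k_polymer=k_n_per_m * N_PER_M_TO_NN_PER_UM,
                             k_cross=None)
    return cfg


def spreading_vs_stiffness(k_values_n_per_m=STIFFNESS_SWEEP_N_PER_M,
                           seeds=(0, 1, 2), scenario: str = "grid",
                           scale: str = "desk", n_steps: int = 400) -> pd.DataFrame:
    """Final area change vs fiber spring stiffness (biphasic on stiff gels)."""
    rows = []
    for k in k_values_n_per_m:
        for seed in seeds:
            maker = desk_config if scale == "desk" else full_config
            cfg = maker(scenario=scenario, seed=seed, n_steps=n_steps) \
                if scale == "desk" else maker(scenario=scenario, seed=seed)
            _with_stiffness(cfg, k)
            traj = run_simulation(cfg)
            m = traj.metrics
            rows.append({"K_N_per_m": k, "seed": seed,
                         "area_initial": int(m["area_sites"].iloc[0]),
                         "area_final": int(m["area_sites"].iloc[-1]),
                         "area_change": int(m["area_sites"].iloc[-1] -
                                            m["area_sites"].iloc[0]),
                         "median_phi_nN": m["median_phi_nN"].iloc[-1],
                         "n_fa_final": int(m["n_fa"].iloc[-1])})
    return pd.DataFrame(rows)


def isotropy_comparison(kappas=(0.0, 10.0), seeds=(0, 1, 2),
                        k_n_per_m: float = 0.016,
                        crosslink_density: float = 0.48,
                        scale: str = "desk",
                        n_steps: int = 400) -> pd.DataFrame:
    """Cell eccentricity and adhesion angles on isotropic vs aligned gels.

    Defaults are the elongation condition: soft fibers (0.016 N/m) and light
    cross-linking (0.48 um^-2) -- stiff or densely linked gels resist the
    cell's pull in every direction and suppress the alignment response.
    """
    rows = []
    for kappa in kappas:
        for seed in seeds:
            scenario = "anisotropic" if kappa > 0 else "isotropic"
            maker = desk_config if scale == "desk" else full_config
            cfg = maker(scenario=scenario, seed=seed, n_steps=n_steps) \
                if scale == "desk" else maker(scenario=scenario, seed=seed)
            cfg.network = dc_replace(cfg.network, kappa=kappa,
                                     crosslink_density=crosslink_density)
            _with_stiffness(cfg, k_n_per_m)
            traj = run_simulation(cfg)
            mask = traj.masks[-1]
            ecc = cell_eccentricity(mask)
            fa_table = traj.fa_tables[-1]
            angles = (fa_angle_histogram(fa_table, traj.final_state.center)
                      if len(fa_table) else np.array([]))
            rows.append({"kappa": kappa, "seed": seed, "eccentricity": ecc,
                         "area_final": int(mask.sum()),
                         "n_fa": len(fa_table),
                         "mean_abs_fa_angle": (float(np.abs(angles).mean())
                                               if len(angles) else np.nan)})
    return pd.DataFrame(rows)


def displacement_vs_crosslinking(densities=CROSSLINK_SWEEP_PER_UM2,
                                 seeds=(0, 1), scale: str = "desk",
                                 n_steps: int = 400) -> pd.DataFrame:
    """Mean bead displacement after the run vs cross-link density (biphasic)."""
    rows = []
    for rho in densities:
        for seed in seeds:
            maker = desk_config if scale == "desk" else full_config
            cfg = maker(scenario="isotropic", seed=seed, n_steps=n_steps) \
                if scale == "desk" else maker(scenario="isotropic", seed=seed)
            cfg.network = dc_replace(cfg.network, crosslink_density=rho)
            traj = run_simulation(cfg)
            disp = mean_displacement(traj.bead_positions[0],
                                     traj.bead_positions[-1],
                                     clamped=traj.final_state.network.clamped)
            rows.append({"crosslink_density": rho, "seed": seed,
                         "mean_displacement_um": disp,
                         "area_final": int(traj.masks[-1].sum())})
    return pd.DataFrame(rows)


def remodeling_run(seed: int = 0, scale: str = "desk",
                   n_steps: int = 400, kappa: float = 0.0):
    """Single run recorded densely for the onset-lag analysis."""
    maker = desk_config if scale == "desk" else full_config
    cfg = maker(scenario="isotropic" if kappa == 0 else "anisotropic",
                seed=seed, n_steps=n_steps) if scale == "desk" else \
        maker(scenario="isotropic" if kappa == 0 else "anisotropic", seed=seed)
    cfg.schedule.output_every = 1
    cfg.network = dc_replace(cfg.network, kappa=kappa)
    return run_simulation(cfg)
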