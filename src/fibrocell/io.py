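"""Plain-text state I/O: network CSV trio, legacy-VTK polydata, cell-mask
CSV/PGM snapshots, adhesion tables and per-step metrics."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .network import FiberNetwork


def write_network_csv(network: FiberNetwork, directory) -> None:
    """Write beads.csv / bonds.csv / angles.csv into ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "id": np.arange(network.n_beads),
        "x": network.positions[:, 0], "y": network.positions[:, 1],
        "clamped": network.clamped.astype(int),
        "fiber_id": network.fiber_id,
        "fa_bound": network.fa_bound.astype(int),
    }).to_csv(d / "beads.csv", index=False)
    pd.DataFrame({
        "i": network.bond_i, "j": network.bond_j,
        "k_stiff": network.bond_k, "rest": network.bond_rest,
        "is_crosslink": network.is_crosslink.astype(int),
    }).to_csv(d / "bonds.csv", index=False)
    pd.DataFrame({
        "i": network.angle_i, "j": network.angle_j, "k": network.angle_k,
        "k_bend": network.angle_kbend, "theta_0": network.angle_theta0,
    }).to_csv(d / "angles.csv", index=False)
    with open(d / "domain.txt", "w") as fh:
        fh.write(f"{network.domain[0]} {network.domain[1]}\n")


def read_network_csv(directory) -> FiberNetwork:
    d = Path(directory)
    beads = pd.read_csv(d / "beads.csv")
    bonds = pd.read_csv(d / "bonds.csv")
    angles = pd.read_csv(d / "angles.csv")
    with open(d / "domain.txt") as fh:
        lx, ly = (float(v) for v in fh.read().split())
    return FiberNetwork(
        positions=beads[["x", "y"]].to_numpy(),
        bond_i=bonds["i"].to_numpy(), bond_j=bonds["j"].to_numpy(),
        bond_k=bonds["k_stiff"].to_numpy(), bond_rest=bonds["rest"].to_numpy(),
        is_crosslink=bonds["is_crosslink"].to_numpy().astype(bool),
        angle_i=angles["i"].to_numpy(), angle_j=angles["j"].to_numpy(),
        angle_k=angles["k"].to_numpy(),
        angle_kbend=angles["k_bend"].to_numpy(),
        angle_theta0=angles["theta_0"].to_numpy(),
        clamped=beads["clamped"].to_numpy().astype(bool),
        fiber_id=beads["fiber_id"].to_numpy(),
        fa_bound=beads["fa_bound"].to_numpy().astype(bool),
        domain=(lx, ly))


def write_network_vtk(network: FiberNetwork, path) -> None:
    """Legacy-VTK polydata (ASCII) with bonds as lines, for visualization."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfiber network\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {network.n_beads} float\n")
        for x, y in network.positions:
            fh.write(f"{x:.6f} {y:.6f} 0.0\n")
        m = network.n_bonds
        fh.write(f"LINES {m} {3 * m}\n")
        for i, j in zip(network.bond_i, network.bond_j):
            fh.write(f"2 {i} {j}\n")
        fh.write(f"CELL_DATA {m}\nSCALARS is_crosslink int 1\nLOOKUP_TABLE default\n")
        for c in network.is_crosslink:
            fh.write(f"{int(c)}\n")


def write_mask_csv(mask: np.ndarray, path) -> None:
    """Cell sites as x,y rows."""
    xs, ys = np.nonzero(mask)
    pd.DataFrame({"x": xs, "y": ys}).to_csv(path, index=False)


def write_mask_pgm(mask: np.ndarray, path) -> None:
    """Portable graymap (P2, ASCII) snapshot of the cell mask."""
    grid = (np.asarray(mask).T.astype(int)[::-1]) * 255   # image rows top-down
    with open(path, "w") as fh:
        fh.write(f"P2\n{grid.shape[1]} {grid.shape[0]}\n255\n")
        for row in grid:
            fh.write(" ".join(str(v) for v in row) + "\n")


def write_fa_table(fa_table: pd.DataFrame, path) -> None:
    fa_table.to_csv(path, index=False)


def write_metrics(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, index=False)
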