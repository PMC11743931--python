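"""Measurement statistics: fiber order, cell shape, adhesion geometry,
spreading/alignment onset timing, and gel displacement.

The nematic order parameter S quantifies apolar alignment of fiber
segments: S = |<e^(2 i theta)>| (length-weighted), 0 for an isotropic gel
and 1 for perfectly parallel segments.  Cell shape is summarized by the
eccentricity of the covariance ellipse of the occupied lattice sites.  To
resolve when a region of the gel aligns relative to when the cell spreads
into it, the domain is tiled into 5x5-site bins and both the per-bin order
S_i(t) and the cell-occupancy fraction C_i(t) are smoothed with a trailing
10-step mean and fitted with a logistic sigmoid; the onset-time difference
t0_cell - t0_S is positive where remodeling precedes spreading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .network import FiberNetwork
from .units import LATTICE_SPACING_UM

BIN_SITES = 5           # bin edge length in lattice sites
SMOOTH_WINDOW = 10      # trailing moving-average window [steps]


def order_parameter(angles: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Nematic scalar S in [0, 1] of apolar segment orientations.

    Raises on empty input -- an undefined S is flagged, never silently 0.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("order parameter of zero segments is undefined")
    if weights is None:
        weights = np.ones_like(angles)
    w = np.asarray(weights, dtype=float)
    z = np.sum(w * np.exp(2j * angles)) / w.sum()
    return float(np.abs(z))


def cell_eccentricity(mask: np.ndarray) -> float:
    """Eccentricity of the site-center covariance ellipse, in [0, 1].

    e = sqrt(1 - l2/l1) with l1 >= l2 the covariance eigenvalues; a disc
    gives ~0, a one-site-wide line exactly 1, a single site 0 by convention.
    """
    xs, ys = np.nonzero(mask)
    if len(xs) == 0:
        raise ValueError("empty mask has no shape")
    if len(xs) == 1:
        return 0.0
    cov = np.cov(np.vstack([xs, ys]))
    l2, l1 = np.sort(np.linalg.eigvalsh(cov))
    if l1 <= 0:
        return 0.0
    return float(np.sqrt(1.0 - max(l2, 0.0) / l1))


def fold_nematic(angle: float | np.ndarray) -> np.ndarray:
    """Fold angles to the nematic half-circle (-pi/2, pi/2]."""
    a = np.mod(np.asarray(angle, dtype=float), np.pi)
    return np.where(a > np.pi / 2, a - np.pi, a)


def fa_angle_histogram(fa_table: pd.DataFrame,
                       cell_center: np.ndarray,
                       reference_axis: float = 0.0) -> np.ndarray:
    """Per-adhesion acute signed angle between the center->FA direction and
    a reference axis, folded to (-pi/2, pi/2].

    Adhesions at the exact center are excluded (bearing undefined).
    ``cell_center`` is in um; adhesion positions come from their lattice sites.
    """
    if len(fa_table) == 0:
        raise ValueError("no adhesions to measure")
    px = (fa_table["site_x"].to_numpy() + 0.5) * LATTICE_SPACING_UM
    py = (fa_table["site_y"].to_numpy() + 0.5) * LATTICE_SPACING_UM
    dx, dy = px - cell_center[0], py - cell_center[1]
    r = np.hypot(dx, dy)
    keep = r > 1e-12
    bearing = np.arctan2(dy[keep], dx[keep]) - reference_axis
    return fold_nematic(bearing)


def moving_average(series: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Causal trailing mean over the past ``window`` samples (shorter at the start)."""
    series = np.asarray(series, dtype=float)
    out = np.empty_like(series)
    csum = np.concatenate([[0.0], np.nancumsum(series)])
    for t in range(len(series)):
        lo = max(0, t - window + 1)
        out[t] = (csum[t + 1] - csum[lo]) / (t + 1 - lo)
    return out


@dataclass
class BinnedSeries:
    """Per-bin nematic order S_i(t) and cell occupancy C_i(t), smoothed."""

    times: np.ndarray          # (T,)
    s: np.ndarray              # (n_bins_x, n_bins_y, T); NaN where no segments
    c: np.ndarray              # (n_bins_x, n_bins_y, T) in [0, 1]
    bin_centers_um: np.ndarray  # (n_bins_x, n_bins_y, 2)


def binned_series(times, masks, bead_positions_list, network: FiberNetwork,
                  window: int = SMOOTH_WINDOW) -> BinnedSeries:
    """Per-bin order/occupancy time series from a recorded trajectory.

    Segments are assigned to bins by midpoint and weighted by length; bins
    with no segments at a time point carry NaN for S.  Both series get the
    trailing ``window``-step mean.
    """
    lsize = masks[0].shape[0]
    nb = lsize // BIN_SITES
    T = len(times)
    s = np.full((nb, nb, T), np.nan)
    c = np.zeros((nb, nb, T))
    sel = ~network.is_crosslink
    bi, bj = network.bond_i[sel], network.bond_j[sel]
    bin_um = BIN_SITES * LATTICE_SPACING_UM
    for t in range(T):
        pos = bead_positions_list[t]
        a, b = pos[bi], pos[bj]
        mid = (a + b) / 2.0
        d = b - a
        lengths = np.hypot(d[:, 0], d[:, 1])
        angles = np.arctan2(d[:, 1], d[:, 0])
        gx = np.floor(mid[:, 0] / bin_um).astype(int)
        gy = np.floor(mid[:, 1] / bin_um).astype(int)
        ok = (gx >= 0) & (gx < nb) & (gy >= 0) & (gy < nb)
        lin = gx[ok] * nb + gy[ok]
        wre = np.bincount(lin, weights=lengths[ok] * np.cos(2 * angles[ok]),
                          minlength=nb * nb)
        wim = np.bincount(lin, weights=lengths[ok] * np.sin(2 * angles[ok]),
                          minlength=nb * nb)
        wtot = np.bincount(lin, weights=lengths[ok], minlength=nb * nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            si = np.hypot(wre, wim) / wtot
        s[:, :, t] = si.reshape(nb, nb)
        m = masks[t][:nb * BIN_SITES, :nb * BIN_SITES]
        c[:, :, t] = m.reshape(nb, BIN_SITES, nb, BIN_SITES).mean(axis=(1, 3))
    for i in range(nb):
        for j in range(nb):
            c[i, j] = moving_average(c[i, j], window)
            if not np.all(np.isnan(s[i, j])):
                s[i, j] = moving_average(np.nan_to_num(s[i, j], nan=np.nanmean(s[i, j])),
                                         window)
    centers = np.empty((nb, nb, 2))
    for i in range(nb):
        for j in range(nb):
            centers[i, j] = ((i + 0.5) * bin_um, (j + 0.5) * bin_um)
    return BinnedSeries(np.asarray(times, dtype=float), s, c, centers)


@dataclass
class SigmoidFit:
    l: float = np.nan          # plateau
    k: float = np.nan          # rate
    t0: float = np.nan         # onset time
    rss: float = np.nan
    ok: bool = False


def _sigmoid(t, l, k, t0):
    return l / (1.0 + np.exp(-np.clip(k * (t - t0), -500, 500)))


def fit_sigmoid(times: np.ndarray, series: np.ndarray) -> SigmoidFit:
    """Least-squares logistic fit f(t) = L / (1 + exp(-k (t - t0))).

    Initialization: L = series max, t0 = first half-max crossing, k = 4 over
    the 10-90% rise interval; k is bounded positive and t0 to the observed
    range extended by one smoothing window.  Flat or non-converging series
    return ``ok = False``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(series, dtype=float)
    keep = ~np.isnan(y)
    t, y = t[keep], y[keep]
    if len(y) < 4 or np.ptp(y) < 1e-9:
        return SigmoidFit()
    l0 = y.max()
    half = np.flatnonzero(y >= l0 / 2.0)
    t0_0 = t[half[0]] if len(half) else t[len(t) // 2]
    above = np.flatnonzero(y >= 0.9 * l0)
    below = np.flatnonzero(y <= 0.1 * l0)
    rise = (t[above[0]] - t[below[-1]]) if len(above) and len(below) and \
        t[above[0]] > t[below[-1]] else (t[-1] - t[0]) / 4.0
    k0 = 4.0 / max(rise, (t[1] - t[0]))
    lo = [1e-12, 1e-9, t[0] - SMOOTH_WINDOW * (t[1] - t[0])]
    hi = [2.0 * l0 + 1e-9, np.inf, t[-1] + SMOOTH_WINDOW * (t[1] - t[0])]
    try:
        popt, _ = curve_fit(_sigmoid, t, y, p0=[l0, k0, t0_0],
                            bounds=(lo, hi), maxfev=10_000)
    except (RuntimeError, ValueError):
        return SigmoidFit()
    resid = y - _sigmoid(t, *popt)
    return SigmoidFit(l=float(popt[0]), k=float(popt[1]), t0=float(popt[2]),
                      rss=float(np.sum(resid**2)), ok=True)


def onset_lag(times: np.ndarray, s_series: np.ndarray,
              c_series: np.ndarray) -> float:
    """Onset-time difference t0_cell - t0_S for one bin; NaN if either fit fails."""
    fs = fit_sigmoid(times, s_series)
    fc = fit_sigmoid(times, c_series)
    if not (fs.ok and fc.ok):
        return float("nan")
    return fc.t0 - fs.t0


def onset_lags(binned: BinnedSeries, min_c_rise: float = 0.2,
               min_s_rise: float = 0.05) -> np.ndarray:
    """Onset lags over all bins where both signals actually transition.

    Bins whose occupancy never rises by ``min_c_rise`` (the cell never
    spreads there) or whose order never changes by ``min_s_rise`` are
    uninformative and skipped.
    """
    lags = []
    nb = binned.s.shape[0]
    for i in range(nb):
        for j in range(nb):
            cseries = binned.c[i, j]
            sseries = binned.s[i, j]
            if np.ptp(cseries) < min_c_rise or cseries[0] > 0.5:
                continue
            if np.all(np.isnan(sseries)) or \
                    np.nanmax(sseries) - np.nanmin(sseries) < min_s_rise:
                continue
            lag = onset_lag(binned.times, sseries - np.nanmin(sseries), cseries)
            if not np.isnan(lag):
                lags.append(lag)
    return np.array(lags)


def annulus_alignment(binned_s_final: np.ndarray,
                      bin_centers_um: np.ndarray,
                      cell_center_um: np.ndarray,
                      cell_length_um: float) -> float:
    """Mean final-time order over bins with r < |x_i - c| < 1.5 r, r = cell length.

    Raises if the annulus contains no bin centers (e.g. beyond the domain).
    """
    d = np.hypot(bin_centers_um[:, :, 0] - cell_center_um[0],
                 bin_centers_um[:, :, 1] - cell_center_um[1])
    sel = (d > cell_length_um) & (d < 1.5 * cell_length_um)
    vals = binned_s_final[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no bins fall in the annulus")
    return float(vals.mean())


def cell_length_um(mask: np.ndarray) -> float:
    """Major-axis length of the mask (4 sigma of the leading eigenvalue), um."""
    xs, ys = np.nonzero(mask)
    if len(xs) < 2:
        return LATTICE_SPACING_UM
    cov = np.cov(np.vstack([xs, ys]))
    l1 = float(np.linalg.eigvalsh(cov)[-1])
    return 4.0 * np.sqrt(max(l1, 0.0)) * LATTICE_SPACING_UM


def mean_displacement(network_t0: FiberNetwork | np.ndarray,
                      network_t: FiberNetwork | np.ndarray,
                      clamped: np.ndarray | None = None) -> float:
    """Mean Euclidean displacement of non-clamped beads [um]."""
    p0 = network_t0.positions if isinstance(network_t0, FiberNetwork) else np.asarray(network_t0)
    p1 = network_t.positions if isinstance(network_t, FiberNetwork) else np.asarray(network_t)
    if p0.shape != p1.shape:
        raise ValueError("bead sets differ between the two states")
    if clamped is None and isinstance(network_t0, FiberNetwork):
        clamped = network_t0.clamped
    free = ~clamped if clamped is not None else np.ones(len(p0), dtype=bool)
    d = np.linalg.norm(p1[free] - p0[free], axis=1)
    return float(d.mean())
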