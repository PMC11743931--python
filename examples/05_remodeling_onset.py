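"""Fiber remodeling precedes local cell spreading.

The domain is tiled into 5x5-site bins; for each bin the local nematic
order of the fibers S_i(t) and the cell occupancy C_i(t) are tracked,
smoothed with a trailing 10-step mean, and fitted with logistic sigmoids.
The onset-time difference t0_cell - t0_S measures whether the gel in a
bin aligns before the cell spreads into it; a majority-positive lag
distribution is the signature of mechanical reciprocity: the cell's pull
reorients fibers ahead of its advancing edge, and the remodeled, stiffer-
feeling gel then stabilizes the protrusion that grows over it.
"""

import numpy as np

from fibrocell.analysis import binned_series, onset_lags
from fibrocell.experiments import remodeling_run

traj = remodeling_run(seed=0, n_steps=400)
binned = binned_series(traj.times, traj.masks, traj.bead_positions,
                       traj.final_state.network)
lags = onset_lags(binned)

print(f"bins with a spreading transition and a usable order signal: {len(lags)}")
if len(lags):
    frac = float(np.mean(lags > 0))
    print(f"onset lags t0_cell - t0_S [steps]: median {np.median(lags):.0f}, "
          f"positive fraction {frac:.2f}")
    print("positive lag = the gel in that bin aligned before the cell arrived.")
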