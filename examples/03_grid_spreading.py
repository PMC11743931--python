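"""Stiffness-dependent cell spreading on a regular fiber lattice.

A 5-um contractile cell is placed on a regular grid of cross-linked
fibers and simulated at three spring stiffnesses.  On soft gels adhesions
never build tension and dissolve (catch regime); at intermediate stiffness
they mature and ratchet the cell outward; on very stiff gels per-integrin
tension overshoots into the slip regime and adhesions break, so spreading
drops again -- the biphasic response.
"""

import time

from fibrocell.experiments import desk_config, _with_stiffness
from fibrocell.simulation import run_simulation

print("K [N/m]   area t=0   area final   adhesions   median tension [nN]")
for k in (0.002, 0.031, 0.496):
    cfg = desk_config(scenario="grid", seed=0, n_steps=400)
    cfg.store_beads = False
    _with_stiffness(cfg, k)
    t0 = time.time()
    m = run_simulation(cfg).metrics
    print(f"{k:7.3f}   {m.area_sites.iloc[0]:8d}   {m.area_sites.iloc[-1]:10d}"
          f"   {m.n_fa.iloc[-1]:9d}   {m.median_phi_nN.iloc[-1]:10.2f}"
          f"     ({time.time() - t0:.0f} s)")

print("\nArea change peaks at intermediate stiffness: adhesion tension must be"
      "\nlarge enough to stabilize integrin clusters yet below the slip regime.")
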