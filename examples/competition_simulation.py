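"""Scaled-down mechanical competition between two cell types.

Two populations collide along straight interfaces (periodic in x): type A
with strong cell-cell adhesion, type B with 8x weaker cell-cell adhesion.
The monolayer is overcrowded (homeostatic compression) and active, so cells
are occasionally squeezed out of the plane - extrusion is emergent, no rule
removes cells.  The run reports where the weak-adhesion type is extruded
relative to the interface and where the in-plane stress fluctuations
(susceptibility) concentrate.

Runtime: a few minutes on one CPU.  Pass a different seed as argv[1].
"""

import sys

import numpy as np

from mechcomp import phasefield as pf
from mechcomp import stress_stats as ss

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
cfg = pf.two_type_competition_config(seed=seed)
print(f"grid {cfg.grid.shape}, {cfg.n_cell} cells, {cfg.n_sim} steps, "
      f"adhesion A:B = {cfg.type_params['A'].omega_cc:.4f}:{cfg.type_params['B'].omega_cc:.4f}")
traj = pf.run_simulation(cfg)

ev = traj.events
print(f"\nextrusions: {len(ev)} total "
      f"(winner type A: {(ev['type'] == 1).sum()}, loser type B: {(ev['type'] == 2).sum()})")
for _, e in ev.iterrows():
    occ = traj.occupancy_frames[int(e["frame"])]
    dist = ss.interface_distance_map(occ)
    d = dist[int(round(e["y"])) % occ.shape[0], int(round(e["x"])) % occ.shape[1]]
    print(f"  step {int(e['step']):5d}  type {'A' if e['type'] == 1 else 'B'}  "
          f"({e['x']:5.1f}, {e['y']:5.1f})  {d / cfg.R0:.1f} R0 from the interface")

burn = traj.occupancy_frames.shape[0] // 3
prof = ss.susceptibility_profile(
    traj.iso_stress_frames[burn:], traj.occupancy_frames[burn:], bin_width=cfg.R0 / 2
)
print("\nper-pixel susceptibility of the in-plane isotropic stress vs distance "
      "from the interface (bins of R0/2):")
for t, name in ((1, "A"), (2, "B")):
    vals = prof[t].values / np.maximum(prof[t].counts, 1)
    vals = np.where(prof[t].counts > 50, vals, np.nan)
    peak = int(np.nanargmax(vals))
    row = "  ".join("nan" if np.isnan(v) else f"{v:.2e}" for v in vals[:6])
    print(f"  type {name}: {row}   peak in bin {peak} "
          f"({'interface' if peak == 0 else f'{peak * 0.5:.1f} R0 away'})")
print("\nA susceptibility peak in the interface bin reproduces the fluctuation "
      "localization that drives elimination of the weak-adhesion type.")
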