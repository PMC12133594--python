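"""Work to eliminate a cell along the cylinder -> cone -> sphere path, and
the win/lose phase diagram over adhesion differences.

All shapes share the volume (4/3) pi 10^3 ~ 4188.8 um^3.  DeltaW > 0 means
the focal type is harder to eliminate at the interface (it wins); the
quadrant with a cell-cell adhesion advantage but a cell-substrate deficit
still contains a win region, which is the model's central qualitative claim.
"""

import numpy as np

from mechcomp import energetics as en

seq = en.ShapeSequence(r_a=10.0, r_s=10.0)
print(f"conserved volume: {seq.volume:.1f} um^3")
for shape, r_b in [("cylinder", 10.0), ("frustum", 5.0), ("frustum", 0.0), ("sphere", 0.0)]:
    a_s, a_cc, a_tot = en.shape_areas(shape, r_b, seq)
    print(f"  {shape:8s} r_b={r_b:5.1f}: A_s={a_s:7.1f}  A_cc={a_cc:7.1f}  A_tot={a_tot:7.1f} um^2")

params = en.AdhesionEnergetics(
    omega_s_I=0.3, omega_s_II=0.6,  # focal type I adheres less to the substrate
    omega_c_I=0.9, omega_c_II=0.2,  # but much more to its own kind
    k_I=1.0, k_II=1.0,
)
w_I = en.elimination_work(params, seq, focal="I")
w_II = en.elimination_work(params, seq, focal="II")
print(f"\nwork to eliminate type I:  {w_I['dW']:8.1f}  (substrate {w_I['substrate_term']:7.1f},"
      f" cell-cell {w_I['cell_cell_term']:7.1f}, tension {w_I['tension_term']:7.1f})")
print(f"work to eliminate type II: {w_II['dW']:8.1f}")
print("type", "I" if w_I["dW"] > w_II["dW"] else "II", "wins (harder to eliminate)")

d = np.linspace(-1.0, 1.0, 51)
pd = en.phase_diagram(d, d)
dw = pd["delta_W"]
win = (pd["delta_omega_cc"] > 0) & (pd["delta_omega_cs"] < 0) & (dw > 0)
print(f"\nphase diagram 51x51: DeltaW range [{dw.min():.2f}, {dw.max():.2f}] (units of |dW0_k|)")
print(f"win-despite-substrate-deficit region: {win.sum()} grid points "
      f"({100 * win.sum() / win.size:.0f}% of the diagram)")
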