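# mechcomp — mechanics of cell competition

When two epithelial cell populations with different adhesion machinery meet
— for example wild-type cells against neighbours that have lost E-cadherin —
one population is progressively eliminated by apical extrusion at the shared
interface. `mechcomp` is a Python toolkit for studying the mechanical basis
of that competition:

* **`mechcomp.phasefield`** — a 3D multiphase-field simulator of an active
  cell monolayer on a rigid substrate. Each cell is a deformable field
  `phi_i` relaxing by Ginzburg–Landau dynamics
  `d(phi_i)/dt + v_i . grad(phi_i) = -Gamma dF/dphi_i`, with per-type
  cortex tension, volume constraint, cell–cell and cell–substrate
  repulsion/adhesion, active shape and substrate stresses, self-propulsion
  with contact-inhibition-of-locomotion polarity, and overdamped force
  balance `v_i = (alpha p_i + F_i)/xi`, `T_i = F_i`. Extrusion is emergent:
  no rule removes cells.
* **`mechcomp.stress_stats`** — coarse-grained stress from tractions,
  susceptibility `chi = N Var` and its distance-to-interface profiles,
  spatial autocorrelation and correlation length (zero crossing),
  extrusion detection/spatial statistics/rates, event-centred ensemble
  stress maps, out-of-plane stress distributions, interface convexity.
* **`mechcomp.tfm`** — Fourier-transform traction cytometry (regularized
  Boussinesq inversion of bead displacements) and Bayesian inversion stress
  microscopy (2D tissue stress from force balance `t = -div sigma`), with
  forward models for validation.
* **`mechcomp.energetics`** — analytic work to eliminate a cell through a
  constant-volume cylinder -> cone -> sphere shape path,
  `dW_I = (omega_s_II - omega_s_I) dA_s - 0.5 omega_c_I dA_cc + k dA_tot`,
  and the resulting win/lose phase diagram over adhesion differences.
* **`mechcomp.synthetic`** — seeded generators of Gaussian random fields
  with prescribed correlation length, two-population geometries,
  interface-biased extrusion catalogs, and stress/traction/displacement
  benchmarks with exact ground truth.
* **`mechcomp.io`** — TIFF field stacks, CSV event tables, YAML configs,
  JSON run manifests (atomic writes, units in sidecars).

## Worked example

`examples/` holds one narrative script per capability. For instance:

```sh
$ python examples/energetics_phase_diagram.py
conserved volume: 4188.8 um^3
  cylinder r_b= 10.0: A_s=  314.2  A_cc=  837.8  A_tot= 1466.1 um^2
  ...
work to eliminate type I:      73.3  (substrate   -94.2, cell-cell   377.0, tension  -209.4)
work to eliminate type II:    -31.4
type I wins (harder to eliminate)

phase diagram 51x51: DeltaW range [-5.00, 5.00] (units of |dW0_k|)
win-despite-substrate-deficit region: 204 grid points (8% of the diagram)
```

Type I adheres less to the substrate but much more to its own kind; the
positive work gap (73.3 vs −31.4, in energy-per-area times um^2 units)
says its elimination costs more work, so it wins the interface — cell–cell
adhesion can beat a substrate-adhesion deficit, which is the model's
central claim.

```sh
$ python examples/traction_and_stress_inference.py
max |u| = 0.056 um, bead noise sigma = 0.0043 um
FTTC traction recovery correlation at 5% noise: 0.948
BISM stress recovery relative L2 error (2-px margin): 0.00%
...
```

The inversion chain recovers known tractions from noisy synthetic bead
displacements (correlation 0.95) and reconstructs a ground-truth 2D stress
tensor from its balancing traction field essentially exactly.

`examples/stress_fluctuation_statistics.py` demonstrates the fluctuation
statistics (susceptibility profile peak at a variance-boosted interface,
correlation lengths, availability-corrected extrusion distance law), and
`examples/competition_simulation.py` runs a scaled-down two-type collision
in which the low-adhesion type is extruded near the interface.

The science, parameter choices and scaled-down study conditions are
documented in `docs/methods.md`.

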