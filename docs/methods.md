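# Methods

`mechcomp` studies mechanical cell competition: two epithelial populations
that differ in adhesion meet at an interface, and one is progressively
eliminated by apical extrusion. The package contains four computational
pillars — a 3D multiphase-field simulator of the monolayer, the statistics
that characterize stress fluctuations and extrusion localization, the
traction/stress inference chain used on experimental-shaped data, and an
analytic energetics model of the work needed to eliminate one cell — plus
synthetic-data generators that give every analysis stage a known ground
truth.

## 1. Multiphase-field monolayer model

Each cell `i` is a smooth 3D indicator field `phi_i(x, t)` on a grid that is
periodic in x and y and bounded in z, resting on a rigid substrate
represented by a static field `phi_w` (a tanh profile of width `lam` around
height `substrate_z`). Interface relaxation follows time-dependent
Ginzburg–Landau dynamics with rigid advection,

    d(phi_i)/dt + v_i . grad(phi_i) = -Gamma dF/dphi_i,

with the free energy per cell: a double-well plus gradient penalty scaled by
the cortex tension `gamma/lam * int {4 phi^2 (1-phi)^2 + lam^2 |grad phi|^2}`;
a soft volume constraint `mu (1 - V_i/V0)^2` with `V_i = int phi_i^2 dx` and
`V0 = (4/3) pi R0^3`; pairwise repulsion `(kappa_cc/lam^2) int phi_i^2 phi_j^2`
and adhesion `omega_cc^i int grad(phi_i) . grad(phi_j)` (counted in both pair
orders, with each cell's own `omega_cc` in its functional derivative, exactly
as the energy is written — with unequal coefficients the flow is therefore
not exactly variational, a documented property of the model as printed); and
the analogous substrate terms with `kappa_cs`, `omega_cs` against `phi_w`.

Forces come from overdamped balance: the interaction stress

    Pi_int = (sum_i -dF/dphi_i) I  +  sum_i (-zeta_S^i phi_i S_i)
             +  sum_i (-zeta_Q^i phi_i phi_w Q_w),

with `S_i` the (negative, deviatoric) second moment of grad(phi_i) and `Q_w`
the traceless nematic tensor of the substrate stress-fibre direction, gives
the interaction force `F_i = -int Pi_int . grad(phi_i) dx`; the velocity is
`v_i = (alpha p_i + F_i)/xi` and the traction transmitted to the substrate
is `T_i = F_i`. (The substrate active term carries the cell's own `phi_i`
factor, exactly parallel to the cell–cell active term: without it the term
sums over the whole population and its force grows linearly with cell count,
which detaches entire monolayers.) Polarity angles follow contact
inhibition of locomotion: `theta_i` relaxes toward the direction of `T_i`
on the timescale `tau_pol` with rotational diffusivity `D_r`; a cell with
zero in-plane traction keeps only the diffusive term.

Extrusion is emergent — no rule removes cells. The analysis layer flags a
cell as extruded at the first step where its core substrate contact
`int phi^2 phi_w^2 dx` (over `phi > 0.2`, see below) falls below 1% of its
initial value and its centre of mass exceeds the population median height
by more than `R0/2`. Both thresholds are detection conventions, exposed in
the configuration; the dynamics itself has no threshold.

### Parameters

The model's reference parameterization fixes `gamma = 0.008`, `mu = 45`, `xi = 1`,
`zeta_S = 4e-5`, `zeta_Q = -0.01`, `R0 = 8`, reference speed `vbar = 0.02`
(defining the time unit `tau = 2 R0 / vbar`, one cell diameter of travel;
one simulated "hour" is mapped to `tau` unless overridden). All remaining
numerics are this package's own calibration, chosen once so that a single
passive cell relaxes to a stable droplet resting on the substrate and a
passive 16-cell monolayer is confluent and quiescent:

| parameter | default | role |
|---|---|---|
| `lam` | 2 a0 | diffuse interface width (>= 2 a0 to be resolved) |
| `Gamma` | 0.6 | interface mobility; relaxation time << tau |
| `dt` | 0.2 | explicit Euler step; a stability guard rejects larger values |
| `kappa_cc` | 0.12 | cell–cell repulsion |
| `kappa_cs`, `omega_cs` | 0.02, 0.02 | substrate repulsion/adhesion; the cell rests with finite contact and |phi| overshoot < 0.05 |
| `omega_cc` | 0.004 | cell–cell adhesion baseline |
| `alpha`, `D_r`, `tau_pol` | 0.02, 0.002, 40 | self-propulsion and polarity noise |

The advection uses first-order upwinding with the rigid per-cell velocity;
a CFL limiter caps the rigid translation at `cfl_cap = 0.4` nodes per step.
The limiter binds only during fast events (the initial overlap transient
and extrusions themselves, which would otherwise outrun the scheme).

### Windowed evaluation

Each cell's field is stored on a moving (x, y) window spanning the full z
extent, re-centred on the cell's centre of mass; interactions are mediated
by shared full-grid sum fields. For compactly supported interactions
(everything except the gradient-form adhesions) windowed and full-grid
evaluation agree to machine precision as long as windows cover the field
support; the initial droplet is clipped at `phi < 1e-9` to make that
support compact, and the regression suite verifies 1e-8 agreement.

The gradient-form adhesion energies are not compact: the variational
derivative of `omega int grad(phi_i) . grad(phi_w)` is `-omega lap(phi_w)`
everywhere, so each cell's exact equilibrium carries a thin wetting film
(amplitude of order `omega lam |lap phi_w| / (8 gamma)`, about 0.03 at the
defaults) across the whole substrate, and similarly on every other cell's
interface. The windowed scheme evaluates each cell's `-dF/dphi_i` on its
own window both for the field update and when assembling `Pi_int`. This is
a projected gradient flow (energy still descends for passive parameters)
and it removes an N-scaled artefact of the truncated literal sum; windows
spanning the whole grid recover the literal global formula exactly. The
extrusion contact integral counts only the cell core (`phi > 0.2`) so that
the film of a detached cell does not mask its loss of substrate contact.

### Scaled-down study conditions

The reference full-scale configuration (400 cells, 320x320x64, 15,000 steps) is cluster-scale.
The package's bundled study conditions are desk-scale equivalents:

* **Passive control**: 16 cells, 64x64x24, 2,000 steps, all activity off.
  Checks: per-step energy descent, volumes within 15% of V0 after the
  initial transient, zero extrusions, exact periodic-translation
  equivariance.
* **Two-type competition**: 36 cells on 96x96x32, collision geometry (type
  A central band, two interfaces), 8:1 cell–cell adhesion ratio between
  types A ("winner", omega_cc = 0.004) and B ("loser", 0.0005), equal
  substrate adhesion (omega_cs = 0.04), 2,500 steps at dt = 0.4. To make
  extrusions observable at this small size within a few thousand steps the
  monolayer is overcrowded (target radius R0 = 9.5 at lattice spacing 16,
  the homeostatic-compression analogue) and the activity is raised relative
  to the single-cell calibration (alpha = 0.12, zeta_S = 4e-4, D_r = 0.02,
  tau_pol = 10). These constitute one fixed, documented operating point;
  the qualitative observables (loser-type extrusions enriched near the
  interface; the loser type's in-plane isotropic-stress susceptibility
  maximal at the interface at cell-scale binning, pooled over seeds) are
  scale-independent claims of the model, not quantitative reproductions of
  the full-scale configuration. At this scale the winner type also extrudes
  occasionally — its strong mutual adhesion densifies its own bulk — and
  its fluctuations are not interface-localized; the loser's are, and that
  localization is what drives its elimination at the interface. A
  ``substrate_contrast`` > 1 (the loser adhering more strongly to the
  substrate, the second reference scenario) makes the outcome one-sided:
  in a bundled spot-check every extrusion was of the losing type.

## 2. Stress and fluctuation statistics

Coarse-grained stress: `sigma(i) = (1/a0^d) sum_j r_ij (x) T_j` over the
2d nearest-neighbour nodes; per-cell tractions are distributed over nodes
with weight `phi_i^2 / int phi_i^2` so node sums reproduce each cell's
total traction. Negative values are compressive. The 2D in-plane isotropic
stress is half the trace of the in-plane block, z-averaged for maps.

Susceptibility is the sample-size-scaled variance `chi = N Var(A)`; `N`
follows a declared convention (pixels by default, cells optionally) and is
reported with every profile. Profiles against distance from the interface
use Euclidean distance to the 8-connected two-population boundary, with
bins of 10 um (experimental units) or `R0/2` (simulation units).

The spatial autocorrelation is estimated non-periodically (zero padding,
overlap-count normalization) after in-mask mean subtraction, radially
averaged, and the correlation length is its first zero crossing (linear
interpolation; right-censored at the maximum lag when no crossing exists).
For a squared-exponential field the true autocovariance never crosses zero;
the measured crossing is created by the mean subtraction at approximately
`ell sqrt(2 ln(L^2/(2 pi ell^2)))`, which the test-suite verifies — the
estimator orders correlation lengths faithfully but maps them through this
domain-dependent bias. The `frame_median` option (median of per-frame
crossings) is far more robust to long-lag noise than the crossing of the
frame-averaged curve and is used whenever few frames are available.

Extrusion statistics: the distance-resolved extrusion probability divides
per-bin event counts by the per-bin pixel availability of the same type
(the uniform-placement baseline) and renormalizes; rates divide windowed
event counts by occupied area and window duration (with the 10x
field-of-view constant 0.514188 mm^2 available for area conversion);
event-centred ensemble maps cut a square window around each event, rotate
it so the opposing population lies in a fixed half-plane, and take the
per-pixel median (mean optional); the local susceptibility time course
applies `chi` to the window per frame, normalized to its earliest point.
Out-of-plane stress distributions collect z-averaged `sigma_zz` within a
band around the interface, normalized by the maximum in-plane compression
over the same band. Interface convexity traces the island boundary at
subpixel resolution, simplifies it (Douglas–Peucker, 1 px) to remove the
marching-squares staircase, and reports hull perimeter / island perimeter
(<= 1; the literal ratio from the convexity definition is its reciprocal).

## 3. Traction and stress inference

FTTC inverts the Boussinesq half-space relation `u(k) = G(k) t(k)` mode by
mode with Tikhonov weight `lambda_fttc` (default 9e-9 in (um/Pa)^2) and a
zero rigid mode; `nu = 0.5` (incompressible silicone). The finite-thickness
correction is omitted (substrates ~100 um thick deform by < 0.1 um here).
BISM solves the 2D force balance `t = -div sigma` as a sparse
Tikhonov-regularized least-squares problem; the prior weight `Lambda`
(default 1e-6) is made dimensionless by scaling with the mean diagonal of
the normal matrix, and the minimum-norm prior fixes the additive stress
gauge (zero-mean stress). Stress units are Pa*um (tension per unit length).

The synthetic benchmark plays the role of the experimental pipeline's PIV
output: 128^2 fields at 1 um spacing on a stiff (45 kPa) substrate with
~100 Pa tractions band-limited to ~100 um features, and 5%-of-max bead
noise. These conditions were chosen once so that the fixed `lambda_fttc`
operates in its useful band: it suppresses the near-Nyquist noise
amplification while leaving the signal band essentially untouched (the original pipeline's normalization of this constant is not
recoverable from its value alone). The BISM
benchmark parameterizes the ground-truth stress as the symmetrized gradient
of a smooth random vector potential evaluated with the same discrete
operators the inversion uses, which guarantees the pair (sigma, t) is
consistent and carries no silent gauge component.

## 4. Elimination energetics

A cell is eliminated through a constant-volume shape path: cylinder (basal
radius = apical radius r_a) -> frusta of shrinking basal radius -> cone ->
detached sphere, all at `V = (4/3) pi r_s^3` with `r_a = r_s = 10 um`
(volume ~ 4,188.8 um^3). The work differential combines substrate adhesion
(with the winner re-occupying the vacated substrate folded into the
`omega_s_II - omega_s_I` prefactor), same-type cell–cell adhesion weighted
by the 0.5 same-type contact fraction, and surface tension `k dA_tot`;
the cross-type adhesion term cancels in the work difference and is dropped.
Because the coefficients are constant the path integral over the frustum
family plus the cone->sphere jump equals the endpoint difference exactly
(both are computed). The pure-tension normalizer `dW0_k = k dA_tot` is
negative — the sphere has less surface than the volume-matched cylinder —
so the phase diagram is normalized by `|dW0_k|`, making `DeltaW` increase
with the focal type's cell–cell adhesion advantage; `DeltaW > 0` marks the
focal type as winner. The apical cap is part of `A_tot` (a closed surface)
but belongs to neither adhesion term; the detached sphere has no contacts.

## 5. Synthetic data

All generators are pure functions of their arguments (bit-reproducible) and
return their true parameters with the data. Gaussian random fields use a
squared-exponential spectrum normalized analytically (ensemble variance
exact; the sample variance converges with domain size). The extrusion
catalogs place events inside one population with either uniform weights or
`exp(-d/decay)` interface bias. The generators emulate additive measurement
noise only; real microscopy artefacts (drift, bleaching, segmentation
errors, tracking gaps) are out of scope, so passing tests validate the
statistical machinery, not robustness to instrument systematics.

## Known limitations

* The simulator is desk-scale; absolute extrusion rates and stress
  magnitudes at the full problem size are not reproduced, only the
  mechanistic, qualitative observables.
* With unequal `omega_cc` across types the printed per-cell-coefficient
  pair coupling makes the relaxation non-variational (no energy theorem);
  all conservation tests use type-uniform parameters.
* The gradient-form adhesions imply global wetting films; the windowed
  scheme truncates them (see above), and window-spanning runs are the
  reference behaviour.
* FTTC assumes an infinite half-space and in-plane tractions; BISM assumes
  a flat 2D tissue with isotropic prior and no body forces.
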