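"""3D multiphase-field model of an active cell monolayer on a rigid substrate.

Each cell ``i`` is a smooth indicator field ``phi_i`` (1 inside, 0 outside,
diffuse interface of width ``lam``) on a grid periodic in x and y and
bounded in z.  The interface relaxes by time-dependent Ginzburg-Landau
dynamics with an advective term that rigidly translates the cell:

    d(phi_i)/dt + v_i . grad(phi_i) = -Gamma * dF/dphi_i.

The free energy F contains, per cell: a Cahn-Hilliard double well and
gradient penalty scaled by the cortex tension ``gamma``; a soft volume
constraint of strength ``mu`` around V0 = (4/3) pi R0^3; cell-cell and
cell-substrate repulsion (``kappa_cc``, ``kappa_cs``) and adhesion
(``omega_cc``, ``omega_cs``) terms, the adhesions coupling interface
gradients.  Forces follow from overdamped force balance: the interaction
force on a cell is the integral of an interaction stress

    Pi_int = (sum_i -dF/dphi_i) I + sum_i(-zeta_S phi_i S_i)
             + sum_i(-zeta_Q phi_i phi_w Q_w)

contracted with the cell's own gradient, a self-propulsion force
``alpha * p_i`` acts along the polarity, and the traction transmitted to
the substrate is T_i = xi v_i - F_sp = F_int.  Polarity realigns toward the
interaction force (contact inhibition of locomotion) on a timescale
``tau_pol`` with rotational diffusion ``D_r``.  Extrusion is emergent: no
rule ever removes a cell; cells leave the monolayer when out-of-plane
forces beat the forces holding them on the substrate.

Numerically, each cell's field is stored on a moving (x, y)-window spanning
the full z extent; interactions are mediated by shared full-grid sum fields.
Each cell's functional derivative is evaluated on its own window, both for
the field update and when assembling Pi_int (windows spanning the grid
recover the literal global formulas exactly; see docs/methods.md for the
treatment of the spatially extended adhesion couplings).  All stencils are
central differences (periodic in x, y; zero-Neumann in z); advection is
first-order upwind with the rigid per-cell velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimGrid",
    "CellTypeParams",
    "SimConfig",
    "CellState",
    "MonolayerState",
    "Trajectory",
    "NumericalInstabilityError",
    "initialize_monolayer",
    "cell_volume",
    "functional_derivative",
    "shape_tensor",
    "interaction_stress",
    "compute_velocity_and_traction",
    "update_polarity",
    "step",
    "total_energy",
    "run_simulation",
    "two_type_competition_config",
]


class NumericalInstabilityError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimGrid:
    """Cuboid grid, periodic in x and y, bounded in z.  ``a0`` is the
    node spacing in simulation length units."""

    nx: int
    ny: int
    nz: int
    a0: float = 1.0

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0 or self.nz <= 0:
            raise ValueError("grid counts must be positive")
        if self.a0 <= 0:
            raise ValueError("grid spacing a0 must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)


@dataclass(frozen=True)
class CellTypeParams:
    """Physical parameters of one cell type.

    gamma: cortex tension; mu: compressibility (volume-constraint
    strength); omega_cc / omega_cs: cell-cell / cell-substrate adhesion;
    kappa_cc / kappa_cs: the corresponding repulsion strengths; zeta_S /
    zeta_Q: cell-cell and cell-substrate active stress amplitudes; alpha:
    self-propulsion strength; D_r: rotational diffusivity; tau_pol:
    polarity alignment time.
    """

    gamma: float = 0.008
    mu: float = 45.0
    omega_cc: float = 0.004
    omega_cs: float = 0.02
    kappa_cc: float = 0.12
    kappa_cs: float = 0.02
    zeta_S: float = 4e-5
    zeta_Q: float = -0.01
    alpha: float = 0.02
    D_r: float = 0.002
    tau_pol: float = 40.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.mu <= 0:
            raise ValueError("gamma and mu must be positive")
        if self.kappa_cc < 0 or self.kappa_cs < 0:
            raise ValueError("repulsion strengths must be nonnegative")
        if self.tau_pol <= 0:
            raise ValueError("tau_pol must be positive")
        if self.D_r < 0:
            raise ValueError("D_r must be nonnegative")


@dataclass(frozen=True)
class SimConfig:
    grid: SimGrid = field(default_factory=lambda: SimGrid(320, 320, 64))
    n_cell: int = 400
    R0: float = 8.0
    Gamma: float = 0.6
    lam: float = 2.0
    xi: float = 1.0
    dt: float = 0.2
    n_sim: int = 15_000
    vbar: float = 0.02
    type_params: dict = field(
        default_factory=lambda: {"A": CellTypeParams(), "B": CellTypeParams()}
    )
    geometry: str = "collision-two-interfaces"
    seed: int = 0
    substrate_z: float = 4.0
    upsilon: float = 0.0
    window: Optional[int] = None
    save_every: int = 50
    record_energy: bool = False
    recenter_every: int = 4
    extrusion_check_every: int = 5
    cfl_cap: float = 0.4

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.lam < 2 * self.grid.a0:
            raise ValueError("interface width lam must be >= 2 a0 to be resolved")
        if self.xi == 0:
            raise ValueError("substrate friction xi must be nonzero")
        if self.geometry not in ("mixed", "collision-two-interfaces", "homogeneous"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        # explicit-Euler stability estimate for the stiffest (gradient) term
        gmax = max(p.gamma for p in self.type_params.values())
        dt_max = self.grid.a0**2 / (6.0 * self.Gamma * 2.0 * gmax * self.lam + 1e-300)
        if self.dt > dt_max:
            raise ValueError(
                f"dt={self.dt} exceeds the explicit-Euler stability estimate {dt_max:.3g}"
            )

    @property
    def V0(self) -> float:
        return (4.0 / 3.0) * np.pi * self.R0**3

    @property
    def tau(self) -> float:
        """Characteristic time for a cell to travel its own diameter."""
        return 2.0 * self.R0 / self.vbar

    @property
    def window_size(self) -> int:
        if self.window is not None:
            w = self.window
        else:
            w = 2 * int(np.ceil(self.R0 + 5 * self.lam)) + 5
        return min(w, self.grid.nx, self.grid.ny)


@dataclass
class CellState:
    """One cell: windowed phase field plus polarity and kinematics."""

    id: int
    type_label: str
    phi: np.ndarray  # (W, W, nz) window
    origin: tuple[int, int]  # window origin (ox, oy) on the full grid
    theta: float
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    traction: np.ndarray = field(default_factory=lambda: np.zeros(3))
    extruded_at: Optional[int] = None
    initial_contact: float = 0.0

    @property
    def polarity(self) -> np.ndarray:
        return np.array([np.cos(self.theta), np.sin(self.theta), 0.0])


@dataclass
class MonolayerState:
    cells: list
    phi_w: np.ndarray  # static substrate field, full grid
    grid: SimGrid
    step_index: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)
    last_energy: Optional[float] = None  # energy of the pre-step state when recorded

    def cell(self, i: int) -> CellState:
        for c in self.cells:
            if c.id == i:
                return c
        raise KeyError(f"no cell with id {i}")


# ---------------------------------------------------------------------------
# window helpers


def _win_indices(origin: int, size: int, n: int, halo: int = 0) -> np.ndarray:
    return (origin - halo + np.arange(size + 2 * halo)) % n


def _gather(full: np.ndarray, cell: CellState, halo: int = 0) -> np.ndarray:
    W = cell.phi.shape[0]
    nx, ny = full.shape[0], full.shape[1]
    ix = _win_indices(cell.origin[0], W, nx, halo)
    iy = _win_indices(cell.origin[1], W, ny, halo)
    return full[np.ix_(ix, iy)]


def _scatter_add(full: np.ndarray, win: np.ndarray, cell: CellState) -> None:
    W = win.shape[0]
    ix = _win_indices(cell.origin[0], W, full.shape[0])
    iy = _win_indices(cell.origin[1], W, full.shape[1])
    full[np.ix_(ix, iy)] += win


def full_field(state: MonolayerState, i: int, values: np.ndarray | None = None) -> np.ndarray:
    """Materialize a cell's windowed field (or a window-shaped array) on the
    full grid."""
    cell = state.cell(i)
    out = np.zeros(state.grid.shape)
    _scatter_add(out, cell.phi if values is None else values, cell)
    return out


def _pad_zero_xy(win: np.ndarray) -> np.ndarray:
    return np.pad(win, ((1, 1), (1, 1), (0, 0)))


def _pad_phi(win: np.ndarray, wrap_x: bool, wrap_y: bool) -> np.ndarray:
    """Halo for a cell window: zero where the window is a strict subdomain
    (the support never reaches the edge), periodic where it spans the grid."""
    out = np.pad(win, ((1, 1), (0, 0), (0, 0)), mode="wrap" if wrap_x else "constant")
    return np.pad(out, ((0, 0), (1, 1), (0, 0)), mode="wrap" if wrap_y else "constant")


def _lap_win(g: np.ndarray, a0: float) -> np.ndarray:
    """Laplacian of a haloed window (zero or wrapped halo in x,y baked in);
    zero-Neumann in z.  Output loses the x,y halo."""
    core = g[1:-1, 1:-1]
    out = (
        g[2:, 1:-1] + g[:-2, 1:-1] + g[1:-1, 2:] + g[1:-1, :-2] - 4.0 * core
    )
    dz = np.empty_like(core)
    dz[..., 1:-1] = core[..., 2:] - 2.0 * core[..., 1:-1] + core[..., :-2]
    dz[..., 0] = core[..., 1] - core[..., 0]
    dz[..., -1] = core[..., -2] - core[..., -1]
    return (out + dz) / a0**2


def _grad_win(g: np.ndarray, a0: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Central-difference gradient of a haloed window; Neumann in z."""
    core = g[1:-1, 1:-1]
    gx = (g[2:, 1:-1] - g[:-2, 1:-1]) / (2 * a0)
    gy = (g[1:-1, 2:] - g[1:-1, :-2]) / (2 * a0)
    gz = np.empty_like(core)
    gz[..., 1:-1] = (core[..., 2:] - core[..., :-2]) / (2 * a0)
    gz[..., 0] = (core[..., 1] - core[..., 0]) / (2 * a0)
    gz[..., -1] = (core[..., -1] - core[..., -2]) / (2 * a0)
    return gx, gy, gz


def _lap_full(f: np.ndarray, a0: float) -> np.ndarray:
    """Full-grid Laplacian, periodic in x and y, zero-Neumann in z."""
    out = (
        np.roll(f, 1, axis=0)
        + np.roll(f, -1, axis=0)
        + np.roll(f, 1, axis=1)
        + np.roll(f, -1, axis=1)
        - 4.0 * f
    )
    dz = np.empty_like(f)
    dz[..., 1:-1] = f[..., 2:] - 2.0 * f[..., 1:-1] + f[..., :-2]
    dz[..., 0] = f[..., 1] - f[..., 0]
    dz[..., -1] = f[..., -2] - f[..., -1]
    return (out + dz) / a0**2


def _upwind_advection(phi_pad: np.ndarray, v: np.ndarray, a0: float) -> np.ndarray:
    """First-order upwind v . grad(phi) for a rigid (uniform) velocity."""
    core = phi_pad[1:-1, 1:-1]
    if v[0] >= 0:
        dx = core - phi_pad[:-2, 1:-1]
    else:
        dx = phi_pad[2:, 1:-1] - core
    if v[1] >= 0:
        dy = core - phi_pad[1:-1, :-2]
    else:
        dy = phi_pad[1:-1, 2:] - core
    dz = np.zeros_like(core)
    if v[2] >= 0:
        dz[..., 1:] = core[..., 1:] - core[..., :-1]
    else:
        dz[..., :-1] = core[..., 1:] - core[..., :-1]
    return (v[0] * dx + v[1] * dy + v[2] * dz) / a0


# ---------------------------------------------------------------------------
# initialization


def _substrate_field(config: SimConfig) -> np.ndarray:
    z = np.arange(config.grid.nz) * config.grid.a0
    prof = 0.5 * (1.0 - np.tanh((z - config.substrate_z) / config.lam))
    return np.broadcast_to(
        prof, (config.grid.nx, config.grid.ny, config.grid.nz)
    ).copy()


def substrate_nematic_tensor(upsilon: float = 0.0, d: int = 3) -> np.ndarray:
    """Traceless nematic tensor of the substrate stress-fibre director."""
    n = np.array([np.cos(upsilon), np.sin(upsilon), 0.0])
    Q = (d / (d - 1)) * (np.outer(n, n) - (n @ n) / d * np.eye(3))
    return Q


def _droplet(config: SimConfig, cx: float, cy: float, cz: float, W: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Tanh droplet of target squared-field volume V0, on a window."""
    g = config.grid
    ox = int(round(cx / g.a0)) - W // 2
    oy = int(round(cy / g.a0)) - W // 2
    # unwrapped window coordinates relative to the centre
    xs = (np.arange(W) + ox) * g.a0
    ys = (np.arange(W) + oy) * g.a0
    zs = np.arange(g.nz) * g.a0
    dx = xs - cx
    dy = ys - cy
    dz = zs - cz
    r = np.sqrt(
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    )
    R = config.R0
    for _ in range(3):
        phi = 0.5 * (1.0 - np.tanh((r - R) / config.lam))
        V = (phi**2).sum() * g.a0**3
        R *= (config.V0 / V) ** (1.0 / 3.0)
    phi = 0.5 * (1.0 - np.tanh((r - R) / config.lam))
    phi[phi < 1e-9] = 0.0  # compact support: clip the far tanh tail
    return phi, (ox % g.nx, oy % g.ny)


def initialize_monolayer(config: SimConfig) -> MonolayerState:
    """Cells on a simple square lattice, resting on the substrate.

    For ``collision-two-interfaces`` geometry type A occupies a central band
    in x and type B the complement (two straight interfaces under periodic
    x); ``mixed`` assigns types at random 50:50; ``homogeneous`` is all A.
    Polarity angles are uniform in [-pi, pi), drawn from ``config.seed`` in
    cell-id order.
    """
    g = config.grid
    n_side = int(round(np.sqrt(config.n_cell)))
    if n_side * n_side != config.n_cell:
        raise ValueError("n_cell must be a square number for the lattice initialization")
    if config.R0 < 2 * g.a0:
        raise ValueError("R0 must be at least 2 a0")
    sx = g.nx * g.a0 / n_side
    sy = g.ny * g.a0 / n_side
    # spacing moderately below 2 R0 is a supported (overcrowded, confluent)
    # initial condition; below 1.6 R0 neighbouring droplets truly overlap
    for name, s in (("x", sx), ("y", sy)):
        if s < 1.6 * config.R0 - 1e-9:
            raise ValueError(
                f"lattice overflow in {name}: spacing {s:.3g} < 1.6 R0 = {1.6 * config.R0:.3g}"
            )
    rng = np.random.default_rng(config.seed)
    W = config.window_size
    z0 = config.substrate_z + config.R0
    if z0 + config.R0 + 2 * config.lam > g.nz * g.a0:
        raise ValueError("lattice overflow in z: cells do not fit below the top boundary")
    phi_w = _substrate_field(config)
    thetas = rng.uniform(-np.pi, np.pi, config.n_cell)
    mixed_types = None
    if config.geometry == "mixed":
        half = config.n_cell // 2
        mixed_types = np.array(["A"] * (config.n_cell - half) + ["B"] * half)
        rng.shuffle(mixed_types)
    cells = []
    Lx = g.nx * g.a0
    k = 0
    for j in range(n_side):
        for i in range(n_side):
            cx = (i + 0.5) * sx
            cy = (j + 0.5) * sy
            if config.n_cell == 1:
                cx, cy = g.nx * g.a0 / 2, g.ny * g.a0 / 2
            if config.geometry == "collision-two-interfaces":
                label = "A" if Lx / 4 <= cx < 3 * Lx / 4 else "B"
            elif config.geometry == "mixed":
                label = str(mixed_types[k])
            else:
                label = "A"
            phi, origin = _droplet(config, cx, cy, z0, W)
            cells.append(
                CellState(id=k, type_label=label, phi=phi, origin=origin, theta=float(thetas[k]))
            )
            k += 1
    state = MonolayerState(cells=cells, phi_w=phi_w, grid=g, rng=rng)
    for c in state.cells:
        c.initial_contact = _contact_integral(c, state, config)
    return state


def cell_volume(phi: np.ndarray, a0: float = 1.0) -> float:
    """Phase-field volume of a cell, int phi^2 dx (node sum times a0^3)."""
    phi = np.asarray(phi)
    if not np.isfinite(phi).all():
        raise ValueError("phase field contains non-finite values")
    return float((phi**2).sum() * a0**3)


def _contact_integral(
    cell: CellState, state: MonolayerState, config: SimConfig, core: float = 0.2
) -> float:
    """Substrate contact int phi^2 phi_w^2 dx of the cell body.

    Only the cell core (phi > ``core``) is counted: the gradient-form
    substrate adhesion grows a thin wetting film (phi of order 0.03) across
    the window, which would otherwise keep the contact integral of a fully
    detached cell at a finite fraction of its initial value.
    """
    w = _gather(state.phi_w, cell)
    phi = np.where(cell.phi > core, cell.phi, 0.0)
    return float((phi**2 * w**2).sum() * state.grid.a0**3)


def _com(cell: CellState, grid: SimGrid) -> np.ndarray:
    """Centre of mass (phi^2-weighted), in unwrapped window coordinates."""
    w = cell.phi**2
    tot = w.sum()
    if tot == 0:
        ox, oy = cell.origin
        W = cell.phi.shape[0]
        return np.array([(ox + W / 2) * grid.a0, (oy + W / 2) * grid.a0, grid.nz * grid.a0 / 2])
    W = cell.phi.shape[0]
    xs = (cell.origin[0] + np.arange(W)) * grid.a0
    ys = (cell.origin[1] + np.arange(W)) * grid.a0
    zs = np.arange(grid.nz) * grid.a0
    cx = (w.sum(axis=(1, 2)) @ xs) / tot
    cy = (w.sum(axis=(0, 2)) @ ys) / tot
    cz = (w.sum(axis=(0, 1)) @ zs) / tot
    return np.array([cx, cy, cz])


# ---------------------------------------------------------------------------
# free energy and its variational derivative


class _StepWorkspace:
    """Per-step shared fields and per-cell intermediates."""

    def __init__(self, state: MonolayerState, config: SimConfig):
        from . import _kernels as K

        g = state.grid
        a0 = g.a0
        self.a0 = a0
        params = {c.id: config.type_params[c.type_label] for c in state.cells}
        self.params = params
        self.idx = {}
        W0 = state.cells[0].phi.shape[0] if state.cells else 0
        self.wrap_x = W0 == g.nx
        self.wrap_y = W0 == g.ny
        for c in state.cells:
            W = c.phi.shape[0]
            self.idx[c.id] = (
                _win_indices(c.origin[0], W, g.nx).astype(np.int64),
                _win_indices(c.origin[1], W, g.ny).astype(np.int64),
            )
        # shared sum fields
        self.sumphi = np.zeros(g.shape)
        self.sumphi2 = np.zeros(g.shape)
        for c in state.cells:
            if K.HAVE_NUMBA:
                ix, iy = self.idx[c.id]
                K.scatter_sums(self.sumphi, self.sumphi2, c.phi, ix, iy)
            else:
                _scatter_add(self.sumphi, c.phi, c)
                _scatter_add(self.sumphi2, c.phi**2, c)
        self.lap_sumphi = _lap_full(self.sumphi, a0)
        self.phi_w2 = state.phi_w**2
        self.lap_phi_w = _lap_full(state.phi_w, a0)
        # per-cell caches
        self.lap_phi: dict[int, np.ndarray | None] = {}
        self.grad_phi: dict[int, tuple] = {}
        self.volume: dict[int, float] = {}
        self.dF_local: dict[int, np.ndarray] = {}
        self.S: dict[int, np.ndarray] = {}



def _cell_terms(cell: CellState, state: MonolayerState, config: SimConfig, ws: _StepWorkspace):
    """Functional derivative (compact part), gradient, volume and deviatoric
    shape tensor of one cell, on its window."""
    from . import _kernels as K

    p = ws.params[cell.id]
    a0 = ws.a0
    lam = config.lam
    phi = cell.phi
    if K.HAVE_NUMBA:
        ix, iy = ws.idx[cell.id]
        dF_local = np.empty_like(phi)
        gx = np.empty_like(phi)
        gy = np.empty_like(phi)
        gz = np.empty_like(phi)
        M = np.empty((3, 3))
        V = K.cell_terms(
            phi, ws.sumphi2, ws.phi_w2, ix, iy, ws.wrap_x, ws.wrap_y,
            a0, lam, p.gamma, p.mu, config.V0, p.kappa_cc, p.kappa_cs, p.omega_cc,
            dF_local, gx, gy, gz, M,
        )
        lap = None
    else:
        padded = _pad_phi(phi, ws.wrap_x, ws.wrap_y)
        lap = _lap_win(padded, a0)
        gx, gy, gz = _grad_win(padded, a0)
        V = (phi**2).sum() * a0**3
        sumphi2_w = _gather(ws.sumphi2, cell)
        phi_w2_w = _gather(ws.phi_w2, cell)
        bulk = (p.gamma / lam) * 8.0 * phi * (1.0 - phi) * (1.0 - 2.0 * phi)
        vol_term = -(4.0 * p.mu / config.V0) * (1.0 - V / config.V0) * phi
        rep_cc = (4.0 * p.kappa_cc / lam**2) * phi * (sumphi2_w - phi**2)
        rep_cs = (2.0 * p.kappa_cs / lam**2) * phi * phi_w2_w
        # gradient penalty and the compact part of the cc-adhesion coupling
        dF_local = bulk + (2.0 * p.omega_cc - 2.0 * p.gamma * lam) * lap
        dF_local += vol_term + rep_cc + rep_cs
        M = np.empty((3, 3))
        G = (gx, gy, gz)
        for a in range(3):
            for b in range(a, 3):
                M[a, b] = M[b, a] = (G[a] * G[b]).sum() * a0**3
    S = -M + np.trace(M) / 3.0 * np.eye(3)
    ws.lap_phi[cell.id] = lap
    ws.grad_phi[cell.id] = (gx, gy, gz)
    ws.volume[cell.id] = V
    ws.dF_local[cell.id] = dF_local
    ws.S[cell.id] = S


def _cell_dF(cell: CellState, ws: _StepWorkspace) -> np.ndarray:
    """Full functional derivative on the window: compact part plus the
    gathered non-compact adhesion pieces."""
    p = ws.params[cell.id]
    return (
        ws.dF_local[cell.id]
        - 2.0 * p.omega_cc * _gather(ws.lap_sumphi, cell)
        - p.omega_cs * _gather(ws.lap_phi_w, cell)
    )


def _prepare(state: MonolayerState, config: SimConfig) -> _StepWorkspace:
    ws = _StepWorkspace(state, config)
    for c in state.cells:
        _cell_terms(c, state, config, ws)
    return ws


def functional_derivative(state: MonolayerState, config: SimConfig, i: int) -> np.ndarray:
    """dF/dphi_i on the full grid.

    Includes the Cahn-Hilliard bulk+gradient terms, the soft volume
    constraint, cell-cell and cell-substrate repulsion, and both adhesion
    couplings (the pair coefficient is the cell's own omega_cc, as the free
    energy is written; no pair symmetrization).
    """
    ws = _prepare(state, config)
    cell = state.cell(i)
    out = full_field(state, i, ws.dF_local[cell.id])
    p = ws.params[cell.id]
    out += -2.0 * p.omega_cc * ws.lap_sumphi - p.omega_cs * ws.lap_phi_w
    return out


def shape_tensor(state: MonolayerState, i: int, config: SimConfig | None = None) -> np.ndarray:
    """Deviatoric shape tensor S_i = -M + Tr(M)/3 I with
    M = int (grad phi)^T (grad phi) dx; trace-free by construction."""
    cell = state.cell(i)
    a0 = state.grid.a0
    W = cell.phi.shape[0]
    padded = _pad_phi(cell.phi, W == state.grid.nx, W == state.grid.ny)
    gx, gy, gz = _grad_win(padded, a0)
    M = np.empty((3, 3))
    G = (gx, gy, gz)
    for a in range(3):
        for b in range(a, 3):
            M[a, b] = M[b, a] = (G[a] * G[b]).sum() * a0**3
    return -M + np.trace(M) / 3.0 * np.eye(3)


_TENSOR_PAIRS = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def _interaction_fields(state: MonolayerState, config: SimConfig, ws: _StepWorkspace):
    """Isotropic and active parts of Pi_int on the full grid.

    Returns (iso, act): iso is the scalar sum_i -dF/dphi_i with each cell's
    derivative evaluated on its compute window (windows spanning the grid
    recover the literal global sum); act stacks the 6 independent components
    (xx, xy, xz, yy, yz, zz) of the active tensor sum_i -zeta_S phi_i S_i +
    sum_i -zeta_Q phi_i phi_w Q_w (both active stresses weighted by the
    cell's own field).
    """
    from . import _kernels as K

    g = state.grid
    iso = np.zeros(g.shape)
    act = np.zeros((6,) + g.shape)
    Q = substrate_nematic_tensor(config.upsilon)
    for c in state.cells:
        p = ws.params[c.id]
        S = ws.S[c.id]
        coefs = np.array([-p.zeta_S * S[ab] for ab in _TENSOR_PAIRS])
        coefs_w = np.array([-p.zeta_Q * Q[ab] for ab in _TENSOR_PAIRS])
        if K.HAVE_NUMBA:
            ix, iy = ws.idx[c.id]
            K.scatter_iso_act(
                iso, act, c.phi, ws.dF_local[c.id],
                ws.lap_sumphi, ws.lap_phi_w, p.omega_cc, p.omega_cs,
                coefs, coefs_w, state.phi_w, ix, iy,
            )
        else:
            _scatter_add(iso, -_cell_dF(c, ws), c)
            phi_w_w = _gather(state.phi_w, c)
            for m in range(6):
                if coefs[m] != 0.0 or coefs_w[m] != 0.0:
                    _scatter_add(act[m], (coefs[m] + coefs_w[m] * phi_w_w) * c.phi, c)
    return iso, act


def interaction_stress(state: MonolayerState, config: SimConfig) -> np.ndarray:
    """Full interaction stress tensor Pi_int(x), shape grid + (3, 3)."""
    ws = _prepare(state, config)
    iso, act = _interaction_fields(state, config, ws)
    out = np.zeros(state.grid.shape + (3, 3))
    for m, (a, b) in enumerate(_TENSOR_PAIRS):
        out[..., a, b] = act[m]
        out[..., b, a] = act[m]
    for a in range(3):
        out[..., a, a] += iso
    return out


def _forces(state: MonolayerState, config: SimConfig, ws: _StepWorkspace, iso, act):
    """Per-cell interaction force, velocity and traction."""
    from . import _kernels as K

    a0 = state.grid.a0
    for c in state.cells:
        gx, gy, gz = ws.grad_phi[c.id]
        if K.HAVE_NUMBA:
            ix, iy = ws.idx[c.id]
            F = np.array(K.contract_force(iso, act, gx, gy, gz, ix, iy, a0))
        else:
            G = (gx, gy, gz)
            iso_w = _gather(iso, c)
            F = np.zeros(3)
            F[0] -= (iso_w * gx).sum()
            F[1] -= (iso_w * gy).sum()
            F[2] -= (iso_w * gz).sum()
            for m, (a, b) in enumerate(_TENSOR_PAIRS):
                f_w = _gather(act[m], c)
                F[a] -= (f_w * G[b]).sum()
                if a != b:
                    F[b] -= (f_w * G[a]).sum()
            F *= a0**3
        p = ws.params[c.id]
        Fsp = p.alpha * c.polarity
        c.traction = F.copy()
        v = (Fsp + F) / config.xi
        # advection CFL limiter: rigid translation of at most cfl_cap nodes
        # per step (binds only during fast events such as extrusions)
        if config.cfl_cap > 0:
            vmax = config.cfl_cap * state.grid.a0 / config.dt
            speed = float(np.linalg.norm(v))
            if speed > vmax:
                v = v * (vmax / speed)
        c.velocity = v


def compute_velocity_and_traction(
    state: MonolayerState, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Overdamped force balance: v_i = (alpha p_i + F_int_i)/xi and the
    substrate traction T_i = xi v_i - alpha p_i = F_int_i, with
    F_int_i = -int Pi_int . grad(phi_i) dx."""
    ws = _prepare(state, config)
    iso, act = _interaction_fields(state, config, ws)
    _forces(state, config, ws, iso, act)
    v = np.array([c.velocity for c in state.cells])
    T = np.array([c.traction for c in state.cells])
    return v, T


def _wrap_angle(a):
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def update_polarity(state: MonolayerState, config: SimConfig, dt: float, rng=None) -> None:
    """Contact-inhibition-of-locomotion alignment with rotational diffusion.

    Euler-Maruyama step of d(theta)/dt = -dTheta/tau_pol + sqrt(2 D_r) eta,
    where dTheta is the signed in-plane angle from the traction direction to
    the polarity; cells with zero in-plane traction keep only the diffusive
    term (no deterministic drift toward an undefined direction).
    """
    rng = rng or state.rng
    z = rng.standard_normal(len(state.cells))
    for k, c in enumerate(state.cells):
        p = config.type_params[c.type_label]
        t_in = np.hypot(c.traction[0], c.traction[1])
        drift = 0.0
        if t_in > 1e-14:
            dtheta = _wrap_angle(c.theta - np.arctan2(c.traction[1], c.traction[0]))
            drift = -dtheta / p.tau_pol * dt
        c.theta = float(_wrap_angle(c.theta + drift + np.sqrt(2.0 * p.D_r * dt) * z[k]))


def total_energy(state: MonolayerState, config: SimConfig, ws: _StepWorkspace | None = None) -> float:
    """Discrete free energy F of the monolayer (literal pair sums, both
    orders counted).  Gradient couplings are evaluated through the discrete
    Laplacian (self-adjoint under the periodic/Neumann boundary
    conditions), so this energy is exactly consistent with
    :func:`functional_derivative` for type-uniform adhesion."""
    ws = ws or _prepare(state, config)
    a0 = state.grid.a0
    lam = config.lam
    F = 0.0
    for c in state.cells:
        p = ws.params[c.id]
        phi = c.phi
        lap = ws.lap_phi[c.id]
        if lap is None:
            lap = _lap_win(_pad_phi(phi, ws.wrap_x, ws.wrap_y), a0)
        V = ws.volume[c.id]
        sumphi2_w = _gather(ws.sumphi2, c)
        lap_sum_w = _gather(ws.lap_sumphi, c)
        lap_phi_w_w = _gather(ws.lap_phi_w, c)
        F += (p.gamma / lam) * (
            (4.0 * phi**2 * (1.0 - phi) ** 2).sum() * a0**3
            - lam**2 * (phi * lap).sum() * a0**3
        )
        F += p.mu * (1.0 - V / config.V0) ** 2
        F += (p.kappa_cc / lam**2) * (phi**2 * (sumphi2_w - phi**2)).sum() * a0**3
        F += (p.kappa_cs / lam**2) * (phi**2 * _gather(ws.phi_w2, c)).sum() * a0**3
        F += -p.omega_cc * (phi * (lap_sum_w - lap)).sum() * a0**3
        F += -p.omega_cs * (phi * lap_phi_w_w).sum() * a0**3
    return float(F)


def _shift_window(arr: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Shift window contents so the origin moves by (dx, dy); vacated cells
    are zero (the field support never reaches the window edge)."""
    out = np.zeros_like(arr)
    W = arr.shape[0]
    sx0, sx1 = max(dx, 0), min(W + dx, W)
    tx0, tx1 = max(-dx, 0), min(W - dx, W)
    sy0, sy1 = max(dy, 0), min(W + dy, W)
    ty0, ty1 = max(-dy, 0), min(W - dy, W)
    out[tx0 : tx0 + (sx1 - sx0), ty0 : ty0 + (sy1 - sy0)] = arr[sx0:sx1, sy0:sy1]
    return out


def _recenter(cell: CellState, grid: SimGrid) -> None:
    com = _com(cell, grid)
    W = cell.phi.shape[0]
    new_ox = int(round(com[0] / grid.a0)) - W // 2
    new_oy = int(round(com[1] / grid.a0)) - W // 2
    # current origin in the same unwrapped frame as the window coordinates
    dx = new_ox % grid.nx - cell.origin[0]
    dy = new_oy % grid.ny - cell.origin[1]
    # choose the minimal shift under periodic wrap
    dx = (dx + grid.nx // 2) % grid.nx - grid.nx // 2
    dy = (dy + grid.ny // 2) % grid.ny - grid.ny // 2
    if dx == 0 and dy == 0:
        return
    if W == grid.nx:
        dx = 0
    if W == grid.ny:
        dy = 0
    if dx or dy:
        cell.phi = _shift_window(cell.phi, dx, dy)
        cell.origin = ((cell.origin[0] + dx) % grid.nx, (cell.origin[1] + dy) % grid.ny)


def step(state: MonolayerState, config: SimConfig) -> MonolayerState:
    """Advance the monolayer by one explicit time step (in place).

    Order: functional derivatives and shape tensors -> interaction stress
    -> per-cell forces, velocities, tractions -> polarity update -> field
    update (upwind advection + relaxation) -> window re-centering ->
    extrusion flags.
    """
    from . import _kernels as K

    ws = _prepare(state, config)
    if config.record_energy:
        state.last_energy = total_energy(state, config, ws)
    iso, act = _interaction_fields(state, config, ws)
    _forces(state, config, ws, iso, act)
    update_polarity(state, config, config.dt)
    a0 = state.grid.a0
    for c in state.cells:
        p = ws.params[c.id]
        if K.HAVE_NUMBA:
            ix, iy = ws.idx[c.id]
            m = K.advect_update(
                c.phi, ws.dF_local[c.id], ws.lap_sumphi, ws.lap_phi_w, ix, iy,
                ws.wrap_x, ws.wrap_y,
                p.omega_cc, p.omega_cs,
                c.velocity[0], c.velocity[1], c.velocity[2],
                config.dt, config.Gamma, a0,
            )
        else:
            adv = _upwind_advection(_pad_phi(c.phi, ws.wrap_x, ws.wrap_y), c.velocity, a0)
            c.phi = c.phi + config.dt * (-adv - config.Gamma * _cell_dF(c, ws))
            m = np.abs(c.phi).max()
        if m > 2.0 or not np.isfinite(m):
            raise NumericalInstabilityError(
                f"phase field blow-up (max|phi|={m:.3g}) at step {state.step_index}; "
                f"reduce dt={config.dt}"
            )
    state.step_index += 1
    if state.step_index % config.recenter_every == 0:
        for c in state.cells:
            _recenter(c, state.grid)
    if state.step_index % config.extrusion_check_every == 0:
        _flag_extrusions(state, config)
    return state


def _flag_extrusions(state: MonolayerState, config: SimConfig) -> None:
    zs = np.array([_com(c, state.grid)[2] for c in state.cells])
    zmed = np.median(zs)
    for k, c in enumerate(state.cells):
        if c.extruded_at is not None:
            continue
        contact = _contact_integral(c, state, config)
        if contact < 0.01 * max(c.initial_contact, 1e-300) and zs[k] > zmed + config.R0 / 2:
            c.extruded_at = state.step_index


# ---------------------------------------------------------------------------
# trajectory archive


@dataclass
class Trajectory:
    """Saved observables of one simulation run."""

    config: SimConfig
    saved_steps: np.ndarray
    contact_series: np.ndarray  # (n_saves, n_cells)
    volume_series: np.ndarray  # (n_saves, n_cells), int phi^2 dx
    z_com_series: np.ndarray
    xy_com_series: np.ndarray  # (n_saves, n_cells, 2), grid units, wrapped
    occupancy_frames: np.ndarray  # (n_saves, ny, nx) labels 0/1/2
    iso_stress_frames: np.ndarray  # z-averaged in-plane isotropic stress
    sigma_zz_frames: np.ndarray
    cell_ids: np.ndarray
    cell_types: np.ndarray
    energy: np.ndarray
    mean_speed: np.ndarray
    events: pd.DataFrame
    cell_table: pd.DataFrame
    manifest: dict

    @property
    def stress_fields(self):
        """Reconstructed (y, x)-layout scalar frames are already stored;
        this returns the saved in-plane isotropic stress frames."""
        return self.iso_stress_frames


def _traction_density(state: MonolayerState, ws: _StepWorkspace) -> np.ndarray:
    g = state.grid
    t = np.zeros(g.shape + (3,))
    for c in state.cells:
        V = ws.volume[c.id]
        if V <= 0:
            continue
        w = c.phi**2 * (g.a0**3 / V)
        for a in range(3):
            if c.traction[a] != 0.0:
                _scatter_add(t[..., a], w * c.traction[a], c)
    return t


def _occupancy_2d(state: MonolayerState, threshold: float = 0.05) -> np.ndarray:
    g = state.grid
    colA = np.zeros((g.nx, g.ny))
    colB = np.zeros((g.nx, g.ny))
    for c in state.cells:
        if c.extruded_at is not None:
            continue
        col = (c.phi**2).sum(axis=2)
        target = colA if c.type_label == "A" else colB
        ix = _win_indices(c.origin[0], c.phi.shape[0], g.nx)
        iy = _win_indices(c.origin[1], c.phi.shape[0], g.ny)
        target[np.ix_(ix, iy)] += col
    total = colA + colB
    lab = np.where(colA >= colB, 1, 2).astype(np.int8)
    lab[total < threshold * max(total.max(), 1e-300)] = 0
    return lab.T  # (y, x) image layout


def run_simulation(config: SimConfig) -> Trajectory:
    """Run a full simulation and collect the trajectory archive.

    Deterministic given ``config.seed``: polarity angles and noise are the
    only random elements and are drawn from one generator in cell-id order.
    """
    from . import __version__
    from .stress_stats import coarse_grain_stress

    state = initialize_monolayer(config)
    n_cells = len(state.cells)
    save_steps = [0]
    save_steps += list(range(config.save_every, config.n_sim + 1, config.save_every))
    if config.n_sim not in save_steps:
        save_steps.append(config.n_sim)
    saves = {
        "contact": [], "volume": [], "z": [], "xy": [], "occ": [], "iso": [], "zz": [],
        "steps": [], "speed": [], "table": [],
    }
    energies = []

    def _save(s: int) -> None:
        ws = _prepare(state, config)
        iso, act = _interaction_fields(state, config, ws)
        _forces(state, config, ws, iso, act)
        saves["steps"].append(s)
        saves["contact"].append([_contact_integral(c, state, config) for c in state.cells])
        saves["volume"].append([cell_volume(c.phi, state.grid.a0) for c in state.cells])
        coms = np.array([_com(c, state.grid) for c in state.cells])
        saves["z"].append(coms[:, 2])
        g = state.grid
        saves["xy"].append(np.stack([coms[:, 0] % (g.nx * g.a0), coms[:, 1] % (g.ny * g.a0)], axis=1))
        saves["occ"].append(_occupancy_2d(state))
        sf = coarse_grain_stress(_traction_density(state, ws), g.a0)
        comp = sf.components
        saves["iso"].append((0.5 * (comp[..., 0, 0] + comp[..., 1, 1])).mean(axis=2).T)
        saves["zz"].append(comp[..., 2, 2].mean(axis=2).T)
        saves["speed"].append(float(np.mean([np.linalg.norm(c.velocity) for c in state.cells])))
        for k, c in enumerate(state.cells):
            saves["table"].append(
                {
                    "step": s, "id": c.id, "type": c.type_label,
                    "x": coms[k, 0] % (g.nx * g.a0), "y": coms[k, 1] % (g.ny * g.a0),
                    "z": coms[k, 2], "theta": c.theta,
                    "vx": c.velocity[0], "vy": c.velocity[1], "vz": c.velocity[2],
                    "Tx": c.traction[0], "Ty": c.traction[1], "Tz": c.traction[2],
                    "extruded_at": c.extruded_at,
                }
            )

    _save(0)
    for s in range(1, config.n_sim + 1):
        step(state, config)  # records the pre-step energy when requested
        if config.record_energy:
            energies.append(state.last_energy)
        if s % config.save_every == 0 or s == config.n_sim:
            _save(s)
    if config.record_energy:
        energies.append(total_energy(state, config))

    traj = Trajectory(
        config=config,
        saved_steps=np.array(saves["steps"]),
        contact_series=np.array(saves["contact"]),
        volume_series=np.array(saves["volume"]),
        z_com_series=np.array(saves["z"]),
        xy_com_series=np.array(saves["xy"]),
        occupancy_frames=np.array(saves["occ"]),
        iso_stress_frames=np.array(saves["iso"]),
        sigma_zz_frames=np.array(saves["zz"]),
        cell_ids=np.array([c.id for c in state.cells]),
        cell_types=np.array([c.type_label for c in state.cells]),
        energy=np.array(energies),
        mean_speed=np.array(saves["speed"]),
        events=pd.DataFrame(),
        cell_table=pd.DataFrame(saves["table"]),
        manifest={
            "seed": config.seed,
            "n_sim": config.n_sim,
            "version": __version__,
            "tau": config.tau,
        },
    )
    # emergent extrusions, flagged by step() as they happen
    rows = []
    for c in state.cells:
        if c.extruded_at is not None:
            k = int(np.searchsorted(traj.saved_steps, c.extruded_at))
            k = min(k, len(traj.saved_steps) - 1)
            i = int(np.nonzero(traj.cell_ids == c.id)[0][0])
            rows.append(
                {
                    "step": c.extruded_at,
                    "frame": k,
                    "x": traj.xy_com_series[k, i, 0],
                    "y": traj.xy_com_series[k, i, 1],
                    "id": c.id,
                    "type": 1 if c.type_label == "A" else 2,
                }
            )
    traj.events = pd.DataFrame(rows, columns=["step", "frame", "x", "y", "id", "type"])
    return traj


def two_type_competition_config(
    n_cell: int = 36,
    grid: SimGrid | None = None,
    n_sim: int = 2500,
    seed: int = 0,
    adhesion_ratio: float = 8.0,
    omega_cc_strong: float = 0.004,
    substrate_contrast: float = 1.0,
    **overrides,
) -> SimConfig:
    """Two-type collision scenario, scaled down to desk size.

    Type A has ``adhesion_ratio`` times the cell-cell adhesion of type B
    (equal substrate adhesion by default; ``substrate_contrast`` > 1 gives
    the low-cc type stronger substrate adhesion, the second scenario, in
    which B is eliminated outright).  The defaults are the package's study
    conditions (see docs/methods.md): an overcrowded monolayer (R0 = 9.5 at
    lattice spacing 16, the homeostatic-compression analogue) with activity
    raised relative to the single-cell calibration so that emergent
    extrusions occur at an observable rate within a few thousand steps.
    """
    grid = grid or SimGrid(96, 96, 32)
    base = CellTypeParams(
        alpha=0.12, zeta_S=4e-4, D_r=0.02, tau_pol=10.0, omega_cs=0.04
    )
    A = replace(base, omega_cc=omega_cc_strong)
    B = replace(
        base,
        omega_cc=omega_cc_strong / adhesion_ratio,
        omega_cs=base.omega_cs * substrate_contrast,
    )
    defaults = dict(R0=9.5, dt=0.4, save_every=50)
    defaults.update(overrides)
    return SimConfig(
        grid=grid,
        n_cell=n_cell,
        n_sim=n_sim,
        seed=seed,
        geometry="collision-two-interfaces",
        type_params={"A": A, "B": B},
        **defaults,
    )
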