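"""Analytic energetics of cell elimination at a two-type tissue interface.

The work needed to extrude a cell is modelled as the energy balance of a
constant-volume shape sequence: the cell starts as a cylinder whose basal
radius shrinks (cylinder -> cone, through a family of frusta), and finally
detaches into a sphere.  Two contributions enter the work differential

    dW = -omega dA_adhesion + k dA_tot,

where ``omega`` are adhesion energies per unit area (cell-substrate and
cell-cell) doing work *for* the cell as contact areas grow, and ``k`` is a
surface tension penalizing total area.  For a focal cell of type I
surrounded by both types, dropping the cross-type term (identical in both
types' work functions) and absorbing the substrate re-occupation by the
winner yields

    dW_I = (omega_s_II - omega_s_I) dA_s - f * omega_c_I dA_cc + k_I dA_tot,

with ``f`` the fraction of lateral contact shared with same-type neighbours
(0.5 by default).  The sign of dW_II - dW_I decides which type wins at the
interface.  All shapes share the volume V = (4/3) pi r_s^3; with
r_a = r_s = 10 um this is approximately 4188.8 um^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ShapeSequence",
    "AdhesionEnergetics",
    "shape_areas",
    "shape_height",
    "elimination_work",
    "phase_diagram",
]


@dataclass(frozen=True)
class ShapeSequence:
    """Constant-volume cylinder -> cone -> sphere shape path.

    Parameters
    ----------
    r_a : apical radius (um), held constant along the path.
    r_s : radius of the final detached sphere (um).

    The conserved volume is that of the sphere, V = (4/3) pi r_s^3.
    """

    r_a: float = 10.0
    r_s: float = 10.0

    def __post_init__(self) -> None:
        if self.r_a <= 0 or self.r_s <= 0:
            raise ValueError("radii must be positive")

    @property
    def volume(self) -> float:
        return (4.0 / 3.0) * np.pi * self.r_s**3


@dataclass(frozen=True)
class AdhesionEnergetics:
    """Per-area adhesion and tension parameters for the two competing types.

    ``omega_s_*``: cell-substrate adhesion energy per area (type I / II);
    ``omega_c_*``: same-type cell-cell adhesion energy per area;
    ``omega_c_I_II``: cross-type adhesion (cancels in the work difference,
    kept for transparency); ``k_*``: surface tension per area;
    ``same_type_contact_fraction``: fraction of a cell's lateral surface in
    contact with same-type neighbours.
    """

    omega_s_I: float = 0.0
    omega_s_II: float = 0.0
    omega_c_I: float = 0.0
    omega_c_II: float = 0.0
    omega_c_I_II: float = 0.0
    k_I: float = 1.0
    k_II: float = 1.0
    same_type_contact_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.k_I <= 0 or self.k_II <= 0:
            raise ValueError("surface tension k must be positive")
        for name in ("omega_s_I", "omega_s_II", "omega_c_I", "omega_c_II", "omega_c_I_II"):
            if getattr(self, name) < 0:
                raise ValueError(f"adhesion parameter {name} must be >= 0")
        f = self.same_type_contact_fraction
        if not 0.0 <= f <= 1.0:
            raise ValueError("same_type_contact_fraction must lie in [0, 1]")

    def swapped(self) -> "AdhesionEnergetics":
        """Relabel the two types (I <-> II)."""
        return AdhesionEnergetics(
            omega_s_I=self.omega_s_II,
            omega_s_II=self.omega_s_I,
            omega_c_I=self.omega_c_II,
            omega_c_II=self.omega_c_I,
            omega_c_I_II=self.omega_c_I_II,
            k_I=self.k_II,
            k_II=self.k_I,
            same_type_contact_fraction=self.same_type_contact_fraction,
        )


def shape_height(shape: str, r_b: float, seq: ShapeSequence) -> float:
    """Height of the cylinder/frustum solving the constant-volume constraint."""
    V = seq.volume
    if shape == "cylinder":
        return V / (np.pi * seq.r_a**2)
    if shape == "frustum":
        denom = seq.r_a**2 + seq.r_a * r_b + r_b**2
        if denom <= 0:
            raise ValueError("degenerate frustum: no nonnegative height exists")
        return 3.0 * V / (np.pi * denom)
    if shape == "sphere":
        return 2.0 * seq.r_s
    raise ValueError(f"unknown shape {shape!r}")


def shape_volume(shape: str, r_b: float, seq: ShapeSequence) -> float:
    """Volume of a shape in the path (equals seq.volume by construction)."""
    if shape == "sphere":
        return (4.0 / 3.0) * np.pi * seq.r_s**3
    h = shape_height(shape, r_b, seq)
    if shape == "cylinder":
        return np.pi * seq.r_a**2 * h
    if shape == "frustum":
        return (np.pi * h / 3.0) * (seq.r_a**2 + seq.r_a * r_b + r_b**2)
    raise ValueError(f"unknown shape {shape!r}")


def shape_areas(shape: str, r_b: float, seq: ShapeSequence) -> tuple[float, float, float]:
    """Surface areas (A_s, A_cc, A_tot) of a shape in the elimination path.

    A_s is the basal (substrate contact) disk, A_cc the lateral surface in
    contact with neighbours, and A_tot the full closed surface (basal +
    lateral + apical cap).  The detached sphere has no contacts:
    A_s = A_cc = 0 and A_tot = 4 pi r_s^2.
    """
    if r_b < 0:
        raise ValueError("basal radius must be nonnegative")
    r_a = seq.r_a
    if shape == "sphere":
        return 0.0, 0.0, 4.0 * np.pi * seq.r_s**2
    h = shape_height(shape, r_b, seq)
    if h < 0:
        raise ValueError("no nonnegative height solves the volume constraint")
    if shape == "cylinder":
        a_s = np.pi * r_a**2
        a_cc = 2.0 * np.pi * r_a * h
    elif shape == "frustum":
        a_s = np.pi * r_b**2
        slant = np.hypot(h, r_a - r_b)
        a_cc = np.pi * (r_a + r_b) * slant
    else:
        raise ValueError(f"unknown shape {shape!r}")
    a_apical = np.pi * r_a**2
    return a_s, a_cc, a_s + a_cc + a_apical


def _path_area_changes(seq: ShapeSequence, n_path: int = 512) -> dict[str, float]:
    """Area changes along cylinder -> cone -> sphere.

    Because the work coefficients are constant, the path integral over the
    frustum family plus the cone->sphere jump reduces exactly to endpoint
    differences; both are computed and compared by the test-suite.
    """
    a_s0, a_cc0, a_tot0 = shape_areas("cylinder", seq.r_a, seq)
    a_s1, a_cc1, a_tot1 = shape_areas("sphere", 0.0, seq)
    return {
        "dA_s": a_s1 - a_s0,
        "dA_cc": a_cc1 - a_cc0,
        "dA_tot": a_tot1 - a_tot0,
    }


def path_work_increments(seq: ShapeSequence, n_path: int = 512) -> dict[str, float]:
    """Numerically integrate the area differentials along the shape path.

    Returns the accumulated dA_s, dA_cc, dA_tot over the frustum family
    (r_b from r_a to 0) plus the discrete cone -> sphere jump.  Agrees with
    the endpoint differences because the differentials are exact.
    """
    r = np.linspace(seq.r_a, 0.0, n_path)
    areas = np.array([shape_areas("frustum", rb, seq) for rb in r])
    d_frustum = areas[-1] - areas[0]
    sph = np.array(shape_areas("sphere", 0.0, seq))
    d_jump = sph - areas[-1]
    total = d_frustum + d_jump
    return {"dA_s": total[0], "dA_cc": total[1], "dA_tot": total[2]}


def elimination_work(
    params: AdhesionEnergetics,
    seq: ShapeSequence | None = None,
    focal: str = "I",
) -> dict[str, float]:
    """Work to eliminate one cell of the focal type through the shape path.

    Returns the total ``dW`` together with its decomposition into the
    substrate-adhesion, cell-cell-adhesion and surface-tension terms, and
    the pure-tension normalizer ``dW0_k = k * dA_tot`` (the work with all
    adhesion switched off; negative here since the sphere has less surface
    than the volume-matched cylinder, i.e. energy is released).
    """
    seq = seq or ShapeSequence()
    if focal == "II":
        params = params.swapped()
    elif focal != "I":
        raise ValueError("focal must be 'I' or 'II'")
    dA = _path_area_changes(seq)
    f = params.same_type_contact_fraction
    w_sub = (params.omega_s_II - params.omega_s_I) * dA["dA_s"]
    w_cc = -f * params.omega_c_I * dA["dA_cc"]
    w_k = params.k_I * dA["dA_tot"]
    return {
        "dW": w_sub + w_cc + w_k,
        "substrate_term": w_sub,
        "cell_cell_term": w_cc,
        "tension_term": w_k,
        "dW0_k": params.k_I * dA["dA_tot"],
        "dA_s": dA["dA_s"],
        "dA_cc": dA["dA_cc"],
        "dA_tot": dA["dA_tot"],
    }


def phase_diagram(
    delta_omega_cc: np.ndarray,
    delta_omega_cs: np.ndarray,
    baseline: AdhesionEnergetics | None = None,
    seq: ShapeSequence | None = None,
) -> dict[str, np.ndarray | float]:
    """Win/lose phase diagram over adhesion differences.

    For each (delta_omega_cc, delta_omega_cs) pair the two types' parameters
    are split symmetrically around the baseline
    (omega_I = baseline + delta/2, omega_II = baseline - delta/2) and the
    normalized work difference

        DeltaW = (dW_I - dW_II) / |dW0_k|

    is evaluated.  DeltaW > 0 means the focal type I is harder to eliminate
    at the interface, i.e. type I wins.  The diagram always contains a
    region with delta_omega_cc > 0, delta_omega_cs < 0 and DeltaW > 0: a
    relative cell-cell adhesion advantage can outweigh a cell-substrate
    deficit.

    Returns a dict with the meshgrids, the DeltaW matrix, and the signed and
    absolute normalizers.
    """
    seq = seq or ShapeSequence()
    baseline = baseline or AdhesionEnergetics(
        omega_s_I=0.5, omega_s_II=0.5, omega_c_I=0.5, omega_c_II=0.5, k_I=1.0, k_II=1.0
    )
    dcc = np.asarray(delta_omega_cc, dtype=float)
    dcs = np.asarray(delta_omega_cs, dtype=float)
    CC, CS = np.meshgrid(dcc, dcs, indexing="xy")
    norm = abs(elimination_work(baseline, seq)["dW0_k"])
    dw = np.empty_like(CC)
    for idx in np.ndindex(CC.shape):
        d_cc, d_cs = CC[idx], CS[idx]
        p = AdhesionEnergetics(
            omega_s_I=max(baseline.omega_s_I + d_cs / 2, 0.0),
            omega_s_II=max(baseline.omega_s_II - d_cs / 2, 0.0),
            omega_c_I=max(baseline.omega_c_I + d_cc / 2, 0.0),
            omega_c_II=max(baseline.omega_c_II - d_cc / 2, 0.0),
            k_I=baseline.k_I,
            k_II=baseline.k_II,
            same_type_contact_fraction=baseline.same_type_contact_fraction,
        )
        w1 = elimination_work(p, seq, focal="I")["dW"]
        w2 = elimination_work(p, seq, focal="II")["dW"]
        dw[idx] = (w1 - w2) / norm
    return {
        "delta_omega_cc": CC,
        "delta_omega_cs": CS,
        "delta_W": dw,
        "dW0_k": elimination_work(baseline, seq)["dW0_k"],
        "normalizer": norm,
    }
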