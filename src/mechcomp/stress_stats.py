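"""Stress coarse-graining and fluctuation/extrusion statistics.

This module turns per-node traction fields from the simulator (or inferred
2D stress fields from traction-force microscopy) into the quantities used
to characterize mechanical cell competition:

* a coarse-grained stress tensor from node tractions,
  sigma(i) = (1/a0^d) sum_j r_ij (x) T_j over nearest-neighbour nodes
  (negative values = compression);
* the susceptibility chi = N * Var of a scalar field, a sample-size-scaled
  variance used as the fluctuation measure, and its profile against
  distance from the two-population interface;
* the radially averaged spatial autocorrelation of a field and its first
  zero crossing (the correlation length);
* extrusion detection from simulated trajectories (loss of substrate
  contact plus a raised centre of mass), the distance-resolved extrusion
  probability corrected by the random (pixel-availability) baseline,
  extrusion rates per time per occupied area, event-centred ensemble
  stress maps and local susceptibility time courses, the distribution of
  the out-of-plane stress component near the interface, and the convexity
  of a population island's interface.

2D image-like inputs use (row=y, col=x) array layout; positions in event
catalogs are (x, y) in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "StressField",
    "Profile",
    "coarse_grain_stress",
    "isotropic_stress",
    "susceptibility",
    "susceptibility_profile",
    "autocorrelation_and_length",
    "interface_mask",
    "interface_distance_map",
    "detect_extrusion_sim",
    "extrusion_distance_pdf",
    "extrusion_rate",
    "ensemble_stress_map",
    "local_susceptibility_timecourse",
    "sigma_zz_distributions",
    "interface_convexity",
    "area_from_fraction",
    "uniformity_gof_pvalue",
]

FOV_AREA_10X_MM2 = 0.514188  # field-of-view area of the 10x objective, mm^2


@dataclass
class StressField:
    """Tensor stress on a grid: components[..., a, b] with grid axes first."""

    components: np.ndarray
    spacing: float = 1.0
    units: str = "simulation"
    time_index: int = 0

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        d = self.components.shape[-1]
        if self.components.shape[-2] != d or d not in (2, 3):
            raise ValueError("components must end in a (2,2) or (3,3) tensor")
        if not np.isfinite(self.components).all():
            raise ValueError("stress field contains non-finite values")

    @property
    def ndim_tensor(self) -> int:
        return self.components.shape[-1]


@dataclass
class Profile:
    """Binned profile against distance from the interface."""

    bin_centers: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    normalization: str = "none"

    def normalized(self) -> "Profile":
        good = np.isfinite(self.values)
        if not good.any():
            raise ValueError("profile has no finite values to normalize")
        peak = np.nanmax(self.values)
        return Profile(self.bin_centers, self.values / peak, self.counts, "max")


# ---------------------------------------------------------------------------
# stress coarse-graining


def coarse_grain_stress(
    tractions: np.ndarray, spacing: float = 1.0, periodic: tuple[bool, ...] | None = None
) -> StressField:
    """Coarse-grained stress from a per-node traction(-density) field.

    ``tractions`` has shape grid_shape + (d,).  For each node the stress is
    the dyadic sum (1/a0^d) sum_j r_ij (x) T_j over the 2d nearest
    neighbours j (the smallest symmetric stencil), with r_ij = x_i - x_j.
    Periodic axes wrap; non-periodic axes drop the out-of-range neighbour.
    """
    tractions = np.asarray(tractions, dtype=float)
    d = tractions.shape[-1]
    grid_shape = tractions.shape[:-1]
    if len(grid_shape) != d:
        raise ValueError("traction field must have one vector component per grid axis")
    if periodic is None:
        periodic = (True, True, False)[:d] if d == 3 else (True,) * d
    sigma = np.zeros(grid_shape + (d, d))
    a0 = spacing
    for axis in range(d):
        for sgn in (+1, -1):
            Tn = np.roll(tractions, -sgn, axis=axis)
            if not periodic[axis]:
                sl = [slice(None)] * (d + 1)
                sl[axis] = -1 if sgn > 0 else 0
                Tn[tuple(sl)] = 0.0
            # r_ij = x_i - x_j = -sgn * a0 * e_axis
            sigma[..., axis, :] += (-sgn * a0) * Tn
    sigma /= a0**d
    return StressField(sigma, spacing)


def isotropic_stress(stress: StressField, mode: str = "2d-half-trace") -> np.ndarray:
    """Scalar isotropic stress: half the trace of the in-plane block.

    ``2d-half-trace`` expects a 2x2 tensor field; ``3d-in-plane`` takes the
    in-plane part (sigma_xx + sigma_yy)/2 of a 3x3 field, as used for the
    2D isotropic stress of a monolayer.
    """
    c = stress.components
    if mode == "2d-half-trace":
        if stress.ndim_tensor != 2:
            raise ValueError("2d-half-trace requires a 2x2 tensor field")
    elif mode == "3d-in-plane":
        if stress.ndim_tensor != 3:
            raise ValueError("3d-in-plane requires a 3x3 tensor field")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 0.5 * (c[..., 0, 0] + c[..., 1, 1])


# ---------------------------------------------------------------------------
# fluctuations


def susceptibility(values: np.ndarray, N: int | None = None) -> float:
    """Susceptibility chi = N * (<A^2> - <A>^2) (population variance).

    ``N`` defaults to the number of samples; pass the number of cells or
    pixels explicitly to use a different sample-size convention.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("susceptibility needs at least 2 samples")
    if N is None:
        N = v.size
    if np.all(v == v[0]):
        return 0.0  # exactly zero for a constant field, whatever the value
    return float(N * v.var())


def interface_mask(occupancy: np.ndarray) -> np.ndarray:
    """Pixels where the two populations meet (8-connected adjacency).

    A pixel belongs to the interface if it carries one type and has a
    neighbour of the other type.
    """
    occ = np.asarray(occupancy)
    a = occ == 1
    b = occ == 2
    st = np.ones((3, 3), dtype=bool)
    a_dil = ndimage.binary_dilation(a, structure=st)
    b_dil = ndimage.binary_dilation(b, structure=st)
    return (a & b_dil) | (b & a_dil)


def interface_distance_map(occupancy: np.ndarray) -> np.ndarray:
    """Euclidean distance of every pixel to the nearest interface pixel."""
    iface = interface_mask(occupancy)
    if not iface.any():
        raise ValueError("occupancy map has no two-population interface")
    return ndimage.distance_transform_edt(~iface)


def _distance_bins(dist_max: float, bin_width: float) -> np.ndarray:
    n = max(int(np.ceil(dist_max / bin_width)), 1)
    return np.arange(n + 1) * bin_width


def susceptibility_profile(
    frames: np.ndarray,
    occupancy: np.ndarray,
    bin_width: float = 10.0,
    normalize: bool = False,
    types: tuple[int, ...] = (1, 2),
    n_convention: str = "pixels",
) -> dict[int, Profile]:
    """Susceptibility of a scalar field versus distance from the interface.

    ``frames``: (T, ny, nx) scalar field frames; ``occupancy``: (ny, nx) or
    (T, ny, nx) type labels.  Pixels are binned by Euclidean distance to
    the interface separately per type; chi in each bin is the variance of
    the pooled (space x time) samples times N, where N is the mean number
    of pixels the bin holds per frame (``pixels`` convention).  Empty bins
    are NaN with count 0, not zero.
    """
    frames = np.atleast_3d(np.asarray(frames, dtype=float))
    if frames.ndim == 2:
        frames = frames[None]
    occ_frames = np.asarray(occupancy)
    static_occ = occ_frames.ndim == 2
    dist = interface_distance_map(occ_frames if static_occ else occ_frames[0])
    edges = _distance_bins(dist.max() + 1e-9, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out: dict[int, Profile] = {}
    for t in types:
        vals = np.full(len(centers), np.nan)
        counts = np.zeros(len(centers), dtype=float)
        for b in range(len(centers)):
            samples = []
            npix = 0.0
            for f in range(frames.shape[0]):
                occ = occ_frames if static_occ else occ_frames[f]
                if not static_occ:
                    dist = interface_distance_map(occ)
                sel = (occ == t) & (dist >= edges[b]) & (dist < edges[b + 1])
                npix += sel.sum()
                samples.append(frames[f][sel])
            samples = np.concatenate(samples)
            counts[b] = npix / frames.shape[0]
            if samples.size >= 2 and counts[b] > 0:
                vals[b] = counts[b] * samples.var()
        prof = Profile(centers, vals, counts)
        out[t] = prof.normalized() if normalize else prof
    return out


def autocorrelation_and_length(
    frames: np.ndarray,
    mask: np.ndarray | None = None,
    max_lag: int | None = None,
    frame_median: bool = False,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Radially averaged spatial autocorrelation and its first zero crossing.

    The field is mean-subtracted over the mask, zero-padded (non-periodic
    estimate) and correlated via FFT with overlap-count normalization.
    Returns (radii, C(r) averaged over frames, correlation length).  C(0)
    is exactly 1.  If C never crosses zero within ``max_lag`` the length is
    right-censored at the largest radius.

    With ``frame_median`` the length is the median of per-frame zero
    crossings instead of the crossing of the frame-averaged curve; the
    median is much more robust to the long-lag noise of a single run.
    Note the estimator's bias: for a field whose true autocovariance is
    positive (e.g. squared-exponential with e-folding length ``ell``), the
    crossing exists only because of the in-mask mean subtraction, at
    approximately ell * sqrt(2 ln(L^2 / (2 pi ell^2))) for domain size L.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    ny, nx = frames.shape[1:]
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if min(mask.sum(axis=0).max(initial=0), mask.sum(axis=1).max(initial=0)) < 32:
        raise ValueError("mask region too small (need >= 32 px linear extent)")
    if max_lag is None:
        max_lag = min(ny, nx) // 2
    shape = (2 * ny, 2 * nx)
    Fm = np.fft.rfft2(mask.astype(float), shape)
    overlap = np.fft.irfft2(Fm * np.conj(Fm), shape).real
    curves = []
    for f in frames:
        g = np.where(mask, f - f[mask].mean(), 0.0)
        Fg = np.fft.rfft2(g, shape)
        num = np.fft.irfft2(Fg * np.conj(Fg), shape).real
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(overlap > 0.5, num / np.maximum(overlap, 0.5), np.nan)
        corr /= corr[0, 0]
        # radial average over lags
        yy = np.minimum(np.arange(2 * ny), 2 * ny - np.arange(2 * ny))
        xx = np.minimum(np.arange(2 * nx), 2 * nx - np.arange(2 * nx))
        R = np.hypot(yy[:, None], xx[None, :])
        rbin = np.rint(R).astype(int)
        sel = (rbin <= max_lag) & np.isfinite(corr)
        sums = np.bincount(rbin[sel], corr[sel], minlength=max_lag + 1)
        cnts = np.bincount(rbin[sel], minlength=max_lag + 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            curves.append(np.where(cnts > 0, sums / cnts, np.nan))
    radii = np.arange(max_lag + 1, dtype=float)

    def _crossing(curve: np.ndarray) -> float:
        below = np.nonzero(curve <= 0)[0]
        if below.size == 0:
            return float(radii[-1])  # right-censored
        j = int(below[0])
        c1, c0 = curve[j], curve[j - 1]
        return float(radii[j - 1] + c0 / (c0 - c1) * (radii[j] - radii[j - 1]))

    C = np.nanmean(np.stack(curves), axis=0)
    C[0] = 1.0
    if frame_median:
        length = float(np.median([_crossing(c) for c in curves]))
    else:
        length = _crossing(C)
    return radii, C, length


# ---------------------------------------------------------------------------
# extrusion statistics


def detect_extrusion_sim(
    trajectory,
    contact_fraction: float = 0.01,
    height_offset: float | None = None,
) -> pd.DataFrame:
    """Extrusion events from a simulated trajectory.

    A cell is flagged extruded at the first saved step where its substrate
    contact integral (int phi^2 phi_w^2 dx) drops below ``contact_fraction``
    of its initial value AND its centre-of-mass height exceeds the
    population median by more than R0/2 (``height_offset`` overrides R0/2).
    The physics has no explicit threshold; these are detection thresholds
    of the analysis layer.  Returns (step, x, y, id, type), one row per
    cell, permanent flags.
    """
    contacts = trajectory.contact_series  # (n_saves, n_cells)
    zs = trajectory.z_com_series
    xy = trajectory.xy_com_series  # (n_saves, n_cells, 2)
    r0 = trajectory.config.R0
    if height_offset is None:
        height_offset = r0 / 2.0
    init = contacts[0]
    rows = []
    flagged = set()
    for s in range(contacts.shape[0]):
        zmed = np.median(zs[s])
        for i in range(contacts.shape[1]):
            if i in flagged:
                continue
            low_contact = contacts[s, i] < contact_fraction * max(init[i], 1e-300)
            raised = zs[s, i] > zmed + height_offset
            if low_contact and raised:
                flagged.add(i)
                rows.append(
                    {
                        "step": int(trajectory.saved_steps[s]),
                        "x": float(xy[s, i, 0]),
                        "y": float(xy[s, i, 1]),
                        "id": int(trajectory.cell_ids[i]),
                        "type": trajectory.cell_types[i],
                    }
                )
    return pd.DataFrame(rows, columns=["step", "x", "y", "id", "type"])


def extrusion_distance_pdf(
    events: pd.DataFrame,
    occupancy: np.ndarray,
    bin_width: float = 10.0,
    types: tuple[int, ...] = (1, 2),
) -> dict[int, Profile]:
    """Probability of extrusion given the distance from the interface.

    For each type, events are binned by the interface distance at their
    position and divided by the number of pixels of that type in the bin
    (the random-placement probability), then renormalized to sum to 1 over
    bins.  Events falling on a pixel of the other type are assigned to the
    nearest same-type pixel and reported in the profile's ``counts``.
    """
    occ = np.asarray(occupancy)
    dist = interface_distance_map(occ)
    edges = _distance_bins(dist.max() + 1e-9, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out: dict[int, Profile] = {}
    for t in types:
        region = occ == t
        if not region.any():
            continue
        ev = events[events["type"] == t]
        xi = np.clip(np.rint(ev["x"].to_numpy()).astype(int), 0, occ.shape[1] - 1)
        yi = np.clip(np.rint(ev["y"].to_numpy()).astype(int), 0, occ.shape[0] - 1)
        misassigned = ~region[yi, xi]
        if misassigned.any():
            # snap to the nearest pixel of the right type
            _, (iy, ix) = ndimage.distance_transform_edt(~region, return_indices=True)
            yi_new = np.where(misassigned, iy[yi, xi], yi)
            xi_new = np.where(misassigned, ix[yi, xi], xi)
            yi, xi = yi_new, xi_new
        d_ev = dist[yi, xi]
        counts, _ = np.histogram(d_ev, bins=edges)
        pix, _ = np.histogram(dist[region], bins=edges)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(pix > 0, counts / pix, np.nan)
        tot = np.nansum(p)
        if tot > 0:
            p = p / tot
        out[t] = Profile(centers, p, counts.astype(float))
    return out


def uniformity_gof_pvalue(
    events: pd.DataFrame, occupancy: np.ndarray, bin_width: float, type_label: int = 2
) -> float:
    """Chi-square goodness-of-fit p-value of event distances against the
    uniform-placement null (expected counts proportional to per-bin pixel
    availability)."""
    from scipy import stats

    occ = np.asarray(occupancy)
    dist = interface_distance_map(occ)
    region = occ == type_label
    edges = _distance_bins(dist[region].max() + 1e-9, bin_width)
    ev = events[events["type"] == type_label]
    xi = np.rint(ev["x"].to_numpy()).astype(int)
    yi = np.rint(ev["y"].to_numpy()).astype(int)
    obs, _ = np.histogram(dist[yi, xi], bins=edges)
    pix, _ = np.histogram(dist[region], bins=edges)
    keep = pix > 0
    exp = pix[keep] / pix[keep].sum() * obs[keep].sum()
    # merge sparse bins to keep the chi-square approximation valid
    obs_k, exp_k = obs[keep].astype(float), exp
    while len(obs_k) > 2 and exp_k.min() < 5:
        j = int(np.argmin(exp_k))
        k = j - 1 if j > 0 else 1
        exp_k[k] += exp_k[j]
        obs_k[k] += obs_k[j]
        exp_k = np.delete(exp_k, j)
        obs_k = np.delete(obs_k, j)
    return float(stats.chisquare(obs_k, exp_k).pvalue)


def extrusion_rate(
    events: pd.DataFrame,
    occupancy_frames: np.ndarray,
    interval_frames: int,
    frame_duration: float,
    pixel_area: float,
    types: tuple[int, ...] = (1, 2),
    rolling: int = 1,
) -> pd.DataFrame:
    """Extrusion rate per unit time per unit occupied area.

    Events are counted per type in consecutive windows of
    ``interval_frames`` frames and divided by the mean area occupied by
    that type over the window (pixel count x ``pixel_area``) and by the
    window duration.  ``rolling`` applies a centred rolling mean over that
    many intervals.  Intervals in which a type occupies no area get NaN.
    """
    occupancy_frames = np.asarray(occupancy_frames)
    if occupancy_frames.ndim == 2:
        occupancy_frames = occupancy_frames[None]
    n_frames = occupancy_frames.shape[0]
    n_int = max(n_frames // interval_frames, 1)
    rows = []
    for w in range(n_int):
        f0, f1 = w * interval_frames, min((w + 1) * interval_frames, n_frames)
        dur = (f1 - f0) * frame_duration
        for t in types:
            area = (occupancy_frames[f0:f1] == t).sum(axis=(1, 2)).mean() * pixel_area
            n_ev = int(((events["type"] == t) & (events["frame"] >= f0) & (events["frame"] < f1)).sum())
            rate = n_ev / (dur * area) if area > 0 else np.nan
            rows.append({"interval": w, "type": t, "count": n_ev, "area": area, "rate": rate})
    df = pd.DataFrame(rows)
    if rolling > 1:
        df["rate"] = (
            df.groupby("type")["rate"]
            .transform(lambda s: s.rolling(rolling, center=True, min_periods=1).mean())
        )
    return df


def area_from_fraction(fraction: float, fov_area_mm2: float = FOV_AREA_10X_MM2) -> float:
    """Absolute occupied area (mm^2) from an area fraction of the field of
    view (0.514188 mm^2 for the 10x objective)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return fraction * fov_area_mm2


def _cut_window(field: np.ndarray, x: float, y: float, half: int) -> np.ndarray | None:
    xi, yi = int(round(x)), int(round(y))
    if (
        yi - half < 0
        or xi - half < 0
        or yi + half + 1 > field.shape[0]
        or xi + half + 1 > field.shape[1]
    ):
        return None
    return field[yi - half : yi + half + 1, xi - half : xi + half + 1]


def _opponent_direction(occupancy: np.ndarray, x: float, y: float, type_label: int) -> float:
    """Angle (rad) from the event towards the nearest opposing-type pixel."""
    other = occupancy == (1 if type_label == 2 else 2)
    _, (iy, ix) = ndimage.distance_transform_edt(~other, return_indices=True)
    yi = int(round(y)); xi = int(round(x))
    yi = np.clip(yi, 0, occupancy.shape[0] - 1)
    xi = np.clip(xi, 0, occupancy.shape[1] - 1)
    return float(np.arctan2(iy[yi, xi] - yi, ix[yi, xi] - xi))


def ensemble_stress_map(
    stress_frames: np.ndarray,
    events: pd.DataFrame,
    occupancy: np.ndarray,
    window_half: int = 30,
    epoch: tuple[int, int] = (-4, -3),
    band: tuple[float, float] | None = None,
    align: bool = True,
    reduce: str = "median",
) -> dict:
    """Event-centred, orientation-aligned ensemble stress map.

    For each event, the scalar stress averaged over the epoch (frame
    offsets relative to the event, end-exclusive) is cut in a square window
    around the event position and, if ``align``, rotated so the opposing
    population lies in one fixed half-plane (the increasing-first-index
    half of the returned array); the per-pixel ``median`` (or
    ``mean``) across events is returned together with the histogram of the
    collected values.  Events outside the distance ``band`` (min, max, in
    pixels from the interface) or too close to the frame edge are excluded
    and counted.
    """
    stress_frames = np.asarray(stress_frames, dtype=float)
    occ = np.asarray(occupancy)
    occ0 = occ if occ.ndim == 2 else occ[0]
    dist = interface_distance_map(occ0)
    maps = []
    n_excluded = 0
    for _, ev in events.iterrows():
        f = int(ev["frame"]) if "frame" in ev else int(ev["step"])
        f0, f1 = f + epoch[0], f + epoch[1]
        if f0 < 0 or f1 > stress_frames.shape[0] or f1 <= f0:
            n_excluded += 1
            continue
        if band is not None:
            d = dist[int(round(ev["y"])) % dist.shape[0], int(round(ev["x"])) % dist.shape[1]]
            if not band[0] <= d <= band[1]:
                n_excluded += 1
                continue
        mean_field = stress_frames[f0:f1].mean(axis=0)
        # cut larger then rotate then crop, to avoid rotation padding artefacts
        pad = int(np.ceil(window_half * 0.4142)) + 1
        big = _cut_window(mean_field, ev["x"], ev["y"], window_half + pad)
        if big is None:
            n_excluded += 1
            continue
        if align:
            occ_f = occ0 if occ.ndim == 2 else occ[min(f, occ.shape[0] - 1)]
            ang = _opponent_direction(occ_f, ev["x"], ev["y"], int(ev["type"]))
            # rotate so the opponent direction points to +y (up in row space)
            big = ndimage.rotate(
                big, np.degrees(ang) - 90.0, reshape=False, order=1, mode="nearest"
            )
        c = big.shape[0] // 2
        maps.append(big[c - window_half : c + window_half + 1, c - window_half : c + window_half + 1])
    if not maps:
        raise ValueError("no usable events for the ensemble map")
    stack = np.stack(maps)
    agg = np.median(stack, axis=0) if reduce == "median" else stack.mean(axis=0)
    hist, edges = np.histogram(stack.ravel(), bins=64, density=True)
    return {
        "map": agg,
        "n_events": len(maps),
        "n_excluded": n_excluded,
        "pdf": hist,
        "pdf_edges": edges,
    }


def local_susceptibility_timecourse(
    stress_frames: np.ndarray,
    events: pd.DataFrame,
    window_half: int = 30,
    t_range: tuple[int, int] = (-8, 2),
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean susceptibility in a square around each event versus time to
    extrusion (frame offsets, t=0 the detection frame).

    chi per frame is the pixel count of the square times the variance of
    the stress values inside it; the ensemble mean over events is
    optionally normalized to its earliest time point.
    """
    stress_frames = np.asarray(stress_frames, dtype=float)
    offsets = np.arange(t_range[0], t_range[1] + 1)
    per_event = []
    for _, ev in events.iterrows():
        f = int(ev["frame"]) if "frame" in ev else int(ev["step"])
        if f + offsets[0] < 0 or f + offsets[-1] >= stress_frames.shape[0]:
            continue
        w0 = _cut_window(stress_frames[f], ev["x"], ev["y"], window_half)
        if w0 is None:
            continue
        chis = []
        for dt in offsets:
            w = _cut_window(stress_frames[f + dt], ev["x"], ev["y"], window_half)
            chis.append(susceptibility(w))
        per_event.append(chis)
    if not per_event:
        raise ValueError("no usable events for the susceptibility time course")
    chi_t = np.mean(np.array(per_event), axis=0)
    if normalize:
        chi_t = chi_t / chi_t[0]
    return offsets, chi_t


def sigma_zz_distributions(
    stress_frames: list[StressField] | np.ndarray,
    occupancy: np.ndarray,
    region_width: float,
    bins: int = 64,
    types: tuple[int, ...] = (1, 2),
) -> dict[int, dict[str, np.ndarray]]:
    """PDF and CDF of the out-of-plane stress near the interface, per type.

    ``stress_frames`` are 3D-tensor stress fields (z-projected to 2D maps of
    sigma_zz and in-plane isotropic stress).  Values are collected within
    ``region_width`` of the interface and normalized by the maximum
    in-plane compression magnitude over the same region.
    """
    occ = np.asarray(occupancy)
    if isinstance(stress_frames, np.ndarray):
        raise ValueError("sigma_zz distributions require 3D tensor StressFields")
    zz_maps, iso_maps = [], []
    for sf in stress_frames:
        if sf.ndim_tensor != 3:
            raise ValueError("sigma_zz distributions require 3D tensor stress")
        c = sf.components
        # project over z (grid axes are (x, y, z))
        zz_maps.append(c[..., 2, 2].mean(axis=-1).T)  # -> (y, x) image layout
        iso_maps.append(0.5 * (c[..., 0, 0] + c[..., 1, 1]).mean(axis=-1).T)
    dist = interface_distance_map(occ)
    band = dist <= region_width
    iso_all = np.stack(iso_maps)
    compression = -iso_all[:, band].min()
    if compression <= 0:
        compression = max(np.abs(iso_all[:, band]).max(), 1e-300)
    out: dict[int, dict[str, np.ndarray]] = {}
    for t in types:
        sel = band & (occ == t)
        vals = np.concatenate([zz[sel] for zz in zz_maps]) / compression
        hist, edges = np.histogram(vals, bins=bins, density=True)
        order = np.sort(vals)
        cdf = np.arange(1, len(order) + 1) / len(order)
        out[t] = {"pdf": hist, "edges": edges, "cdf_x": order, "cdf": cdf, "values": vals}
    return out


def interface_convexity(mask: np.ndarray, simplify_tol: float = 1.0) -> float:
    """Convexity of a population island in (0, 1].

    The island boundary is traced at subpixel resolution, simplified with a
    Douglas-Peucker tolerance of ``simplify_tol`` pixels (removing the
    marching-squares staircase, which otherwise inflates diagonal edges by
    up to ~8%), and scored as perimeter(convex hull) / perimeter(island):
    1 for convex shapes, < 1 for indented interfaces.  The literal
    island/hull perimeter ratio (>= 1) is the reciprocal.
    """
    from shapely.geometry import Polygon
    from skimage import measure

    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    lab, n = ndimage.label(mask)
    if n != 1:
        raise ValueError(f"mask must be a single connected component (got {n})")
    contours = measure.find_contours(np.pad(mask, 1).astype(float), 0.5)
    boundary = max(contours, key=len)
    poly = Polygon(boundary[:, ::-1]).simplify(simplify_tol)
    perim = poly.length
    hull_perim = poly.convex_hull.length
    if perim == 0:
        raise ValueError("degenerate mask with zero perimeter")
    return float(min(hull_perim / perim, 1.0))
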