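"""Synthetic inputs with known ground truth for every analysis stage.

Each generator is a pure function of its arguments (including the seed), so
outputs are bit-reproducible, and each returns the true parameters alongside
the data so downstream tests never re-derive them.

Generators cover: stationary Gaussian random fields with a prescribed
correlation length (squared-exponential autocovariance), two-population
occupancy geometries, fields whose variance is boosted in a band around the
interface, extrusion-event catalogs with uniform or exponentially
interface-biased placement, smooth stress/traction pairs consistent with 2D
force balance (for the stress-inference benchmark), and noisy bead
displacements from known tractions (for the traction-recovery benchmark).
"""

from __future__ import annotations

import numpy as np

from . import tfm as _tfm
from .tfm import (
    DisplacementField2D,
    ElasticSubstrate,
    Stress2DField,
    TractionField2D,
)

__all__ = [
    "gen_gaussian_field",
    "gen_occupancy_bands",
    "gen_interface_variance_field",
    "gen_extrusion_catalog",
    "gen_stress_traction_pair",
    "gen_displacement_from_traction",
]


def gen_gaussian_field(
    shape: tuple[int, int],
    ell: float,
    variance: float = 1.0,
    n_frames: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Stationary Gaussian random field frames with squared-exponential
    autocovariance C(r) = variance * exp(-r^2 / (2 ell^2)).

    ``ell`` is the e-folding correlation length in pixels; ``ell <= 0``
    degenerates to white noise.  The field is synthesized spectrally on a
    periodic domain and normalized analytically (not per sample), so the
    ensemble variance equals the target and the sample variance converges
    to it with domain size.
    """
    ny, nx = shape
    if ell >= min(nx, ny) / 4:
        raise ValueError("correlation length too large for the domain (need ell < extent/4)")
    rng = np.random.default_rng(seed)
    ky = 2 * np.pi * np.fft.fftfreq(ny)
    kx = 2 * np.pi * np.fft.fftfreq(nx)
    KX, KY = np.meshgrid(kx, ky)
    k2 = KX**2 + KY**2
    amp = np.exp(-k2 * ell**2 / 4.0) if ell > 0 else np.ones_like(k2)
    # normalize so the real-space variance is exact for the discrete spectrum
    power = amp**2
    power /= power.mean()
    frames = np.empty((n_frames, ny, nx))
    for f in range(n_frames):
        white = rng.standard_normal((ny, nx))
        frames[f] = np.fft.ifft2(np.fft.fft2(white) * np.sqrt(power)).real
    frames *= np.sqrt(variance)
    truth = {"ell": ell, "variance": variance, "seed": seed, "shape": tuple(shape)}
    return frames, truth


def gen_occupancy_bands(
    shape: tuple[int, int], band_fraction: float = 0.5
) -> np.ndarray:
    """Two-population occupancy labels: type A (label 1) occupies a central
    vertical band in x, type B (label 2) the complement.  Under periodic x
    this produces two straight interfaces."""
    ny, nx = shape
    labels = np.full((ny, nx), 2, dtype=np.int8)
    half = band_fraction / 2.0
    x = np.arange(nx)
    central = np.abs((x + 0.5) / nx - 0.5) < half
    labels[:, central] = 1
    return labels


def gen_interface_variance_field(
    shape: tuple[int, int],
    occupancy: np.ndarray,
    boost: float = 4.0,
    band_width: float = 16.0,
    ell: float = 0.0,
    n_frames: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Random field frames whose variance is multiplied by ``boost`` within
    ``band_width`` pixels of the two-population interface.

    Ground truth for the susceptibility-versus-distance profile: the
    profile should peak in the interface bin with a pre-normalization ratio
    of about ``boost``.
    """
    from .stress_stats import interface_distance_map

    if boost <= 0:
        raise ValueError("boost must be positive")
    frames, truth = gen_gaussian_field(shape, ell, 1.0, n_frames, seed)
    dist = interface_distance_map(occupancy)
    gain = np.where(dist <= band_width, np.sqrt(boost), 1.0)
    frames = frames * gain
    truth.update({"boost": boost, "band_width": band_width})
    return frames, truth


def gen_extrusion_catalog(
    occupancy: np.ndarray,
    n_events: int,
    type_label: int = 2,
    bias: str = "uniform",
    decay: float | None = None,
    n_frames: int = 1,
    seed: int = 0,
):
    """Extrusion-event catalog with a prescribed interface-distance law.

    Events are sampled among the pixels of ``type_label``; ``bias='uniform'``
    weights all pixels equally, ``bias='exp'`` weights by exp(-d/decay) with
    d the distance to the population interface.  Returns a DataFrame with
    columns (frame, x, y, type) plus the truth dict.
    """
    import pandas as pd

    from .stress_stats import interface_distance_map

    rng = np.random.default_rng(seed)
    yy, xx = np.nonzero(occupancy == type_label)
    if len(xx) == 0:
        raise ValueError(f"occupancy has no pixels of type {type_label}")
    if bias == "uniform":
        w = np.ones(len(xx))
    elif bias == "exp":
        if decay is None or decay <= 0:
            raise ValueError("exponential bias requires a positive decay length")
        dist = interface_distance_map(occupancy)
        w = np.exp(-dist[yy, xx] / decay)
    else:
        raise ValueError(f"unknown bias {bias!r}")
    w = w / w.sum()
    idx = rng.choice(len(xx), size=n_events, replace=True, p=w)
    frames = rng.integers(0, n_frames, size=n_events)
    cat = pd.DataFrame(
        {
            "frame": frames,
            "x": xx[idx].astype(float),
            "y": yy[idx].astype(float),
            "type": type_label,
        }
    ).sort_values("frame", kind="stable", ignore_index=True)
    truth = {"bias": bias, "decay": decay, "n_events": n_events, "seed": seed}
    return cat, truth


def gen_stress_traction_pair(
    shape: tuple[int, int] = (128, 128),
    smoothness: float = 8.0,
    amplitude: float = 100.0,
    pixel_size: float = 1.0,
    seed: int = 0,
) -> tuple[Stress2DField, TractionField2D, dict]:
    """Smooth random symmetric 2D stress field and its balancing traction.

    The stress is parameterized as the symmetrized gradient of a smooth
    random vector potential (evaluated with the same discrete operators the
    inversion uses), which guarantees it carries no silent gauge component:
    the pair (sigma, t = -div sigma) is an exactly consistent benchmark for
    :func:`mechcomp.tfm.bism`.
    """
    if smoothness <= 0:
        raise ValueError("smoothness (correlation length of the potential) must be positive")
    ny, nx = shape
    if min(nx, ny) < 64:
        raise ValueError("grid must be at least 64x64")
    wx, _ = gen_gaussian_field(shape, smoothness, 1.0, 1, seed)
    wy, _ = gen_gaussian_field(shape, smoothness, 1.0, 1, seed + 1_000_003)
    A = _tfm.divergence_operator(shape, pixel_size)
    svec = A.T @ np.concatenate([wx[0].ravel(), wy[0].ravel()])
    svec *= amplitude / np.abs(svec).max()
    n = ny * nx
    stress = Stress2DField(
        svec[:n].reshape(shape),
        svec[n : 2 * n].reshape(shape),
        svec[2 * n :].reshape(shape),
        pixel_size,
    )
    traction = _tfm.forward_traction_from_stress(stress)
    truth = {"smoothness": smoothness, "amplitude": amplitude, "seed": seed}
    return stress, traction, truth


def gen_bandlimited_traction(
    shape: tuple[int, int] = (128, 128),
    k_sigma: float = 0.01,
    t_max: float = 100.0,
    pixel_size: float = 1.0,
    seed: int = 0,
) -> TractionField2D:
    """Zero-mean band-limited random traction field (Pa), the ground truth
    of the traction-recovery benchmark.  ``k_sigma`` is the spectral width
    in cycles/pixel."""
    rng = np.random.default_rng(seed)
    ny, nx = shape
    kx = np.fft.fftfreq(nx)
    ky = np.fft.fftfreq(ny)
    KX, KY = np.meshgrid(kx, ky)
    filt = np.exp(-(KX**2 + KY**2) / (2 * k_sigma**2))
    comps = []
    for _ in range(2):
        w = rng.standard_normal(shape)
        t = np.fft.ifft2(np.fft.fft2(w) * filt).real
        comps.append(t - t.mean())
    scale = t_max / max(np.abs(comps[0]).max(), np.abs(comps[1]).max())
    return TractionField2D(comps[0] * scale, comps[1] * scale, pixel_size)


def gen_displacement_from_traction(
    traction: TractionField2D,
    substrate: ElasticSubstrate,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[DisplacementField2D, dict]:
    """Forward substrate displacement plus i.i.d. Gaussian bead noise.

    ``noise_sigma`` is the standard deviation of the additive noise in um;
    it emulates PIV measurement error on the bead images.
    """
    u = _tfm.forward_displacement(traction, substrate)
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        u = DisplacementField2D(
            u.u_x + rng.normal(0.0, noise_sigma, u.u_x.shape),
            u.u_y + rng.normal(0.0, noise_sigma, u.u_y.shape),
            u.pixel_size,
            u.frame,
        )
    truth = {"noise_sigma": noise_sigma, "seed": seed, "E": substrate.E, "nu": substrate.nu}
    return u, truth
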