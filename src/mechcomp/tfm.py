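"""Traction-force and monolayer-stress inference on elastic substrates.

Two linear inverse problems are implemented:

* **FTTC** (Fourier-transform traction cytometry): substrate displacements
  ``u`` relate to tractions ``t`` through the Boussinesq half-space Green
  tensor, ``u(k) = G(k) t(k)`` mode by mode.  The inverse is Tikhonov
  regularized, ``t = (G*G + lambda I)^-1 G* u``, with the rigid zero-
  frequency mode set to zero (force balance over the field of view).

* **BISM** (Bayesian inversion stress microscopy): the 2D tissue stress
  tensor ``sigma`` is inferred from the traction field through mechanical
  force balance ``div sigma = -t``, discretized as a sparse linear system
  and solved as a Tikhonov/maximum-a-posteriori least-squares problem with
  a dimensionless prior weight ``Lambda`` scaled to the normalized system
  matrix.  The additive (gauge) freedom is resolved by the minimum-norm
  prior, which drives the spatial mean of the stress to zero.

Units follow the traction-force-microscopy convention: displacements in um,
Young modulus and tractions in Pa, 2D tissue stress in Pa*um (tension per
unit length of monolayer cross-section).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "DisplacementField2D",
    "TractionField2D",
    "Stress2DField",
    "ElasticSubstrate",
    "forward_displacement",
    "fttc",
    "bism",
    "forward_traction_from_stress",
    "divergence_operator",
]


@dataclass
class ElasticSubstrate:
    """Linear-elastic half-space substrate plus inversion hyper-parameters.

    E: Young modulus (Pa).  nu: Poisson ratio (0.5 for incompressible
    silicone).  lambda_fttc: Tikhonov weight of the FTTC inversion, in the
    units of |G(k)|^2, i.e. (um/Pa)^2.  lambda_bism: dimensionless prior
    weight of the BISM inversion.
    """

    E: float = 45_000.0
    nu: float = 0.5
    lambda_fttc: float = 9e-9
    lambda_bism: float = 1e-6

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("Young modulus must be positive")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")
        if self.lambda_fttc < 0:
            raise ValueError("lambda_fttc must be nonnegative")
        if self.lambda_bism < 0:
            raise ValueError("lambda_bism must be nonnegative")


@dataclass
class DisplacementField2D:
    """In-plane substrate displacement field, components in um."""

    u_x: np.ndarray
    u_y: np.ndarray
    pixel_size: float = 1.0
    frame: int = 0

    def __post_init__(self) -> None:
        self.u_x = np.asarray(self.u_x, dtype=float)
        self.u_y = np.asarray(self.u_y, dtype=float)
        if self.u_x.shape != self.u_y.shape or self.u_x.ndim != 2:
            raise ValueError("u_x and u_y must be 2D arrays of equal shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if not (np.isfinite(self.u_x).all() and np.isfinite(self.u_y).all()):
            raise ValueError("displacement field contains non-finite values")


@dataclass
class TractionField2D:
    """In-plane traction stress exerted by cells on the substrate (Pa)."""

    t_x: np.ndarray
    t_y: np.ndarray
    pixel_size: float = 1.0
    frame: int = 0

    def __post_init__(self) -> None:
        self.t_x = np.asarray(self.t_x, dtype=float)
        self.t_y = np.asarray(self.t_y, dtype=float)
        if self.t_x.shape != self.t_y.shape or self.t_x.ndim != 2:
            raise ValueError("t_x and t_y must be 2D arrays of equal shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.t_x, self.t_y)


@dataclass
class Stress2DField:
    """Symmetric 2D tissue stress tensor (Pa*um)."""

    sigma_xx: np.ndarray
    sigma_xy: np.ndarray
    sigma_yy: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.sigma_xx = np.asarray(self.sigma_xx, dtype=float)
        self.sigma_xy = np.asarray(self.sigma_xy, dtype=float)
        self.sigma_yy = np.asarray(self.sigma_yy, dtype=float)
        if not (self.sigma_xx.shape == self.sigma_xy.shape == self.sigma_yy.shape):
            raise ValueError("stress components must share one shape")

    @property
    def isotropic(self) -> np.ndarray:
        """Half trace; negative = compression, positive = tension."""
        return 0.5 * (self.sigma_xx + self.sigma_yy)


def _wavevectors(shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = shape
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=pixel_size)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=pixel_size)
    KX, KY = np.meshgrid(kx, ky)
    return KX, KY


def _green_tensor(KX: np.ndarray, KY: np.ndarray, substrate: ElasticSubstrate) -> np.ndarray:
    """Boussinesq surface Green tensor in Fourier space, shape (ny, nx, 2, 2)."""
    E, nu = substrate.E, substrate.nu
    k2 = KX**2 + KY**2
    k = np.sqrt(k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k**3)
        G = np.empty(KX.shape + (2, 2))
        G[..., 0, 0] = pref * ((1.0 - nu) * k2 + nu * KY**2)
        G[..., 1, 1] = pref * ((1.0 - nu) * k2 + nu * KX**2)
        G[..., 0, 1] = -pref * nu * KX * KY
        G[..., 1, 0] = G[..., 0, 1]
    G[np.isclose(k, 0.0)] = 0.0
    return G


def forward_displacement(
    traction: TractionField2D, substrate: ElasticSubstrate
) -> DisplacementField2D:
    """Displacements induced on a half-space substrate by a traction field.

    Spectral convolution with the Boussinesq Green tensor; the zero-
    frequency (rigid) mode is dropped, so the output has zero mean.  Serves
    as the forward model and validation oracle for :func:`fttc`.
    """
    G = _green_tensor(*_wavevectors(traction.t_x.shape, traction.pixel_size), substrate)
    tk = np.stack([np.fft.fft2(traction.t_x), np.fft.fft2(traction.t_y)], axis=-1)
    uk = np.einsum("...ab,...b->...a", G, tk)
    u_x = np.fft.ifft2(uk[..., 0]).real
    u_y = np.fft.ifft2(uk[..., 1]).real
    return DisplacementField2D(u_x, u_y, traction.pixel_size, traction.frame)


def fttc(displacement: DisplacementField2D, substrate: ElasticSubstrate) -> TractionField2D:
    """Regularized Fourier-transform traction cytometry.

    Per-mode Tikhonov inversion of the Boussinesq forward model with weight
    ``substrate.lambda_fttc``; the mean (rigid) displacement is subtracted
    before inversion and the recovered traction has zero mean.
    """
    lam = substrate.lambda_fttc
    u_x = displacement.u_x - displacement.u_x.mean()
    u_y = displacement.u_y - displacement.u_y.mean()
    G = _green_tensor(*_wavevectors(u_x.shape, displacement.pixel_size), substrate)
    uk = np.stack([np.fft.fft2(u_x), np.fft.fft2(u_y)], axis=-1)
    # t = (G^T G + lam I)^-1 G^T u, G real-symmetric 2x2 per mode
    GtG = np.einsum("...ab,...ac->...bc", G, G)
    GtG[..., 0, 0] += lam
    GtG[..., 1, 1] += lam
    rhs = np.einsum("...ab,...a->...b", G, uk)
    tk = np.linalg.solve(GtG.astype(complex), rhs[..., None])[..., 0]
    tk[0, 0, :] = 0.0
    t_x = np.fft.ifft2(tk[..., 0]).real
    t_y = np.fft.ifft2(tk[..., 1]).real
    return TractionField2D(t_x, t_y, displacement.pixel_size, displacement.frame)


def _diff_matrix(n: int, h: float) -> sp.csr_matrix:
    """Central-difference first derivative with one-sided ends (non-periodic)."""
    main = np.zeros(n)
    upper = np.full(n - 1, 0.5 / h)
    lower = np.full(n - 1, -0.5 / h)
    D = sp.diags([lower, main, upper], [-1, 0, 1], format="lil")
    D[0, 0], D[0, 1] = -1.0 / h, 1.0 / h
    D[n - 1, n - 2], D[n - 1, n - 1] = -1.0 / h, 1.0 / h
    return D.tocsr()


def divergence_operator(shape: tuple[int, int], pixel_size: float) -> sp.csr_matrix:
    """Sparse operator A mapping stacked (sxx, sxy, syy) to -div(sigma).

    Row blocks are the x and y components of the traction
    t = -div sigma; columns are the three stress components flattened in C
    order over an (ny, nx) grid.
    """
    ny, nx = shape
    Dx1 = _diff_matrix(nx, pixel_size)
    Dy1 = _diff_matrix(ny, pixel_size)
    Ix = sp.eye(nx, format="csr")
    Iy = sp.eye(ny, format="csr")
    Dx = sp.kron(Iy, Dx1, format="csr")  # d/dx on C-ordered (ny, nx)
    Dy = sp.kron(Dy1, Ix, format="csr")
    Z = sp.csr_matrix((ny * nx, ny * nx))
    A = sp.bmat([[-Dx, -Dy, Z], [Z, -Dx, -Dy]], format="csr")
    return A


def forward_traction_from_stress(stress: Stress2DField) -> TractionField2D:
    """Traction balancing a smooth stress field: t = -div sigma.

    Central differences (one-sided at the boundary); validation oracle for
    :func:`bism`.
    """
    shape = stress.sigma_xx.shape
    A = divergence_operator(shape, stress.pixel_size)
    s = np.concatenate(
        [stress.sigma_xx.ravel(), stress.sigma_xy.ravel(), stress.sigma_yy.ravel()]
    )
    t = A @ s
    n = shape[0] * shape[1]
    return TractionField2D(t[:n].reshape(shape), t[n:].reshape(shape), stress.pixel_size)


_BISM_CACHE: dict[tuple, tuple] = {}


def _bism_system(shape: tuple[int, int], pixel_size: float, lam: float):
    """Factorized normal equations of the BISM inversion, cached per grid."""
    key = (shape, float(pixel_size), float(lam))
    if key not in _BISM_CACHE:
        n = shape[0] * shape[1]
        A = divergence_operator(shape, pixel_size)
        AtA = (A.T @ A).tocsc()
        c = AtA.diagonal().mean()
        if c == 0:
            raise ValueError("singular system: degenerate traction domain")
        M = AtA + sp.identity(3 * n, format="csc") * (lam * c)
        lu = spla.splu(M)
        if len(_BISM_CACHE) > 8:
            _BISM_CACHE.clear()
        _BISM_CACHE[key] = (A, lu.solve)
    return _BISM_CACHE[key]


def bism(
    traction: TractionField2D,
    lambda_bism: float = 1e-6,
) -> Stress2DField:
    """Bayesian inversion stress microscopy.

    Solves ``min_s ||A s - t||^2 + Lambda * c * ||s||^2`` where ``A s``
    is the sparse discrete ``-div sigma`` (force balance: the divergence of
    the tissue stress balances the traction exerted on the substrate) and
    ``c`` is the mean
    diagonal of ``A^T A``, making ``Lambda`` dimensionless.  The minimum-
    norm prior fixes the undetermined stress gauge (zero-mean stress).
    """
    if lambda_bism < 0:
        raise ValueError("lambda_bism must be nonnegative")
    shape = traction.t_x.shape
    n = shape[0] * shape[1]
    if n == 0:
        raise ValueError("empty traction field")
    A, solve = _bism_system(shape, traction.pixel_size, lambda_bism)
    b = np.concatenate([traction.t_x.ravel(), traction.t_y.ravel()])
    s = solve(A.T @ b)
    return Stress2DField(
        s[:n].reshape(shape), s[n : 2 * n].reshape(shape), s[2 * n :].reshape(shape),
        traction.pixel_size,
    )
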