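"""Optional numba kernels for the multiphase-field inner loops.

Each kernel fuses one per-cell pass (stencils, gathers from the full grid
through wrapped index arrays, and scatter accumulation) that the pure-numpy
path expresses as a sequence of whole-array operations.  Semantics match the
numpy helpers in :mod:`mechcomp.phasefield` exactly: zero halo around the
cell window in x and y, zero-Neumann stencils in z, first-order upwind
advection.  If numba is unavailable the simulator transparently falls back
to numpy.
"""

from __future__ import annotations

import numpy as np

try:
    import numba as nb

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is present in supported envs
    nb = None
    HAVE_NUMBA = False


if HAVE_NUMBA:

    @nb.njit(cache=True)
    def scatter_sums(sumphi, sumphi2, phi, ix, iy):
        W1, W2, nz = phi.shape
        for i in range(W1):
            gi = ix[i]
            for j in range(W2):
                gj = iy[j]
                for k in range(nz):
                    p = phi[i, j, k]
                    sumphi[gi, gj, k] += p
                    sumphi2[gi, gj, k] += p * p

    @nb.njit(cache=True)
    def cell_terms(
        phi, sumphi2, phi_w2, ix, iy, wrap_x, wrap_y,
        a0, lam, gamma, mu, V0, kcc, kcs, wcc,
        dF_local, gx, gy, gz, M,
    ):
        """Fused gradient/Laplacian/derivative/shape-tensor pass.

        Returns the cell volume; fills dF_local, gx, gy, gz (window arrays)
        and M (3x3 gradient second-moment, including the a0^3 measure).
        """
        W1, W2, nz = phi.shape
        inv2a = 1.0 / (2.0 * a0)
        inva2 = 1.0 / (a0 * a0)
        a03 = a0 * a0 * a0
        V = 0.0
        for i in range(W1):
            for j in range(W2):
                for k in range(nz):
                    V += phi[i, j, k] * phi[i, j, k]
        V *= a03
        c_bulk = gamma / lam * 8.0
        c_lap = 2.0 * wcc - 2.0 * gamma * lam
        c_vol = 4.0 * mu / V0 * (1.0 - V / V0)
        c_rcc = 4.0 * kcc / (lam * lam)
        c_rcs = 2.0 * kcs / (lam * lam)
        m00 = 0.0; m01 = 0.0; m02 = 0.0; m11 = 0.0; m12 = 0.0; m22 = 0.0
        for i in range(W1):
            gi = ix[i]
            for j in range(W2):
                gj = iy[j]
                for k in range(nz):
                    p = phi[i, j, k]
                    if i > 0:
                        xm = phi[i - 1, j, k]
                    else:
                        xm = phi[W1 - 1, j, k] if wrap_x else 0.0
                    if i < W1 - 1:
                        xp = phi[i + 1, j, k]
                    else:
                        xp = phi[0, j, k] if wrap_x else 0.0
                    if j > 0:
                        ym = phi[i, j - 1, k]
                    else:
                        ym = phi[i, W2 - 1, k] if wrap_y else 0.0
                    if j < W2 - 1:
                        yp = phi[i, j + 1, k]
                    else:
                        yp = phi[i, 0, k] if wrap_y else 0.0
                    if k == 0:
                        zm = p
                        zp = phi[i, j, 1]
                    elif k == nz - 1:
                        zm = phi[i, j, nz - 2]
                        zp = p
                    else:
                        zm = phi[i, j, k - 1]
                        zp = phi[i, j, k + 1]
                    lap = (xp + xm + yp + ym + zp + zm - 6.0 * p) * inva2
                    ggx = (xp - xm) * inv2a
                    ggy = (yp - ym) * inv2a
                    ggz = (zp - zm) * inv2a
                    gx[i, j, k] = ggx
                    gy[i, j, k] = ggy
                    gz[i, j, k] = ggz
                    m00 += ggx * ggx; m01 += ggx * ggy; m02 += ggx * ggz
                    m11 += ggy * ggy; m12 += ggy * ggz; m22 += ggz * ggz
                    s2 = sumphi2[gi, gj, k]
                    w2 = phi_w2[gi, gj, k]
                    dF_local[i, j, k] = (
                        c_bulk * p * (1.0 - p) * (1.0 - 2.0 * p)
                        + c_lap * lap
                        - c_vol * p
                        + c_rcc * p * (s2 - p * p)
                        + c_rcs * p * w2
                    )
        M[0, 0] = m00 * a03; M[0, 1] = m01 * a03; M[0, 2] = m02 * a03
        M[1, 0] = m01 * a03; M[1, 1] = m11 * a03; M[1, 2] = m12 * a03
        M[2, 0] = m02 * a03; M[2, 1] = m12 * a03; M[2, 2] = m22 * a03
        return V

    @nb.njit(cache=True)
    def scatter_iso_act(
        iso, act, phi, dF_local, lap_sum, lap_phi_w, wcc, wcs,
        coefs, coefs_w, phi_w, ix, iy,
    ):
        """Accumulate the cell's -dF/dphi (window-truncated: compact part
        plus the gathered adhesion pieces) into iso, and the active-stress
        contributions (coefs[c] + coefs_w[c] * phi_w) * phi into act[c]."""
        W1, W2, nz = phi.shape
        nc = coefs.shape[0]
        for i in range(W1):
            gi = ix[i]
            for j in range(W2):
                gj = iy[j]
                for k in range(nz):
                    iso[gi, gj, k] -= (
                        dF_local[i, j, k]
                        - 2.0 * wcc * lap_sum[gi, gj, k]
                        - wcs * lap_phi_w[gi, gj, k]
                    )
                    p = phi[i, j, k]
                    for c in range(nc):
                        cw = coefs_w[c]
                        if coefs[c] != 0.0 or cw != 0.0:
                            act[c, gi, gj, k] += (
                                coefs[c] + cw * phi_w[gi, gj, k]
                            ) * p

    @nb.njit(cache=True)
    def contract_force(iso, act, gx, gy, gz, ix, iy, a0):
        """F_a = -a0^3 sum_x Pi_ab d_b phi, with Pi = iso I + act(6 comps,
        order xx, xy, xz, yy, yz, zz)."""
        W1, W2, nz = gx.shape
        fx = 0.0; fy = 0.0; fz = 0.0
        for i in range(W1):
            gi = ix[i]
            for j in range(W2):
                gj = iy[j]
                for k in range(nz):
                    s = iso[gi, gj, k]
                    axx = act[0, gi, gj, k] + s
                    axy = act[1, gi, gj, k]
                    axz = act[2, gi, gj, k]
                    ayy = act[3, gi, gj, k] + s
                    ayz = act[4, gi, gj, k]
                    azz = act[5, gi, gj, k] + s
                    ggx = gx[i, j, k]; ggy = gy[i, j, k]; ggz = gz[i, j, k]
                    fx += axx * ggx + axy * ggy + axz * ggz
                    fy += axy * ggx + ayy * ggy + ayz * ggz
                    fz += axz * ggx + ayz * ggy + azz * ggz
        a03 = a0 * a0 * a0
        return -fx * a03, -fy * a03, -fz * a03

    @nb.njit(cache=True)
    def advect_update(
        phi, dF_local, lap_sum, lap_phi_w, ix, iy, wrap_x, wrap_y,
        wcc, wcs, vx, vy, vz, dt, Gamma, a0,
    ):
        """phi += dt * (-v.grad(phi)|upwind - Gamma dF); returns max |phi|.

        dF = dF_local - 2 wcc lap_sum - wcs lap_phi_w, gathered in place.
        """
        W1, W2, nz = phi.shape
        inva = 1.0 / a0
        out = np.empty_like(phi)
        m = 0.0
        for i in range(W1):
            gi = ix[i]
            for j in range(W2):
                gj = iy[j]
                for k in range(nz):
                    p = phi[i, j, k]
                    if i > 0:
                        xm = phi[i - 1, j, k]
                    else:
                        xm = phi[W1 - 1, j, k] if wrap_x else 0.0
                    if i < W1 - 1:
                        xp = phi[i + 1, j, k]
                    else:
                        xp = phi[0, j, k] if wrap_x else 0.0
                    if j > 0:
                        ym = phi[i, j - 1, k]
                    else:
                        ym = phi[i, W2 - 1, k] if wrap_y else 0.0
                    if j < W2 - 1:
                        yp = phi[i, j + 1, k]
                    else:
                        yp = phi[i, 0, k] if wrap_y else 0.0
                    if vx >= 0:
                        dx = p - xm
                    else:
                        dx = xp - p
                    if vy >= 0:
                        dy = p - ym
                    else:
                        dy = yp - p
                    if vz >= 0:
                        dz = (p - phi[i, j, k - 1]) if k > 0 else 0.0
                    else:
                        dz = (phi[i, j, k + 1] - p) if k < nz - 1 else 0.0
                    adv = (vx * dx + vy * dy + vz * dz) * inva
                    dF = (
                        dF_local[i, j, k]
                        - 2.0 * wcc * lap_sum[gi, gj, k]
                        - wcs * lap_phi_w[gi, gj, k]
                    )
                    q = p + dt * (-adv - Gamma * dF)
                    out[i, j, k] = q
                    aq = abs(q)
                    if aq > m:
                        m = aq
        phi[:] = out
        return m
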