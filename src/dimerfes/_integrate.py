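"""Euler–Maruyama core for overdamped Langevin dynamics on model potentials.

Compiled with numba.  The state lives in d-dimensional CV space; forces come
from the Gaussian-well potential, an optional per-dimension harmonic
(umbrella) bias, quartic confining walls (intrinsic and restraint), and an
evolving well-tempered metadynamics bias maintained on a cached grid over at
most two CV dimensions (value plus analytic gradient grids, so the bias
force is exact up to bilinear interpolation).

Update rule per CV i:  x += −(D_i/kT)·∂U/∂x_i·Δt + √(2 D_i Δt)·ξ,  ξ~N(0,1).
"""

import numpy as np
from numba import njit

_WALL_EXP = 4
_TRUNC = 6.0  # hill truncation, units of sigma


@njit(cache=True)
def _bilinear(grid, lo0, dx0, n0, lo1, dx1, n1, x0, x1):
    """Bilinear interpolation with edge clamping; handles n1 == 1 (1D)."""
    t0 = (x0 - lo0) / dx0
    if t0 < 0.0:
        t0 = 0.0
    if t0 > n0 - 1.000001:
        t0 = n0 - 1.000001
    i0 = int(t0)
    f0 = t0 - i0
    if n1 == 1:
        return grid[i0, 0] * (1.0 - f0) + grid[i0 + 1, 0] * f0
    t1 = (x1 - lo1) / dx1
    if t1 < 0.0:
        t1 = 0.0
    if t1 > n1 - 1.000001:
        t1 = n1 - 1.000001
    i1 = int(t1)
    f1 = t1 - i1
    return (
        grid[i0, i1] * (1.0 - f0) * (1.0 - f1)
        + grid[i0 + 1, i1] * f0 * (1.0 - f1)
        + grid[i0, i1 + 1] * (1.0 - f0) * f1
        + grid[i0 + 1, i1 + 1] * f0 * f1
    )


@njit(cache=True)
def _deposit(V, G0, G1, lo0, dx0, n0, lo1, dx1, n1,
             c0, c1, s0, s1, h):
    """Add one Gaussian hill (truncated at ±6σ) to value/gradient grids."""
    i_lo = max(0, int((c0 - _TRUNC * s0 - lo0) / dx0))
    i_hi = min(n0 - 1, int((c0 + _TRUNC * s0 - lo0) / dx0) + 1)
    if n1 == 1:
        for i in range(i_lo, i_hi + 1):
            d0 = lo0 + i * dx0 - c0
            g = h * np.exp(-0.5 * d0 * d0 / (s0 * s0))
            V[i, 0] += g
            G0[i, 0] += g * (-d0 / (s0 * s0))
        return
    j_lo = max(0, int((c1 - _TRUNC * s1 - lo1) / dx1))
    j_hi = min(n1 - 1, int((c1 + _TRUNC * s1 - lo1) / dx1) + 1)
    for i in range(i_lo, i_hi + 1):
        d0 = lo0 + i * dx0 - c0
        e0 = np.exp(-0.5 * d0 * d0 / (s0 * s0))
        for j in range(j_lo, j_hi + 1):
            d1 = lo1 + j * dx1 - c1
            g = h * e0 * np.exp(-0.5 * d1 * d1 / (s1 * s1))
            V[i, j] += g
            G0[i, j] += g * (-d0 / (s0 * s0))
            G1[i, j] += g * (-d1 / (s1 * s1))


@njit(cache=True)
def integrate(
    x0, D, dt, n_steps, out_stride, kT, seed, max_step,
    well_A, well_c, well_s,
    harm_k, harm_c,
    pwall_lo, pwall_hi, pwall_k,
    umb_k, umb_c,
    bwall_lo, bwall_hi, bwall_k,
    md_dim0, md_dim1,
    md_w0, md_sig0, md_sig1, md_gamma, md_stride,
    grid_lo0, grid_hi0, grid_n0, grid_lo1, grid_hi1, grid_n1,
):
    np.random.seed(seed)
    d = x0.shape[0]
    nw = well_A.shape[0]
    n_out = n_steps // out_stride + 1
    times = np.empty(n_out)
    X = np.empty((n_out, d))
    vbias = np.zeros(n_out)

    metad_on = md_dim0 >= 0 and md_w0 > 0.0
    if metad_on:
        n0, n1 = grid_n0, grid_n1
        dx0 = (grid_hi0 - grid_lo0) / (n0 - 1)
        dx1 = (grid_hi1 - grid_lo1) / (n1 - 1) if n1 > 1 else 1.0
        max_hills = n_steps // md_stride + 1
    else:
        n0, n1, dx0, dx1 = 2, 1, 1.0, 1.0
        max_hills = 1
    V = np.zeros((n0, n1))
    G0 = np.zeros((n0, n1))
    G1 = np.zeros((n0, n1))
    hills_t = np.empty(max_hills)
    hills_c0 = np.empty(max_hills)
    hills_c1 = np.empty(max_hills)
    hills_h = np.empty(max_hills)
    n_hills = 0

    x = x0.copy()
    grad = np.empty(d)
    sqrt2Ddt = np.sqrt(2.0 * D * dt)
    pref = D * dt / kT

    # record initial frame
    times[0] = 0.0
    for i in range(d):
        X[0, i] = x[i]
    if metad_on:
        xm1 = x[md_dim1] if md_dim1 >= 0 else 0.0
        vbias[0] = _bilinear(V, grid_lo0, dx0, n0, grid_lo1, dx1, n1,
                             x[md_dim0], xm1)
    out_i = 1
    diverged = 0

    for step in range(1, n_steps + 1):
        # ---- forces
        for i in range(d):
            grad[i] = 0.0
        for w in range(nw):
            e = 0.0
            for i in range(d):
                dd = (x[i] - well_c[w, i]) / well_s[w, i]
                e += dd * dd
            e = well_A[w] * np.exp(-0.5 * e)
            for i in range(d):
                grad[i] += e * (-(x[i] - well_c[w, i]) / (well_s[w, i] ** 2))
        for i in range(d):
            grad[i] += harm_k[i] * (x[i] - harm_c[i])
            grad[i] += umb_k[i] * (x[i] - umb_c[i])
            if np.isfinite(pwall_lo[i]) and x[i] < pwall_lo[i]:
                exc = pwall_lo[i] - x[i]
                grad[i] -= _WALL_EXP * pwall_k[i] * exc ** (_WALL_EXP - 1)
            if np.isfinite(pwall_hi[i]) and x[i] > pwall_hi[i]:
                exc = x[i] - pwall_hi[i]
                grad[i] += _WALL_EXP * pwall_k[i] * exc ** (_WALL_EXP - 1)
            if np.isfinite(bwall_lo[i]) and x[i] < bwall_lo[i]:
                exc = bwall_lo[i] - x[i]
                grad[i] -= _WALL_EXP * bwall_k[i] * exc ** (_WALL_EXP - 1)
            if np.isfinite(bwall_hi[i]) and x[i] > bwall_hi[i]:
                exc = x[i] - bwall_hi[i]
                grad[i] += _WALL_EXP * bwall_k[i] * exc ** (_WALL_EXP - 1)
        if metad_on:
            xm1 = x[md_dim1] if md_dim1 >= 0 else 0.0
            grad[md_dim0] += _bilinear(G0, grid_lo0, dx0, n0,
                                       grid_lo1, dx1, n1, x[md_dim0], xm1)
            if md_dim1 >= 0:
                grad[md_dim1] += _bilinear(G1, grid_lo0, dx0, n0,
                                           grid_lo1, dx1, n1, x[md_dim0], xm1)

        # ---- Euler–Maruyama update
        for i in range(d):
            dxi = -pref[i] * grad[i] + sqrt2Ddt[i] * np.random.standard_normal()
            if np.abs(dxi) > max_step:
                diverged = 1
            x[i] += dxi
        if diverged == 1:
            break

        # ---- hill deposition (well-tempered rule)
        if metad_on and step % md_stride == 0:
            xm1 = x[md_dim1] if md_dim1 >= 0 else 0.0
            v_here = _bilinear(V, grid_lo0, dx0, n0, grid_lo1, dx1, n1,
                               x[md_dim0], xm1)
            h = md_w0 * np.exp(-v_here / ((md_gamma - 1.0) * kT))
            _deposit(V, G0, G1, grid_lo0, dx0, n0, grid_lo1, dx1, n1,
                     x[md_dim0], xm1, md_sig0, md_sig1, h)
            hills_t[n_hills] = step * dt
            hills_c0[n_hills] = x[md_dim0]
            hills_c1[n_hills] = xm1
            hills_h[n_hills] = h
            n_hills += 1

        # ---- output
        if step % out_stride == 0:
            times[out_i] = step * dt
            for i in range(d):
                X[out_i, i] = x[i]
            if metad_on:
                xm1 = x[md_dim1] if md_dim1 >= 0 else 0.0
                vbias[out_i] = _bilinear(V, grid_lo0, dx0, n0,
                                         grid_lo1, dx1, n1, x[md_dim0], xm1)
            out_i += 1

    return (times[:out_i], X[:out_i], vbias[:out_i],
            hills_t[:n_hills], hills_c0[:n_hills], hills_c1[:n_hills],
            hills_h[:n_hills], diverged)
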