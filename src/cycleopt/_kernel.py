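"""Numba-compiled right-hand side and fixed-step DDE integrator.

The single delay in the system acts on inhibin, which is an algebraic
function of the ovarian stage masses, so the delayed quantity can be
reconstructed from the stored past solution rather than carried as an
extra state.  Integration uses the method of steps with classical RK4 on a
fixed grid; the delayed inhibin lookup interpolates the stored series with
cubic Hermite polynomials (values plus time-derivatives at the grid
nodes), keeping the overall scheme fourth-order for delays ``tau >= h``.

The parameter vector layout is fixed by :data:`cycleopt.params.PARAM_ORDER`;
the index constants below must match it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# parameter vector indices (see params.PARAM_ORDER)
_V0_LH, _V1_LH, _KM_LH, _KI_LH_P, _K_LH, _C_LH_P, _C_LH_E, _A_LH = range(8)
_V_FSH, _KI_FSH_INH, _TAU, _K_FSH, _C_FSH_P, _C_FSH_E, _A_FSH = range(8, 15)
_V = 15
_W, _Q = 16, 17
_B, _C1, _C2, _C3, _C4, _D1, _D2, _K1, _K2, _K3, _K4 = range(18, 29)
_ALPHA, _GAMMA = 29, 30
_E0, _E1, _E2C, _E3 = range(31, 35)
_P0, _P1, _P2 = range(35, 38)
_H0, _H1, _H2, _H3 = range(38, 42)
_B1, _B2 = 42, 43

N_PARAMS = 44
N_STATES = 13


@njit(cache=False)
def aux_hormones(y, e2exo, p4exo, th):
    """(E2, P4, Inh) from a state vector and the exogenous dose at t."""
    e2 = th[_E0] + th[_E1] * y[5] + th[_E2C] * y[6] + th[_E3] * y[12] \
        + th[_B1] * e2exo
    p4 = th[_P0] + th[_P1] * y[11] + th[_P2] * y[12] + th[_B2] * p4exo
    inh = th[_H0] + th[_H1] * y[6] + th[_H2] * y[10] + th[_H3] * y[11]
    return e2, p4, inh


@njit(cache=False)
def rhs(y, inh_delay, e2exo, p4exo, th, dy):
    """Derivatives of the 13 states; writes into ``dy``, returns dInh/dt.

    ``inh_delay`` is Inh evaluated at t - tau.  Concentrations entering
    nonlinear terms are floored at zero so that transient sub-zero
    numerical excursions cannot produce complex powers.
    """
    e2, p4, inh = aux_hormones(y, e2exo, p4exo, th)
    if e2 < 0.0:
        e2 = 0.0
    if p4 < 0.0:
        p4 = 0.0
    lh = y[1]
    if lh < 0.0:
        lh = 0.0
    fsh = y[3]
    if fsh < 0.0:
        fsh = 0.0

    # pituitary LH: order-8 Hill stimulation by E2, P4 inhibits synthesis,
    # P4 bolsters / E2 inhibits release
    e2_8 = e2 ** 8
    hill = th[_V1_LH] * e2_8 / (th[_KM_LH] ** 8 + e2_8)
    syn_lh = (th[_V0_LH] + hill) / (1.0 + p4 / th[_KI_LH_P])
    rel_lh = th[_K_LH] * (1.0 + th[_C_LH_P] * p4) * y[0] \
        / (1.0 + th[_C_LH_E] * e2)
    dy[0] = syn_lh - rel_lh
    dy[1] = rel_lh / th[_V] - th[_A_LH] * y[1]

    # pituitary FSH: delayed inhibin and P4/w inhibit synthesis; the E2
    # release factor is squared (stronger inhibition than for LH)
    syn_fsh = th[_V_FSH] / (1.0 + inh_delay / th[_KI_FSH_INH] + p4 / th[_W])
    den = 1.0 + th[_C_FSH_E] * e2
    rel_fsh = th[_K_FSH] * (1.0 + th[_C_FSH_P] * p4) * y[2] / (den * den)
    dy[2] = syn_fsh - rel_fsh
    dy[3] = rel_fsh / th[_V] - th[_A_FSH] * y[3]

    # ovarian stage chain
    lh_a = lh ** th[_ALPHA]
    lh_g = lh ** th[_GAMMA]
    recruit = (th[_B] + th[_C1] * y[4]) * fsh / (1.0 + p4 / th[_Q])
    out_rcf = th[_C2] * lh_a * y[4]
    out_grf = th[_C3] * lh * y[5]
    out_dom = th[_C4] * lh_g * y[6]
    dy[4] = recruit - out_rcf
    dy[5] = out_rcf - out_grf
    dy[6] = out_grf - out_dom
    dy[7] = out_dom - th[_D1] * y[7]
    dy[8] = th[_D1] * y[7] - th[_D2] * y[8]
    dy[9] = th[_D2] * y[8] - th[_K1] * y[9]
    dy[10] = th[_K1] * y[9] - th[_K2] * y[10]
    dy[11] = th[_K2] * y[10] - th[_K3] * y[11]
    dy[12] = th[_K3] * y[11] - th[_K4] * y[12]

    # dInh/dt, needed for Hermite interpolation of the delayed lookup
    return th[_H1] * dy[6] + th[_H2] * dy[10] + th[_H3] * dy[11]


@njit(cache=False)
def _hermite(x, j, vals, dvals, h):
    xi = x - j
    om = 1.0 - xi
    h00 = (1.0 + 2.0 * xi) * om * om
    h10 = xi * om * om
    h01 = xi * xi * (3.0 - 2.0 * xi)
    h11 = xi * xi * (xi - 1.0)
    return h00 * vals[j] + h01 * vals[j + 1] \
        + h * (h10 * dvals[j] + h11 * dvals[j + 1])


@njit(cache=False)
def _inh_lookup(s, h, inh, dinh, nmax, hist_inh, hist_dinh):
    """Cubic-Hermite interpolation of Inh(s).

    For s <= 0 the pre-history arrays (covering ``[-(len-1)*h, 0]``) are
    interpolated; times before their start clamp to the first value, so a
    single-element history behaves as a constant.
    """
    if s <= 0.0:
        m = len(hist_inh) - 1
        x = s / h + m
        if x <= 0.0:
            return hist_inh[0]
        j = int(x)
        if j >= m:
            j = m - 1
        return _hermite(x, j, hist_inh, hist_dinh, h)
    x = s / h
    j = int(x)
    if j >= nmax:
        j = nmax - 1
    if j < 0:
        j = 0
    return _hermite(x, j, inh, dinh, h)


@njit(cache=False)
def pituitary_loop(syn_lh, rel_lh, syn_fsh, rel_fsh, vinv, a_lh, a_fsh,
                   ic, step, n):
    """RK4 for the forced pituitary submodel.

    The forcing-dependent term coefficients are pre-evaluated on the
    half-step grid (index ``2*i + {0,1,2}`` for the RK4 stages of step i).
    Returns (n+1, 4) states.
    """
    out = np.empty((n + 1, 4))
    y0, y1, y2, y3 = ic[0], ic[1], ic[2], ic[3]
    out[0, 0], out[0, 1], out[0, 2], out[0, 3] = y0, y1, y2, y3
    h2 = 0.5 * step
    h6 = step / 6.0
    for i in range(n):
        j = 2 * i
        a0 = syn_lh[j] - rel_lh[j] * y0
        a1 = rel_lh[j] * y0 * vinv - a_lh * y1
        a2 = syn_fsh[j] - rel_fsh[j] * y2
        a3 = rel_fsh[j] * y2 * vinv - a_fsh * y3
        u0 = y0 + h2 * a0
        u1 = y1 + h2 * a1
        u2 = y2 + h2 * a2
        u3 = y3 + h2 * a3
        b0 = syn_lh[j + 1] - rel_lh[j + 1] * u0
        b1 = rel_lh[j + 1] * u0 * vinv - a_lh * u1
        b2 = syn_fsh[j + 1] - rel_fsh[j + 1] * u2
        b3 = rel_fsh[j + 1] * u2 * vinv - a_fsh * u3
        u0 = y0 + h2 * b0
        u1 = y1 + h2 * b1
        u2 = y2 + h2 * b2
        u3 = y3 + h2 * b3
        c0 = syn_lh[j + 1] - rel_lh[j + 1] * u0
        c1 = rel_lh[j + 1] * u0 * vinv - a_lh * u1
        c2 = syn_fsh[j + 1] - rel_fsh[j + 1] * u2
        c3 = rel_fsh[j + 1] * u2 * vinv - a_fsh * u3
        u0 = y0 + step * c0
        u1 = y1 + step * c1
        u2 = y2 + step * c2
        u3 = y3 + step * c3
        d0 = syn_lh[j + 2] - rel_lh[j + 2] * u0
        d1 = rel_lh[j + 2] * u0 * vinv - a_lh * u1
        d2 = syn_fsh[j + 2] - rel_fsh[j + 2] * u2
        d3 = rel_fsh[j + 2] * u2 * vinv - a_fsh * u3
        y0 += h6 * (a0 + 2.0 * b0 + 2.0 * c0 + d0)
        y1 += h6 * (a1 + 2.0 * b1 + 2.0 * c1 + d1)
        y2 += h6 * (a2 + 2.0 * b2 + 2.0 * c2 + d2)
        y3 += h6 * (a3 + 2.0 * b3 + 2.0 * c3 + d3)
        out[i + 1, 0] = y0
        out[i + 1, 1] = y1
        out[i + 1, 2] = y2
        out[i + 1, 3] = y3
    return out


@njit(cache=False)
def _ov_deriv(u, rec_g, out_rcf, out_grf, out_dom, b, c1,
              d1, d2, k1, k2, k3, k4, p0, p1, p2, q, dy):
    p4 = p0 + p1 * u[7] + p2 * u[8]
    if p4 < 0.0:
        p4 = 0.0
    rec = (b + c1 * u[0]) * rec_g / (1.0 + p4 / q)
    o0 = out_rcf * u[0]
    o1 = out_grf * u[1]
    o2 = out_dom * u[2]
    dy[0] = rec - o0
    dy[1] = o0 - o1
    dy[2] = o1 - o2
    dy[3] = o2 - d1 * u[3]
    dy[4] = d1 * u[3] - d2 * u[4]
    dy[5] = d2 * u[4] - k1 * u[5]
    dy[6] = k1 * u[5] - k2 * u[6]
    dy[7] = k2 * u[6] - k3 * u[7]
    dy[8] = k3 * u[7] - k4 * u[8]


@njit(cache=False)
def ovarian_loop(fsh_g, out_rcf_g, out_grf_g, out_dom_g, b, c1,
                 d1, d2, k1, k2, k3, k4, p0, p1, p2, q, ic, step, n):
    """RK4 for the forced ovarian submodel (9 stage masses).

    ``fsh_g`` and the three LH-power outflow coefficient arrays are
    pre-evaluated on the half-step grid.  ``q = inf`` disables the
    recruitment inhibition.  Returns (n+1, 9) masses.
    """
    out = np.empty((n + 1, 9))
    y = ic.copy()
    out[0] = y
    dy1 = np.empty(9)
    dy2 = np.empty(9)
    dy3 = np.empty(9)
    dy4 = np.empty(9)
    u = np.empty(9)
    h2 = 0.5 * step
    h6 = step / 6.0
    for i in range(n):
        j = 2 * i
        _ov_deriv(y, fsh_g[j], out_rcf_g[j], out_grf_g[j], out_dom_g[j],
                  b, c1, d1, d2, k1, k2, k3, k4, p0, p1, p2, q, dy1)
        for m in range(9):
            u[m] = y[m] + h2 * dy1[m]
        _ov_deriv(u, fsh_g[j + 1], out_rcf_g[j + 1], out_grf_g[j + 1],
                  out_dom_g[j + 1], b, c1, d1, d2, k1, k2, k3, k4,
                  p0, p1, p2, q, dy2)
        for m in range(9):
            u[m] = y[m] + h2 * dy2[m]
        _ov_deriv(u, fsh_g[j + 1], out_rcf_g[j + 1], out_grf_g[j + 1],
                  out_dom_g[j + 1], b, c1, d1, d2, k1, k2, k3, k4,
                  p0, p1, p2, q, dy3)
        for m in range(9):
            u[m] = y[m] + step * dy3[m]
        _ov_deriv(u, fsh_g[j + 2], out_rcf_g[j + 2], out_grf_g[j + 2],
                  out_dom_g[j + 2], b, c1, d1, d2, k1, k2, k3, k4,
                  p0, p1, p2, q, dy4)
        for m in range(9):
            y[m] = y[m] + h6 * (dy1[m] + 2.0 * dy2[m] + 2.0 * dy3[m] + dy4[m])
        out[i + 1] = y
    return out


@njit(cache=False)
def integrate(y0, n_steps, h, th, e2half, p4half, hist_inh, hist_dinh):
    """Fixed-step RK4 with Hermite delayed-inhibin lookup.

    ``e2half``/``p4half`` are dose samples on the half-step grid
    ``t0 + j*h/2`` for ``j = 0..2*n_steps``.  ``hist_inh``/``hist_dinh``
    give the pre-history inhibin series on the step grid ending at t0
    (single-element arrays give a constant history).  Returns the state
    matrix, the inhibin series, and its derivative on the output grid.
    """
    ys = np.empty((n_steps + 1, N_STATES))
    inh = np.empty(n_steps + 1)
    dinh = np.zeros(n_steps + 1)
    ys[0] = y0

    tau = th[_TAU]
    use_delay = tau >= h  # tau < h treated as undelayed

    k1 = np.empty(N_STATES)
    k2 = np.empty(N_STATES)
    k3 = np.empty(N_STATES)
    k4 = np.empty(N_STATES)
    ytmp = np.empty(N_STATES)

    for n in range(n_steps):
        t = n * h
        y = ys[n]
        _, _, inh_n = aux_hormones(y, e2half[2 * n], p4half[2 * n], th)
        inh[n] = inh_n

        if use_delay:
            idel = _inh_lookup(t - tau, h, inh, dinh, n, hist_inh, hist_dinh)
        else:
            idel = inh_n
        dinh[n] = rhs(y, idel, e2half[2 * n], p4half[2 * n], th, k1)

        for i in range(N_STATES):
            ytmp[i] = y[i] + 0.5 * h * k1[i]
        if use_delay:
            idel = _inh_lookup(t + 0.5 * h - tau, h, inh, dinh, n, hist_inh, hist_dinh)
        else:
            _, _, idel = aux_hormones(ytmp, e2half[2 * n + 1], p4half[2 * n + 1], th)
        rhs(ytmp, idel, e2half[2 * n + 1], p4half[2 * n + 1], th, k2)

        for i in range(N_STATES):
            ytmp[i] = y[i] + 0.5 * h * k2[i]
        if not use_delay:
            _, _, idel = aux_hormones(ytmp, e2half[2 * n + 1], p4half[2 * n + 1], th)
        rhs(ytmp, idel, e2half[2 * n + 1], p4half[2 * n + 1], th, k3)

        for i in range(N_STATES):
            ytmp[i] = y[i] + h * k3[i]
        if use_delay:
            idel = _inh_lookup(t + h - tau, h, inh, dinh, n, hist_inh, hist_dinh)
        else:
            _, _, idel = aux_hormones(ytmp, e2half[2 * n + 2], p4half[2 * n + 2], th)
        rhs(ytmp, idel, e2half[2 * n + 2], p4half[2 * n + 2], th, k4)

        for i in range(N_STATES):
            ys[n + 1, i] = y[i] + h / 6.0 * (k1[i] + 2.0 * k2[i]
                                             + 2.0 * k3[i] + k4[i])
        if not np.isfinite(ys[n + 1, 0]):
            # blow-up: truncate by repeating last finite row; caller checks
            for m in range(n + 1, n_steps + 1):
                for i in range(N_STATES):
                    ys[m, i] = np.nan
                inh[m] = np.nan
            return ys, inh, dinh

    _, _, inh[n_steps] = aux_hormones(
        ys[n_steps], e2half[2 * n_steps], p4half[2 * n_steps], th)
    rhs(ys[n_steps],
        _inh_lookup(n_steps * h - tau, h, inh, dinh, n_steps, hist_inh, hist_dinh)
        if use_delay else inh[n_steps],
        e2half[2 * n_steps], p4half[2 * n_steps], th, k1)
    dinh[n_steps] = th[_H1] * k1[6] + th[_H2] * k1[10] + th[_H3] * k1[11]
    return ys, inh, dinh
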