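"""Numba kernels for the Laplace inner problem.

The per-subject posterior-mode search dominates the cost of the marginal
likelihood; these kernels run it with scalar loops and analytic
concentration derivatives.  A pure-numpy complex-step implementation of the
same computation lives in :mod:`pkgan.nlme` and the two are cross-checked in
the test suite.
"""

from __future__ import annotations

import cmath
import math

import numpy as np
from numba import njit

__all__ = ["laplace_parts"]


@njit(cache=True)
def _conc_derivs(ka, v, cl, dose, t):
    """Concentration and its derivatives w.r.t. the log-scale random effects.

    Returns (C, dC/deta_ka, dC/deta_V, dC/deta_Cl) for the one-compartment
    oral model in the cancellation-free form C = F*t*E*phi(x) with
    F = dose*ka/V and the slower rate constant in the exponential E, so no
    branch overflows.
    """
    ke = cl / v
    x = (ka - ke) * t
    f = dose * ka / v
    if x >= 0.0:
        e = math.exp(-ke * t)
    else:
        e = math.exp(-ka * t)
        x = -x
    if abs(x) < 1e-4:
        phi = 1.0 - x / 2.0 + x * x / 6.0 - x * x * x / 24.0
        dphi = -0.5 + x / 3.0 - x * x / 8.0
    else:
        phi = -math.expm1(-x) / x
        dphi = (math.exp(-x) * (1.0 + x) - 1.0) / (x * x)
    c = f * t * e * phi
    if ka >= ke:
        dc_dka = c / ka + f * t * t * e * dphi
        dc_dke = -f * t * t * e * (phi + dphi)
    else:
        dc_dka = c / ka - f * t * t * e * (phi + dphi)
        dc_dke = f * t * t * e * dphi
    g_ka = ka * dc_dka
    g_v = -c - ke * dc_dke
    g_cl = ke * dc_dke
    return c, g_ka, g_v, g_cl


@njit(cache=True)
def _conc_derivs_c(ka, v, cl, dose, t):
    """Complex-dtype twin of :func:`_conc_derivs` (for complex-step)."""
    ke = cl / v
    x = (ka - ke) * t
    f = dose * ka / v
    if x.real >= 0.0:
        e = cmath.exp(-ke * t)
    else:
        e = cmath.exp(-ka * t)
        x = -x
    if abs(x) < 1e-4:
        phi = 1.0 - x / 2.0 + x * x / 6.0 - x * x * x / 24.0
        dphi = -0.5 + x / 3.0 - x * x / 8.0
    else:
        ex = cmath.exp(-x)
        phi = (1.0 - ex) / x
        dphi = (ex * (1.0 + x) - 1.0) / (x * x)
    c = f * t * e * phi
    if ka.real >= ke.real:
        dc_dka = c / ka + f * t * t * e * dphi
        dc_dke = -f * t * t * e * (phi + dphi)
    else:
        dc_dka = c / ka - f * t * t * e * (phi + dphi)
        dc_dke = f * t * t * e * dphi
    g_ka = ka * dc_dka
    g_v = -c - ke * dc_dke
    g_cl = ke * dc_dke
    return c, g_ka, g_v, g_cl


@njit(cache=True)
def _grad_subject_c(e0, e1, e2, t, y, nobs, i, wti, dosei, ka_pop, v_pop, cl_pop,
                    beta, wref, a, b, omega, active, q, out):
    """Analytic inner gradient at complex random effects (complex-step use)."""
    ka = ka_pop * cmath.exp(e0)
    v = v_pop * (wti / wref) ** beta * cmath.exp(e1)
    cl = cl_pop * cmath.exp(e2)
    g0 = 0.0 + 0.0j
    g1 = 0.0 + 0.0j
    g2 = 0.0 + 0.0j
    for j in range(nobs):
        c, g_ka, g_v, g_cl = _conc_derivs_c(ka, v, cl, dosei, t[i, j])
        sig = a + b * c
        r = y[i, j] - c
        dh_dc = b / sig - r / sig**2 - b * r * r / sig**3
        g0 += dh_dc * g_ka
        g1 += dh_dc * g_v
        g2 += dh_dc * g_cl
    e = (e0, e1, e2)
    gsub = (g0, g1, g2)
    for k in range(q):
        out[k] = gsub[active[k]] + e[active[k]] / omega[k] ** 2


@njit(cache=True)
def _exact_logdet(e, t, y, nobs, i, wti, dosei, ka_pop, v_pop, cl_pop, beta, wref,
                  a, b, omega, active, q, hess_gn):
    """log|H| at the mode with the exact Hessian.

    The exact Hessian splits into a data part (analytic second derivatives,
    :func:`hessian_analytic`) and the prior precision diag(1/omega^2).  The
    data part can be indefinite away from a true local minimum, so its
    eigenvalues are clamped at zero before adding the prior back; the clamp
    is continuous in the parameters (no branch jumps that would break outer
    line searches) and inactive wherever the data part is already positive
    semi-definite.
    """
    h_ex = hessian_analytic(e, t, y, nobs, i, wti, dosei, ka_pop, v_pop,
                            cl_pop, beta, wref, a, b, active, q)
    ok = True
    for k in range(q):
        for m in range(q):
            if not np.isfinite(h_ex[k, m]):
                ok = False
    if not ok:
        return _logdet_sym(hess_gn, q)
    # fast path: data part strictly positive definite (Sylvester's minors)
    # -> the eigenvalue clamp is inactive and log|H| follows directly
    pd = h_ex[0, 0] > 0.0
    if pd and q >= 2:
        pd = h_ex[0, 0] * h_ex[1, 1] - h_ex[0, 1] * h_ex[0, 1] > 0.0
    if pd and q == 3:
        pd = (
            h_ex[0, 0] * (h_ex[1, 1] * h_ex[2, 2] - h_ex[1, 2] * h_ex[1, 2])
            - h_ex[0, 1] * (h_ex[0, 1] * h_ex[2, 2] - h_ex[1, 2] * h_ex[0, 2])
            + h_ex[0, 2] * (h_ex[0, 1] * h_ex[1, 2] - h_ex[1, 1] * h_ex[0, 2])
        ) > 0.0
    if pd:
        for k in range(q):
            h_ex[k, k] += 1.0 / omega[k] ** 2
        return _logdet_sym(h_ex, q)
    w, v = np.linalg.eigh(h_ex)
    h_pd = np.zeros((q, q))
    for k in range(q):
        wk = w[k] if w[k] > 0.0 else 0.0
        for r in range(q):
            for c in range(q):
                h_pd[r, c] += wk * v[r, k] * v[c, k]
    for k in range(q):
        h_pd[k, k] += 1.0 / omega[k] ** 2
    return _logdet_sym(h_pd, q)


@njit(cache=True)
def _conc_second(ka, v, cl, dose, t):
    """Concentration with first AND second derivatives w.r.t. the log-scale
    random effects (eta_ka, eta_V, eta_Cl).

    Returns (c, g0, g1, g2, G00, G01, G02, G11, G12, G22) where g are the
    first derivatives and G the symmetric second-derivative entries.  Uses
    the same slow-rate-in-the-exponential branch as :func:`_conc_derivs`;
    phi'' is evaluated by series near 0.  Verified against the complex-step
    Hessian (:func:`hessian_complex_step`) in the test suite.
    """
    ke = cl / v
    x = (ka - ke) * t
    f = dose * ka / v
    first_branch = x >= 0.0
    if first_branch:
        e = math.exp(-ke * t)
    else:
        e = math.exp(-ka * t)
        x = -x
    if x < 1e-2:
        phi = 1.0 - x / 2.0 + x * x / 6.0 - x**3 / 24.0 + x**4 / 120.0
        dphi = -0.5 + x / 3.0 - x * x / 8.0 + x**3 / 30.0
        d2phi = 1.0 / 3.0 - x / 4.0 + x * x / 10.0 - x**3 / 36.0
    else:
        ex = math.exp(-x)
        phi = -math.expm1(-x) / x
        dphi = (ex * (1.0 + x) - 1.0) / (x * x)
        d2phi = (2.0 - ex * (x * x + 2.0 * x + 2.0)) / x**3
    c = f * t * e * phi
    ft2e = f * t * t * e
    ft3e = ft2e * t
    if first_branch:
        c_ka = c / ka + ft2e * dphi
        c_ke = -ft2e * (phi + dphi)
        c_kaka = 2.0 * (c_ka - c / ka) / ka + ft3e * d2phi
        c_keke = ft3e * (phi + 2.0 * dphi + d2phi)
    else:
        c_ka = c / ka - ft2e * (phi + dphi)
        c_ke = ft2e * dphi
        c_kaka = 2.0 * (c_ka - c / ka) / ka + ft3e * (phi + 2.0 * dphi + d2phi)
        c_keke = ft3e * d2phi
    c_kake = c_ke / ka - ft3e * (dphi + d2phi)
    g0 = ka * c_ka
    g2 = ke * c_ke
    g1 = -c - g2
    kake = ka * ke
    ke2 = ke * ke
    g00 = g0 + ka * ka * c_kaka
    g01 = -g0 - kake * c_kake
    g02 = kake * c_kake
    g11 = -g1 + 2.0 * g2 + ke2 * c_keke
    g12 = -2.0 * g2 - ke2 * c_keke
    g22 = g2 + ke2 * c_keke
    return c, g0, g1, g2, g00, g01, g02, g11, g12, g22


@njit(cache=True)
def hessian_complex_step(e, t, y, nobs, i, wti, dosei, ka_pop, v_pop, cl_pop,
                         beta, wref, a, b, omega, active, q):
    """Exact data-part Hessian via complex-step of the analytic gradient.

    Independent of :func:`_conc_second`; kept as the cross-check route and
    used by the tests to validate the analytic second derivatives.
    """
    h_ex = np.zeros((q, q))
    gradc = np.zeros(q, dtype=np.complex128)
    step = 1e-20
    for k in range(q):
        e0 = complex(e[0], 0.0)
        e1 = complex(e[1], 0.0)
        e2 = complex(e[2], 0.0)
        if active[k] == 0:
            e0 = complex(e[0], step)
        elif active[k] == 1:
            e1 = complex(e[1], step)
        else:
            e2 = complex(e[2], step)
        _grad_subject_c(e0, e1, e2, t, y, nobs, i, wti, dosei, ka_pop, v_pop,
                        cl_pop, beta, wref, a, b, omega, active, q, gradc)
        for m in range(q):
            h_ex[k, m] = gradc[m].imag / step
    for k in range(q):
        for m in range(k + 1, q):
            s = 0.5 * (h_ex[k, m] + h_ex[m, k])
            h_ex[k, m] = s
            h_ex[m, k] = s
    for k in range(q):
        h_ex[k, k] -= 1.0 / omega[k] ** 2
    return h_ex


@njit(cache=True)
def hessian_analytic(e, t, y, nobs, i, wti, dosei, ka_pop, v_pop, cl_pop,
                     beta, wref, a, b, active, q):
    """Exact data-part Hessian from the analytic second derivatives:
    H[k,m] = sum_j [ d2h/dC^2 * g_k g_m + dh/dC * G_km ]."""
    ka = ka_pop * math.exp(e[0])
    v = v_pop * (wti / wref) ** beta * math.exp(e[1])
    cl = cl_pop * math.exp(e[2])
    h_ex = np.zeros((q, q))
    g = np.zeros(3)
    gg = np.zeros((3, 3))
    for j in range(nobs):
        c, g0, g1, g2, g00, g01, g02, g11, g12, g22 = _conc_second(
            ka, v, cl, dosei, t[i, j]
        )
        sig = a + b * c
        r = y[i, j] - c
        dh_dc = b / sig - r / sig**2 - b * r * r / sig**3
        d2h = (1.0 - b * b) / sig**2 + 4.0 * b * r / sig**3 + 3.0 * b * b * r * r / sig**4
        g[0] = g0
        g[1] = g1
        g[2] = g2
        gg[0, 0] = g00
        gg[0, 1] = g01
        gg[0, 2] = g02
        gg[1, 1] = g11
        gg[1, 2] = g12
        gg[2, 2] = g22
        gg[1, 0] = g01
        gg[2, 0] = g02
        gg[2, 1] = g12
        for k in range(q):
            ak = active[k]
            for m in range(k, q):
                am = active[m]
                h_ex[k, m] += d2h * g[ak] * g[am] + dh_dc * gg[ak, am]
    for k in range(q):
        for m in range(k):
            h_ex[k, m] = h_ex[m, k]
    return h_ex


@njit(cache=True)
def _conc_only(ka, v, cl, dose, t):
    ke = cl / v
    x = (ka - ke) * t
    if x >= 0.0:
        e = math.exp(-ke * t)
    else:
        e = math.exp(-ka * t)
        x = -x
    if abs(x) < 1e-4:
        phi = 1.0 - x / 2.0 + x * x / 6.0 - x * x * x / 24.0
    else:
        phi = -math.expm1(-x) / x
    return dose * ka / v * t * e * phi


@njit(cache=True)
def _h_subject(e0, e1, e2, t, y, nobs, i, wti, dosei, ka_pop, v_pop, cl_pop, beta, wref, a, b,
               omega, active, q):
    """Penalized deviance of one subject at random effects (e0, e1, e2)."""
    if abs(e0) > 50.0 or abs(e1) > 50.0 or abs(e2) > 50.0:
        return np.inf
    ka = ka_pop * math.exp(e0)
    v = v_pop * (wti / wref) ** beta * math.exp(e1)
    cl = cl_pop * math.exp(e2)
    h = 0.0
    for j in range(nobs):
        c = _conc_only(ka, v, cl, dosei, t[i, j])
        if c < 0.0:
            c = 0.0
        sig = a + b * c
        r = y[i, j] - c
        h += math.log(sig) + 0.5 * (r / sig) ** 2
    e = (e0, e1, e2)
    for k in range(q):
        h += 0.5 * (e[active[k]] / omega[k]) ** 2
    return h


@njit(cache=True)
def _solve_sym(H, g, q, out):
    """Solve H out = g for symmetric positive-definite H of size q <= 3."""
    if q == 1:
        out[0] = g[0] / H[0, 0]
    elif q == 2:
        det = H[0, 0] * H[1, 1] - H[0, 1] * H[1, 0]
        out[0] = (g[0] * H[1, 1] - g[1] * H[0, 1]) / det
        out[1] = (g[1] * H[0, 0] - g[0] * H[1, 0]) / det
    else:
        a, b_, c = H[0, 0], H[0, 1], H[0, 2]
        d, e_, f = H[1, 1], H[1, 2], H[2, 2]
        det = a * (d * f - e_ * e_) - b_ * (b_ * f - e_ * c) + c * (b_ * e_ - d * c)
        i00 = d * f - e_ * e_
        i01 = c * e_ - b_ * f
        i02 = b_ * e_ - c * d
        i11 = a * f - c * c
        i12 = c * b_ - a * e_
        i22 = a * d - b_ * b_
        out[0] = (i00 * g[0] + i01 * g[1] + i02 * g[2]) / det
        out[1] = (i01 * g[0] + i11 * g[1] + i12 * g[2]) / det
        out[2] = (i02 * g[0] + i12 * g[1] + i22 * g[2]) / det


@njit(cache=True)
def _logdet_sym(H, q):
    if q == 1:
        return math.log(H[0, 0])
    if q == 2:
        return math.log(H[0, 0] * H[1, 1] - H[0, 1] * H[1, 0])
    a, b_, c = H[0, 0], H[0, 1], H[0, 2]
    d, e_, f = H[1, 1], H[1, 2], H[2, 2]
    det = a * (d * f - e_ * e_) - b_ * (b_ * f - e_ * c) + c * (b_ * e_ - d * c)
    return math.log(det)


@njit(cache=True)
def laplace_parts(t, y, nobs, wt, dose, ka_pop, v_pop, cl_pop, beta, omega, a, b,
                  wref, active, eta0, tol, maxiter):
    """Per-subject Laplace ingredients for all subjects.

    Returns (eta_modes (n, q), h_core (n,), logdet_H (n,)) where h_core is
    the penalized deviance at the mode (no 2*pi constants) and H the
    Gauss-Newton (expected-information) Hessian of the inner problem.
    ``active`` maps the q active random effects onto (ka, V, Cl); ``omega``
    holds the q active standard deviations; ``eta0`` is the warm start.
    """
    n = y.shape[0]
    q = active.shape[0]
    eta = eta0.copy()
    h_out = np.empty(n)
    ld_out = np.zeros(n)
    grad = np.zeros(q)
    hess = np.zeros((q, q))
    delta = np.zeros(q)
    gsub = np.zeros(3)
    for i in range(n):
        e = np.zeros(3)
        for k in range(q):
            e[active[k]] = eta[i, k]
        h = _h_subject(e[0], e[1], e[2], t, y, nobs[i], i, wt[i], dose[i],
                       ka_pop, v_pop, cl_pop, beta, wref, a, b, omega, active, q)
        h_zero = _h_subject(0.0, 0.0, 0.0, t, y, nobs[i], i, wt[i], dose[i],
                            ka_pop, v_pop, cl_pop, beta, wref, a, b, omega, active, q)
        if not h < h_zero:  # also catches nan/inf warm starts
            e[:] = 0.0
            h = h_zero
        wfac = 1.0 + 2.0 * b * b
        for _ in range(maxiter):
            ka = ka_pop * math.exp(e[0])
            v = v_pop * (wt[i] / wref) ** beta * math.exp(e[1])
            cl = cl_pop * math.exp(e[2])
            for k in range(q):
                grad[k] = e[active[k]] / omega[k] ** 2
                for m in range(q):
                    hess[k, m] = 0.0
                hess[k, k] = 1.0 / omega[k] ** 2
            for j in range(nobs[i]):
                c, g_ka, g_v, g_cl = _conc_derivs(ka, v, cl, dose[i], t[i, j])
                if c < 0.0:
                    c = 0.0
                sig = a + b * c
                r = y[i, j] - c
                dh_dc = b / sig - r / sig**2 - b * r * r / sig**3
                w = wfac / (sig * sig)
                gsub[0] = g_ka
                gsub[1] = g_v
                gsub[2] = g_cl
                for k in range(q):
                    gk = gsub[active[k]]
                    grad[k] += dh_dc * gk
                    for m in range(q):
                        hess[k, m] += w * gk * gsub[active[m]]
            gmax = 0.0
            for k in range(q):
                if abs(grad[k]) > gmax:
                    gmax = abs(grad[k])
            if gmax < tol:
                break
            _solve_sym(hess, grad, q, delta)
            dnorm = 0.0
            for k in range(q):
                dnorm += delta[k] * delta[k]
            dnorm = math.sqrt(dnorm)
            if dnorm > 4.0:
                for k in range(q):
                    delta[k] *= 4.0 / dnorm
            slope = 0.0
            for k in range(q):
                slope += grad[k] * delta[k]
            step = 1.0
            accepted = False
            for _ in range(12):
                e0t, e1t, e2t = e[0], e[1], e[2]
                for k in range(q):
                    if active[k] == 0:
                        e0t = e[0] - step * delta[k]
                    elif active[k] == 1:
                        e1t = e[1] - step * delta[k]
                    else:
                        e2t = e[2] - step * delta[k]
                h_try = _h_subject(e0t, e1t, e2t, t, y, nobs[i], i, wt[i], dose[i],
                                   ka_pop, v_pop, cl_pop, beta, wref, a, b, omega, active, q)
                if h_try <= h - 1e-4 * step * slope:
                    e[0], e[1], e[2] = e0t, e1t, e2t
                    h = h_try
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
        ld_out[i] = _exact_logdet(e, t, y, nobs[i], i, wt[i], dose[i], ka_pop,
                                  v_pop, cl_pop, beta, wref, a, b, omega, active,
                                  q, hess)
        h_out[i] = h
        for k in range(q):
            eta[i, k] = e[active[k]]
    return eta, h_out, ld_out
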