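"""Jitted explicit integrator for the fit objective.

A Cash-Karp RK45 with step-size control, compiled with numba.  The switch
network is only mildly stiff for realistic parameters (the fastest rate is
the pairing sink k_pair * mS), so an explicit adaptive method is far
cheaper per solve than the general-purpose stiff machinery; the public
simulation API still uses LSODA at tight tolerance.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["integrate_constant_input"]

_MAX_STEPS = 20_000_000


@njit(cache=True, inline="always")
def _deriv(y, tf_a, pv, dy):
    (alpha_R, beta_R, K_TF, n_act, alpha_S, K_R, n_rep, k_pair,
     d_mR, d_mS, d_R, d_G, l_R, l_G, mu) = (
        pv[0], pv[1], pv[2], pv[3], pv[4], pv[5], pv[6], pv[7],
        pv[8], pv[9], pv[10], pv[11], pv[12], pv[13], pv[14])
    mR = y[0] if y[0] > 0.0 else 0.0
    mS = y[1] if y[1] > 0.0 else 0.0
    R = y[2] if y[2] > 0.0 else 0.0
    G = y[3] if y[3] > 0.0 else 0.0
    act = 0.0
    if tf_a > 0.0:
        r = (tf_a / K_TF) ** n_act
        act = r / (1.0 + r)
    rep = 1.0 / (1.0 + (R / K_R) ** n_rep)
    pair = k_pair * mR * mS
    dy[0] = beta_R + alpha_R * act - (d_mR + mu) * mR - pair
    dy[1] = alpha_S * rep - (d_mS + mu) * mS - pair
    dy[2] = l_R * mR - (d_R + mu) * R
    dy[3] = l_G * mR - (d_G + mu) * G


@njit(cache=True)
def integrate_constant_input(pv, tf_a, y0, t_out, rtol, atol):
    """Integrate from t=0 under constant input, sampling at ``t_out``.

    Returns (states, ok) where states has shape (len(t_out), 4).
    """
    n_out = t_out.shape[0]
    out = np.zeros((n_out, 4))
    y = y0.copy()
    k1 = np.zeros(4); k2 = np.zeros(4); k3 = np.zeros(4)
    k4 = np.zeros(4); k5 = np.zeros(4); k6 = np.zeros(4)
    ytmp = np.zeros(4)
    y5 = np.zeros(4)
    t = 0.0
    i_out = 0
    while i_out < n_out and t_out[i_out] <= t:
        out[i_out] = y
        i_out += 1
    h = 1e-3
    t_end = t_out[n_out - 1]
    steps = 0
    while t < t_end:
        if steps > _MAX_STEPS:
            return out, False
        steps += 1
        if t + h > t_end:
            h = t_end - t
        # land exactly on the next requested output time
        if i_out < n_out and t + h > t_out[i_out]:
            h = t_out[i_out] - t
        # Cash-Karp coefficients
        _deriv(y, tf_a, pv, k1)
        for i in range(4):
            ytmp[i] = y[i] + h * 0.2 * k1[i]
        _deriv(ytmp, tf_a, pv, k2)
        for i in range(4):
            ytmp[i] = y[i] + h * (0.075 * k1[i] + 0.225 * k2[i])
        _deriv(ytmp, tf_a, pv, k3)
        for i in range(4):
            ytmp[i] = y[i] + h * (0.3 * k1[i] - 0.9 * k2[i] + 1.2 * k3[i])
        _deriv(ytmp, tf_a, pv, k4)
        for i in range(4):
            ytmp[i] = y[i] + h * (
                -11.0 / 54.0 * k1[i] + 2.5 * k2[i]
                - 70.0 / 27.0 * k3[i] + 35.0 / 27.0 * k4[i]
            )
        _deriv(ytmp, tf_a, pv, k5)
        for i in range(4):
            ytmp[i] = y[i] + h * (
                1631.0 / 55296.0 * k1[i] + 175.0 / 512.0 * k2[i]
                + 575.0 / 13824.0 * k3[i] + 44275.0 / 110592.0 * k4[i]
                + 253.0 / 4096.0 * k5[i]
            )
        _deriv(ytmp, tf_a, pv, k6)
        err = 0.0
        for i in range(4):
            y5[i] = y[i] + h * (
                37.0 / 378.0 * k1[i] + 250.0 / 621.0 * k3[i]
                + 125.0 / 594.0 * k4[i] + 512.0 / 1771.0 * k6[i]
            )
            y4 = y[i] + h * (
                2825.0 / 27648.0 * k1[i] + 18575.0 / 48384.0 * k3[i]
                + 13525.0 / 55296.0 * k4[i] + 277.0 / 14336.0 * k5[i]
                + 0.25 * k6[i]
            )
            sc = atol + rtol * (abs(y[i]) if abs(y[i]) > abs(y5[i]) else abs(y5[i]))
            e = abs(y5[i] - y4) / sc
            if e > err:
                err = e
        if err <= 1.0:
            t_new = t + h
            for i in range(4):
                y[i] = y5[i] if y5[i] > 0.0 else 0.0
            t = t_new
            while i_out < n_out and t_out[i_out] <= t:
                out[i_out] = y
                i_out += 1
        fac = 0.9 * err ** -0.2 if err > 1e-10 else 5.0
        if fac > 5.0:
            fac = 5.0
        if fac < 0.1:
            fac = 0.1
        h *= fac
        if h < 1e-12:
            return out, False
    while i_out < n_out:
        out[i_out] = y
        i_out += 1
    return out, True
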