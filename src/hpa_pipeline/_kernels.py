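"""Numba-compiled Dormand-Prince integration kernel for the 4-component network.

The right-hand side hard-codes the fixed HPA wiring (stress -> CRH -> ACTH ->
cortisol -> GR, GR repressing CRH/ACTH, CRH and GR self-activation); the
parameter vector layout is the canonical order defined in
:mod:`hpa_pipeline.model_core` (8 regulatory, 4 background, 4 timescale).

Exogenous stress and treatment overlays are piecewise-constant, so the public
integrator splits the time axis into segments of constant (stress, parameters)
and this kernel only ever integrates an autonomous smooth system between
forced stops at segment boundaries and output points.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the kernel
OK = 0
STEP_UNDERFLOW = 1
NONFINITE = 2

# exponent clamp keeping exp() finite in float64
_EXP_CLAMP = 700.0


@njit(cache=True)
def rhs(x, p, ss, sigma, out):
    """dX/dt = ts_i * (logistic(sigma * W_i) - X_i) for the fixed wiring."""
    w0 = p[8] + p[0] * ss + p[1] * x[0] + p[2] * x[3]   # CRH
    w1 = p[9] + p[3] * x[0] + p[4] * x[3]               # ACTH
    w2 = p[10] + p[5] * x[1]                            # COR
    w3 = p[11] + p[6] * x[2] + p[7] * x[3]              # GR
    w = (w0, w1, w2, w3)
    for i in range(4):
        z = sigma * w[i]
        if z > _EXP_CLAMP:
            z = _EXP_CLAMP
        elif z < -_EXP_CLAMP:
            z = -_EXP_CLAMP
        out[i] = p[12 + i] * (1.0 / (1.0 + np.exp(-z)) - x[i])


@njit(cache=True)
def _advance(x, p, ss, sigma, t0, t1, atol, rtol, h_init):
    """Adaptive Dormand-Prince(4)5 from t0 to t1 with constant ss and p.

    Mutates ``x`` in place; returns (status, last_step_size).
    """
    span = t1 - t0
    if span <= 0.0:
        return OK, h_init
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    k5 = np.empty(4)
    k6 = np.empty(4)
    k7 = np.empty(4)
    xt = np.empty(4)
    h = h_init
    if h <= 0.0 or h > span:
        h = span
    t = t0
    rhs(x, p, ss, sigma, k1)
    while t < t1:
        if t + h > t1:
            h = t1 - t
        for i in range(4):
            xt[i] = x[i] + h * (0.2 * k1[i])
        rhs(xt, p, ss, sigma, k2)
        for i in range(4):
            xt[i] = x[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
        rhs(xt, p, ss, sigma, k3)
        for i in range(4):
            xt[i] = x[i] + h * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i]
                                + 32.0 / 9.0 * k3[i])
        rhs(xt, p, ss, sigma, k4)
        for i in range(4):
            xt[i] = x[i] + h * (19372.0 / 6561.0 * k1[i]
                                - 25360.0 / 2187.0 * k2[i]
                                + 64448.0 / 6561.0 * k3[i]
                                - 212.0 / 729.0 * k4[i])
        rhs(xt, p, ss, sigma, k5)
        for i in range(4):
            xt[i] = x[i] + h * (9017.0 / 3168.0 * k1[i]
                                - 355.0 / 33.0 * k2[i]
                                + 46732.0 / 5247.0 * k3[i]
                                + 49.0 / 176.0 * k4[i]
                                - 5103.0 / 18656.0 * k5[i])
        rhs(xt, p, ss, sigma, k6)
        for i in range(4):
            xt[i] = x[i] + h * (35.0 / 384.0 * k1[i]
                                + 500.0 / 1113.0 * k3[i]
                                + 125.0 / 192.0 * k4[i]
                                - 2187.0 / 6784.0 * k5[i]
                                + 11.0 / 84.0 * k6[i])
        rhs(xt, p, ss, sigma, k7)
        err = 0.0
        for i in range(4):
            e = h * (71.0 / 57600.0 * k1[i]
                     - 71.0 / 16695.0 * k3[i]
                     + 71.0 / 1920.0 * k4[i]
                     - 17253.0 / 339200.0 * k5[i]
                     + 22.0 / 525.0 * k6[i]
                     - 1.0 / 40.0 * k7[i])
            if not np.isfinite(xt[i]):
                return NONFINITE, h
            sc = atol + rtol * max(abs(x[i]), abs(xt[i]))
            r = e / sc
            err += r * r
        err = np.sqrt(err / 4.0)
        if err <= 1.0:
            t += h
            for i in range(4):
                x[i] = xt[i]
                k1[i] = k7[i]
        if err > 0.0:
            fac = 0.9 * err ** (-0.2)
        else:
            fac = 5.0
        if fac > 5.0:
            fac = 5.0
        elif fac < 0.2:
            fac = 0.2
        h *= fac
        if h < 1e-13 * span:
            return STEP_UNDERFLOW, h
    return OK, h


@njit(cache=True)
def integrate_piecewise(x0, seg_bounds, seg_params, seg_stress, sigma,
                        t_out, atol, rtol):
    """Integrate over consecutive segments of constant stress and parameters.

    Parameters
    ----------
    x0 : (4,) initial state at seg_bounds[0]
    seg_bounds : (n_seg + 1,) strictly increasing segment boundary times
    seg_params : (n_seg, 16) effective parameter vector per segment
    seg_stress : (n_seg,) constant stress value per segment
    t_out : (n_out,) sorted output times within [seg_bounds[0], seg_bounds[-1]]

    Returns (status, out) with out of shape (n_out, 4); output at
    t == seg_bounds[0] is the initial state.
    """
    n_out = t_out.shape[0]
    out = np.empty((n_out, 4))
    x = x0.copy()
    j = 0
    while j < n_out and t_out[j] <= seg_bounds[0]:
        for i in range(4):
            out[j, i] = x[i]
        j += 1
    h = -1.0
    for s in range(seg_bounds.shape[0] - 1):
        ta = seg_bounds[s]
        tb = seg_bounds[s + 1]
        p = seg_params[s]
        ss = seg_stress[s]
        t = ta
        # restart step-size heuristic at discontinuities
        h = (tb - ta) / 50.0
        while j < n_out and t_out[j] <= tb:
            status, h = _advance(x, p, ss, sigma, t, t_out[j], atol, rtol, h)
            if status != OK:
                return status, out
            t = t_out[j]
            for i in range(4):
                out[j, i] = x[i]
            j += 1
        status, h = _advance(x, p, ss, sigma, t, tb, atol, rtol, h)
        if status != OK:
            return status, out
    return OK, out
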