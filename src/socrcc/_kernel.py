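"""Compiled fixed-step integration kernel for the coupled network.

One numba-jitted routine advances all units through one perturbation epoch
with an explicit Runge-Kutta tableau.  The derivative is evaluated at every
stage from the stage state, so the coupling sum and the instantaneous global
observable M are stage-level quantities (required by the global-feedback
contract).  The pure-numpy reference path lives in :mod:`socrcc.network`;
tests assert bit-level agreement between the two on short runs.
"""

from __future__ import annotations

import numba as nb
import numpy as np

# parameter-vector layout (see BerryParams.as_vector / RCCParams.as_vector)
# par: gamma beta K_R K_S K_G K_deg k_g k_deg k_a hill_n hill_l
# rcc: mu_f xi_p xi_g f_p f_g enabled


@nb.njit(cache=True)
def _eval_rhs(Ys, Ycommit, K, w, eps, v_signed, mode, rows, cols, par, rcc, clamp):
    n = Ys.shape[0]
    gamma, beta, K_R, K_S, K_G, K_deg = par[0], par[1], par[2], par[3], par[4], par[5]
    k_g, k_deg, k_a = par[6], par[7], par[8]
    hn = int(par[9])
    hl = int(par[10])
    mu_f, xi_p, xi_g, f_p, f_g = rcc[0], rcc[1], rcc[2], rcc[3], rcc[4]
    enabled = rcc[5] > 0.5

    KRn = 1.0
    for _ in range(hn):
        KRn *= K_R
    KSl = 1.0
    for _ in range(hl):
        KSl *= K_S

    S = 0.0
    Msum = 0.0
    for i in range(n):
        S += w[i] * Ys[i, 0]
        Msum += Ys[i, 0]

    for i in range(n):
        m = Ys[i, 0]
        f = Ys[i, 1]
        p = Ys[i, 2]
        g = Ys[i, 3]

        if mode == 0:
            r = S - w[i] * m
        else:
            # grid-local stencil; mode 1 averages current and previous-step
            # neighbour values (Crank-Nicholson), mode 2 uses current only
            r = 0.0
            rr = i // cols
            cc = i - rr * cols
            for d in range(4):
                if d == 0:
                    k2 = i - cols if rr > 0 else -1
                elif d == 1:
                    k2 = i + cols if rr < rows - 1 else -1
                elif d == 2:
                    k2 = i - 1 if cc > 0 else -1
                else:
                    k2 = i + 1 if cc < cols - 1 else -1
                if k2 >= 0:
                    if mode == 1:
                        r += w[k2] * 0.5 * (Ys[k2, 0] + Ycommit[k2, 0])
                    else:
                        r += w[k2] * Ys[k2, 0]
        r += eps[i] + v_signed * Msum
        if clamp and r < 0.0:
            r = 0.0  # supply from neighbouring cells cannot be negative

        if enabled:
            q = f / (f + mu_f)
            sigma_p = f_p * np.exp(xi_p * q)
            sigma_g = f_g * np.exp(xi_g * q)
        else:
            sigma_p = f_p
            sigma_g = f_g

        exchange = k_g * f * g / (K_G + f)
        hydrolysis = m * p / (1.0 + m)
        fn = 1.0
        for _ in range(hn):
            fn *= f
        fl = 1.0
        for _ in range(hl):
            fl *= f

        K[i, 0] = exchange - hydrolysis + r
        K[i, 1] = -exchange + hydrolysis - f * p / (1.0 + f)
        K[i, 2] = sigma_p * gamma * fn / (KRn + fn) - k_a * p * p
        K[i, 3] = sigma_g * beta * fl / (KSl + fl) - k_deg * g * p / (K_deg + g)


@nb.njit(cache=True)
def run_epoch(Y, w, eps, v_signed, mode, rows, cols, par, rcc,
              A, B, dt, n_steps, stride, ceiling,
              M_out, F_out, states_out, record_states, clamp):
    """Advance the committed state ``Y`` (modified in place) by ``n_steps``.

    Records M, F (and optionally full states) every ``stride`` committed
    steps.  Returns (status, n_recorded, negative_seen): status is 0 on
    success or the 1-based step index at which a non-finite value or the
    amplitude ceiling was hit.
    """
    n = Y.shape[0]
    ns = B.shape[0]
    K = np.empty((ns, n, 4))
    Ystage = np.empty((n, 4))
    rec = 0
    neg = False
    for it in range(n_steps):
        for s in range(ns):
            for i in range(n):
                for j in range(4):
                    acc = Y[i, j]
                    for q in range(s):
                        aq = A[s, q]
                        if aq != 0.0:
                            acc += dt * aq * K[q, i, j]
                    Ystage[i, j] = acc
            _eval_rhs(Ystage, Y, K[s], w, eps, v_signed, mode, rows, cols, par, rcc, clamp)
        ok = True
        for i in range(n):
            for j in range(4):
                acc = 0.0
                for s in range(ns):
                    acc += B[s] * K[s, i, j]
                val = Y[i, j] + dt * acc
                Y[i, j] = val
                if not np.isfinite(val) or np.abs(val) > ceiling:
                    ok = False
                if val < 0.0:
                    neg = True
        if not ok:
            return it + 1, rec, neg
        if (it + 1) % stride == 0:
            Msum = 0.0
            Fsum = 0.0
            for i in range(n):
                Msum += Y[i, 0]
                Fsum += Y[i, 1]
            M_out[rec] = Msum
            F_out[rec] = Fsum
            if record_states:
                for i in range(n):
                    for j in range(4):
                        states_out[rec, i, j] = Y[i, j]
            rec += 1
    return 0, rec, neg
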