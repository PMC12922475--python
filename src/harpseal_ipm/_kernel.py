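"""Compiled inner loop of the annual projection (numba).

The math here mirrors the module-level operations in ``hazards`` and
``projection`` exactly; the test suite asserts equality of every rate
against those operations. Only the per-year recursion lives here — it is
the MCMC hot path and dominates likelihood evaluation cost otherwise.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def project_kernel(exp_gamma_a, gamma_0, f_static, n_immature,
                   nlci, eps_s, eps_f, hic, hh0_sum, hha_sum,
                   zeta, delta, phi_s_sc, phi_f_sc, n0,
                   sad_tol, sad_max_iter):
    A = exp_gamma_a.shape[0]
    T = nlci.shape[0]
    n = np.zeros((A, T))
    h0 = np.empty(T)
    ha = np.empty((A, T))
    s0 = np.empty(T)
    sa = np.empty((A, T))
    f = np.empty((A, T))

    ha_t = np.empty(A)
    sa_t = np.empty(A)
    f_t = np.empty(A)

    def _rates(t, n_now, n_prev, nlci_prev):
        gd0 = phi_s_sc * n_now * np.exp(delta * nlci[t] + eps_s[t])
        gda = np.log1p(np.expm1(gd0) * zeta)
        h0_t = np.exp(gamma_0 + gd0)
        mult = np.exp(gda)
        fec_mod = phi_f_sc * n_prev * np.exp(delta * nlci_prev + eps_f[t])
        for i in range(A):
            ha_t[i] = exp_gamma_a[i] * mult
            sa_t[i] = np.exp(-(ha_t[i] + hha_sum[t]))
            if i < n_immature:
                f_t[i] = 0.0
            else:
                f_t[i] = np.exp(-np.exp(f_static[i] + fec_mod))
        s0_t = np.exp(-(h0_t + hic[t] + hh0_sum[t]))
        return h0_t, s0_t

    # year-0 schedule at N = N0 fixes the stationary age distribution
    h0_0, s0_0 = _rates(0, n0, n0, nlci[0])
    sad = np.full(A, 1.0 / A)
    w_new = np.empty(A)
    converged = False
    for _ in range(sad_max_iter):
        w_new[0] = 0.0
        for i in range(A):
            w_new[0] += 0.5 * s0_0 * f_t[i] * sad[i]
        for i in range(1, A):
            w_new[i] = sa_t[i - 1] * sad[i - 1]
        w_new[A - 1] += sa_t[A - 1] * sad[A - 1]
        total = 0.0
        for i in range(A):
            total += w_new[i]
        if total <= 0:
            break
        diff = 0.0
        for i in range(A):
            w_new[i] /= total
            diff += abs(w_new[i] - sad[i])
            sad[i] = w_new[i]
        if diff < sad_tol:
            converged = True
            break
    for i in range(A):
        n[i, 0] = n0 * sad[i]

    for t in range(T):
        n_now = 0.0
        for i in range(A):
            n_now += n[i, t]
        if t > 0:
            n_prev = 0.0
            for i in range(A):
                n_prev += n[i, t - 1]
            nlci_prev = nlci[t - 1]
        else:
            n_prev = n0
            nlci_prev = nlci[0]
        h0[t], s0[t] = _rates(t, n_now, n_prev, nlci_prev)
        for i in range(A):
            ha[i, t] = ha_t[i]
            sa[i, t] = sa_t[i]
            f[i, t] = f_t[i]
        if t + 1 < T:
            rec = 0.0
            for i in range(A):
                rec += f[i, t] * n[i, t]
            n[0, t + 1] = 0.5 * s0[t] * rec
            for i in range(1, A):
                n[i, t + 1] = sa[i - 1, t] * n[i - 1, t]
            n[A - 1, t + 1] += sa[A - 1, t] * n[A - 1, t]

    return n, h0, ha, s0, sa, f, sad, converged
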