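"""Compiled Gibbs-chain core for the kernel mixed model.

The model, after rotating each random effect into the eigenbasis of its
covariance, is

    y = X beta + V1 diag(sqrt(lam1)) delta1 + V2 diag(sqrt(lam2)) delta2 + e

with delta1 ~ N(0, vg I), delta2 ~ N(0, vge I), e ~ N(0, ve I), flat priors
on beta and scaled-inverse-chi-square priors on the three variances. All
full conditionals are conjugate; coordinates of delta are conditionally
independent given the other block, so one sweep costs O(m1 + m2) plus the
cross-rotation products.

``M = V1.T @ V2`` couples the two blocks. When the design is a complete
balanced line-by-environment layout the two eigenbases coincide up to a
Kronecker factor and M is the trivial selector [I 0]; ``selector=True``
replaces every product with a slice, making a sweep O(n).

All randomness is pre-drawn by the caller (standard normals and chi-square
deviates), so the chain itself is deterministic arithmetic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["gibbs_chain"]

_VAR_FLOOR = 1e-12


@njit(cache=True)
def gibbs_chain(
    B1, B2, A1, A2, lam1, lam2, M, MT, selector,
    XtX, XtXinv, Lbeta, Xty, yty,
    df0, S0g, S0ge, S0e, n_obs,
    n_iter, burn_in, thin,
    z1, z2, zb, chi_g, chi_ge, chi_e,
    beta_init, vg0, vge0, ve0,
):  # pragma: no cover - exercised via fit_gibbs
    m1 = lam1.shape[0]
    m2 = lam2.shape[0]
    q = Xty.shape[0]
    s1 = np.sqrt(lam1)
    s2 = np.sqrt(lam2)
    beta = beta_init.copy()
    delta1 = np.zeros(m1)
    delta2 = np.zeros(m2)
    w1 = np.zeros(m1)
    w2 = np.zeros(m2)
    vg = vg0
    vge = vge0
    ve = ve0
    n_keep = (n_iter - burn_in) // thin
    var_draws = np.zeros((n_keep, 3))
    beta_acc = np.zeros(q)
    d1_acc = np.zeros(m1)
    d2_acc = np.zeros(m2)
    kept = 0
    A1b = A1 @ beta
    A2b = A2 @ beta
    for it in range(n_iter):
        # delta1 | rest: rotated residual is B1 - A1 beta - M w2
        if selector:
            for k in range(m1):
                a = B1[k] - A1b[k] - w2[k]
                denom = lam1[k] + ve / vg
                mu_k = s1[k] * a / denom
                sd_k = np.sqrt(ve / denom)
                delta1[k] = mu_k + sd_k * z1[it, k]
                w1[k] = s1[k] * delta1[k]
        else:
            Mw2 = M @ w2
            for k in range(m1):
                a = B1[k] - A1b[k] - Mw2[k]
                denom = lam1[k] + ve / vg
                mu_k = s1[k] * a / denom
                sd_k = np.sqrt(ve / denom)
                delta1[k] = mu_k + sd_k * z1[it, k]
                w1[k] = s1[k] * delta1[k]
        # delta2 | rest
        if selector:
            for k in range(m2):
                cross = w1[k] if k < m1 else 0.0
                a = B2[k] - A2b[k] - cross
                denom = lam2[k] + ve / vge
                mu_k = s2[k] * a / denom
                sd_k = np.sqrt(ve / denom)
                delta2[k] = mu_k + sd_k * z2[it, k]
                w2[k] = s2[k] * delta2[k]
        else:
            Mtw1 = MT @ w1
            for k in range(m2):
                a = B2[k] - A2b[k] - Mtw1[k]
                denom = lam2[k] + ve / vge
                mu_k = s2[k] * a / denom
                sd_k = np.sqrt(ve / denom)
                delta2[k] = mu_k + sd_k * z2[it, k]
                w2[k] = s2[k] * delta2[k]
        # beta | rest (flat prior)
        rhs = Xty - A1.T @ w1 - A2.T @ w2
        beta_mean = XtXinv @ rhs
        beta = beta_mean + np.sqrt(ve) * (Lbeta @ zb[it])
        A1b = A1 @ beta
        A2b = A2 @ beta
        # variance components | rest (scaled-inverse-chi-square)
        ssd1 = 0.0
        for k in range(m1):
            ssd1 += delta1[k] * delta1[k]
        vg = (ssd1 + df0 * S0g) / chi_g[it]
        if vg < _VAR_FLOOR:
            vg = _VAR_FLOOR
        ssd2 = 0.0
        for k in range(m2):
            ssd2 += delta2[k] * delta2[k]
        vge = (ssd2 + df0 * S0ge) / chi_ge[it]
        if vge < _VAR_FLOOR:
            vge = _VAR_FLOOR
        # ||y - X beta - u1 - u2||^2 via rotated quantities
        quad = beta @ (XtX @ beta)
        bxty = beta @ Xty
        t1 = w1 @ (B1 - A1b)
        t2 = w2 @ (B2 - A2b)
        if selector:
            crossw = w1 @ w2[:m1]
        else:
            crossw = w1 @ (M @ w2)
        sse = (yty - 2.0 * bxty + quad - 2.0 * t1 - 2.0 * t2
               + w1 @ w1 + w2 @ w2 + 2.0 * crossw)
        if sse < 0.0:
            sse = 0.0
        ve = (sse + df0 * S0e) / chi_e[it]
        if ve < _VAR_FLOOR:
            ve = _VAR_FLOOR
        if it >= burn_in and (it - burn_in) % thin == thin - 1:
            if kept < n_keep:
                var_draws[kept, 0] = vg
                var_draws[kept, 1] = vge
                var_draws[kept, 2] = ve
                beta_acc += beta
                d1_acc += delta1
                d2_acc += delta2
                kept += 1
    return var_draws, beta_acc / kept, d1_acc / kept, d2_acc / kept
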