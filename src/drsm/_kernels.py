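"""Fused likelihood/gradient kernel.

The Bernoulli-logit likelihood over all person-item cells dominates the
sampling cost, so it is evaluated in a single compiled pass when numba is
available; ``BuiltModel`` keeps an equivalent vectorized numpy path that
doubles as a correctness oracle in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def loglik_grad_kernel(
    thw,  # (N, I) trait value per cell, wording sign already folded in
    eta,  # (N,)
    kappa,  # (N,)
    a_at, a_et, a_ers, a_mrs,  # (I,) loadings per slot
    b1, b2, b0,  # (I,) difficulties per node
    Y1, Y2, Y0,  # (N, I) pseudo-item outcomes (0 where unobserved)
    O1, O2, O0,  # (N, I) observation indicators
    sgn,  # (N, I) +-1 extreme-branch sign
    dim_idx,  # (I,) trait dimension per item
    w,  # (I,) wording sign
    D: int,
    use_eta: bool,
    use_kappa: bool,
    use_mod: bool,
):
    N, I = thw.shape
    ll = 0.0
    d_theta = np.zeros((N, D))
    d_eta = np.zeros(N)
    d_kappa = np.zeros(N)
    d_b1 = np.zeros(I)
    d_b2 = np.zeros(I)
    d_b0 = np.zeros(I)
    d_a_at = np.zeros(I)
    d_a_et = np.zeros(I)
    d_a_ers = np.zeros(I)
    d_a_mrs = np.zeros(I)
    for p in range(N):
        for i in range(I):
            th = thw[p, i]
            dth = 0.0
            if O1[p, i] > 0.0:
                lp = a_at[i] * th - b1[i]
                e = math.exp(-abs(lp))
                l1e = math.log1p(e)
                if lp >= 0.0:
                    sig = 1.0 / (1.0 + e)
                    sp = lp + l1e
                else:
                    sig = e / (1.0 + e)
                    sp = l1e
                r = Y1[p, i] - sig
                ll += Y1[p, i] * lp - sp
                d_b1[i] -= r
                d_a_at[i] += r * th
                dth += r * a_at[i]
            if O2[p, i] > 0.0:
                s = sgn[p, i]
                lp = s * a_et[i] * th - b2[i]
                if use_eta:
                    lp += a_ers[i] * eta[p]
                e = math.exp(-abs(lp))
                l1e = math.log1p(e)
                if lp >= 0.0:
                    sig = 1.0 / (1.0 + e)
                    sp = lp + l1e
                else:
                    sig = e / (1.0 + e)
                    sp = l1e
                r = Y2[p, i] - sig
                ll += Y2[p, i] * lp - sp
                d_b2[i] -= r
                d_a_et[i] += r * s * th
                dth += r * s * a_et[i]
                if use_eta:
                    d_a_ers[i] += r * eta[p]
                    d_eta[p] += r * a_ers[i]
            if use_mod and O0[p, i] > 0.0:
                lp = -b0[i]
                if use_kappa:
                    lp += a_mrs[i] * kappa[p]
                e = math.exp(-abs(lp))
                l1e = math.log1p(e)
                if lp >= 0.0:
                    sig = 1.0 / (1.0 + e)
                    sp = lp + l1e
                else:
                    sig = e / (1.0 + e)
                    sp = l1e
                r = Y0[p, i] - sig
                ll += Y0[p, i] * lp - sp
                d_b0[i] -= r
                if use_kappa:
                    d_a_mrs[i] += r * kappa[p]
                    d_kappa[p] += r * a_mrs[i]
            if dth != 0.0:
                d_theta[p, dim_idx[i]] += dth * w[i]
    return ll, d_theta, d_eta, d_kappa, d_b1, d_b2, d_b0, d_a_at, d_a_et, d_a_ers, d_a_mrs
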