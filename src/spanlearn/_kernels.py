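"""Numba-compiled likelihood kernels.

The psychometric probability is constant across the items of one trial
(same set size, same trial-resolved parameters), so the Bernoulli
log-likelihood aggregates to ``k log p + (n - k) log(1 - p)`` per trial.
``fused_logp_grad`` resolves the per-trial linear predictors, evaluates the
likelihood, and scatters the gradient back to fixed effects, condition
offsets, participant intercepts and block terms in one pass; the
hierarchical model falls back to an equivalent vectorized numpy
implementation when numba is unavailable.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .core_model import DECAY_BASE, GUESS_RATE, PROB_CLAMP

_LN2 = math.log(2.0)
_LNB = math.log(DECAY_BASE)
_U_MAX = 1e10
_V_CLIP = 60.0  # resolved log parameters are clipped so exp() stays finite


@njit(cache=True, error_model="numpy")
def fused_logp_grad(b4, d_all, sd3, z3, blk3, wvec3, ci, pi, bi,
                    t, log_s, k, n, nC, nP, want_grad):
    """Resolve linear predictors, evaluate the likelihood, scatter gradients.

    Parameters are packed as dense arrays with zeros for absent effects:
    ``b4`` the four reference fixed effects (start, rate, asym, shape);
    ``d_all`` (4, nC) condition offsets; ``sd3``/``z3`` random-effect SDs and
    standardized intercepts for (start, rate, asym); ``blk3``/``wvec3``
    (3, nC) block total-deltas and (3, 4) block weights.  ``ci``/``pi``/``bi``
    are per-trial condition, participant, and block (0-based) indices.

    Returns ``(total, p, gb4, gd, gz_raw, gsd_raw, gblk, gw2, gw3)`` where
    the ``g*`` arrays are likelihood-gradient accumulators on the resolved
    log-parameter scale (chain factors for sd / weight transforms are
    applied by the caller).
    """
    m = t.size
    pv = np.empty(m)
    gb4 = np.zeros(4)
    gd = np.zeros((4, nC))
    gz_raw = np.zeros((3, nP))
    gsd_raw = np.zeros(3)
    gblk = np.zeros((3, nC))
    gw2 = np.zeros(3)
    gw3 = np.zeros(3)
    total = 0.0
    for i in range(m):
        c = ci[i]
        p_ = pi[i]
        b_ = bi[i]
        ls = b4[0] + d_all[0, c] + sd3[0] * z3[0, p_] + blk3[0, c] * wvec3[0, b_]
        lr = b4[1] + d_all[1, c] + sd3[1] * z3[1, p_] + blk3[1, c] * wvec3[1, b_]
        la = b4[2] + d_all[2, c] + sd3[2] * z3[2, p_] + blk3[2, c] * wvec3[2, b_]
        lb = b4[3] + d_all[3, c]
        if ls > _V_CLIP:
            ls = _V_CLIP
        elif ls < -_V_CLIP:
            ls = -_V_CLIP
        if lr > _V_CLIP:
            lr = _V_CLIP
        elif lr < -_V_CLIP:
            lr = -_V_CLIP
        if la > _V_CLIP:
            la = _V_CLIP
        elif la < -_V_CLIP:
            la = -_V_CLIP
        if lb > _V_CLIP:
            lb = _V_CLIP
        elif lb < -_V_CLIP:
            lb = -_V_CLIP

        S = math.exp(ls)
        H = math.exp(lr)
        A = math.exp(la)
        beta = math.exp(lb)
        g = math.exp(-_LN2 * (t[i] - 1.0) / H)
        th = A + (S - A) * g
        lth = math.log(th)
        ex = beta * (log_s[i] - lth)
        u = math.exp(ex) if ex < 23.0 else _U_MAX
        q = math.exp(u * _LNB)
        p = GUESS_RATE + (1.0 - GUESS_RATE) * q
        if p > 1.0 - PROB_CLAMP:
            p = 1.0 - PROB_CLAMP
        elif p < PROB_CLAMP:
            p = PROB_CLAMP
        pv[i] = p
        total += k[i] * math.log(p) + (n[i] - k[i]) * math.log1p(-p)
        if want_grad:
            dLdp = k[i] / p - (n[i] - k[i]) / (1.0 - p)
            common = dLdp * (1.0 - GUESS_RATE) * q * _LNB
            dLdth = common * (-beta * u / th)
            d_s = dLdth * g * S
            d_r = dLdth * (S - A) * g * _LN2 * (t[i] - 1.0) / H
            d_a = dLdth * A * (1.0 - g)
            d_b = common * u * (log_s[i] - lth) * beta

            gb4[0] += d_s
            gb4[1] += d_r
            gb4[2] += d_a
            gb4[3] += d_b
            gd[0, c] += d_s
            gd[1, c] += d_r
            gd[2, c] += d_a
            gd[3, c] += d_b
            gz_raw[0, p_] += d_s
            gz_raw[1, p_] += d_r
            gz_raw[2, p_] += d_a
            gsd_raw[0] += z3[0, p_] * d_s
            gsd_raw[1] += z3[1, p_] * d_r
            gsd_raw[2] += z3[2, p_] * d_a
            gblk[0, c] += d_s * wvec3[0, b_]
            gblk[1, c] += d_r * wvec3[1, b_]
            gblk[2, c] += d_a * wvec3[2, b_]
            if b_ == 1:
                gw2[0] += d_s * blk3[0, c]
                gw2[1] += d_r * blk3[1, c]
                gw2[2] += d_a * blk3[2, c]
            elif b_ == 2:
                gw3[0] += d_s * blk3[0, c]
                gw3[1] += d_r * blk3[1, c]
                gw3[2] += d_a * blk3[2, c]
    return total, pv, gb4, gd, gz_raw, gsd_raw, gblk, gw2, gw3
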