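"""Fused inner-loop kernels for the sampler.

The Metropolis ratios need Bernoulli log likelihoods summed over
species x station x occasion at two parameter points per update; doing
this with numpy temporaries dominates the sweep cost, so the three hot
reductions are compiled with numba when it is available.  The numpy
fallbacks compute identical values (same order of magnitude of
round-off; both paths are exercised by the test suite's tolerance).

Detection logits are passed decomposed as ``lp = a0_site + a1_site *
day`` so one kernel serves both the intercept and the slope updates.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=True)
def _softplus(x):
    # log(1 + e^x), stable
    if x > 0.0:
        return x + np.log1p(np.exp(-x))
    return np.log1p(np.exp(x))


@njit(cache=True, fastmath=True)
def _det_ll_pair_nb(yf, eff, z, a0c, a0n, a1c, a1n, day, group, n_groups):
    K, I, J = yf.shape
    ll_cur = np.zeros((K, n_groups))
    ll_new = np.zeros((K, n_groups))
    for k in range(K):
        for i in range(I):
            if z[k, i] == 0:
                continue
            g = group[i]
            sc = 0.0
            sn = 0.0
            for j in range(J):
                if not eff[i, j]:
                    continue
                d = day[i, j]
                lc = a0c[k, i] + a1c[k, i] * d
                ln = a0n[k, i] + a1n[k, i] * d
                y = yf[k, i, j]
                sc += y * lc - _softplus(lc)
                sn += y * ln - _softplus(ln)
            ll_cur[k, g] += sc
            ll_new[k, g] += sn
    return ll_cur, ll_new


@njit(cache=True, fastmath=True)
def _occ_ll_pair_nb(z, eligible, lp_cur, lp_new, group, n_groups):
    K, I = z.shape
    ll_cur = np.zeros((K, n_groups))
    ll_new = np.zeros((K, n_groups))
    for k in range(K):
        for i in range(I):
            if eligible[k, i] == 0:
                continue
            g = group[i]
            zz = z[k, i]
            ll_cur[k, g] += zz * lp_cur[k, i] - _softplus(lp_cur[k, i])
            ll_new[k, g] += zz * lp_new[k, i] - _softplus(lp_new[k, i])
    return ll_cur, ll_new


@njit(cache=True, fastmath=True)
def _log_q0_nb(eff, a0s, a1s, day):
    K, I = a0s.shape
    J = day.shape[1]
    out = np.zeros((K, I))
    for k in range(K):
        for i in range(I):
            s = 0.0
            for j in range(J):
                if eff[i, j]:
                    # log(1 - p) = log_sigmoid(-lp) = -softplus(lp)
                    s -= _softplus(a0s[k, i] + a1s[k, i] * day[i, j])
            out[k, i] = s
    return out


# ---------------------------------------------------------------------------
# numpy fallbacks


def _det_ll_pair_np(yf, eff, z, a0c, a0n, a1c, a1n, day, group, n_groups):
    efff = eff.astype(float)
    onehot = np.zeros((len(group), n_groups))
    onehot[np.arange(len(group)), group] = 1.0
    out = []
    for a0, a1 in ((a0c, a1c), (a0n, a1n)):
        lp = a0[:, :, None] + a1[:, :, None] * day[None]
        t = (yf * lp - np.logaddexp(0.0, lp) * efff[None]).sum(axis=2)
        out.append((t * z) @ onehot)
    return out[0], out[1]


def _occ_ll_pair_np(z, eligible, lp_cur, lp_new, group, n_groups):
    onehot = np.zeros((len(group), n_groups))
    onehot[np.arange(len(group)), group] = 1.0
    out = []
    for lp in (lp_cur, lp_new):
        ll = (z * lp - np.logaddexp(0.0, lp)) * eligible
        out.append(ll @ onehot)
    return out[0], out[1]


def _log_q0_np(eff, a0s, a1s, day):
    lp = a0s[:, :, None] + a1s[:, :, None] * day[None]
    return -(np.logaddexp(0.0, lp) * eff.astype(float)[None]).sum(axis=2)


if HAVE_NUMBA:
    det_ll_pair = _det_ll_pair_nb
    occ_ll_pair = _occ_ll_pair_nb
    log_q0 = _log_q0_nb
else:  # pragma: no cover
    det_ll_pair = _det_ll_pair_np
    occ_ll_pair = _occ_ll_pair_np
    log_q0 = _log_q0_np
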