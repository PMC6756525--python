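"""Hot numerical loops for the social-dive likelihood and streaming WAIC.

Each record's social label is "does any candidate cue satisfy
(dt <= T) and (dist < D) and (|bearing| <= theta/2)"; the label scan is
the inner loop of every MCMC proposal in T, D or theta, so it is
numba-jitted when numba is importable and falls back to vectorized numpy
otherwise.  Both paths evaluate the identical comparisons.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _labels_jit(cue_dt, cue_dist, cue_bear, ptr, lag, dist, half):
    n = ptr.shape[0] - 1
    out = np.zeros(n, dtype=np.uint8)
    for i in range(n):
        for j in range(ptr[i], ptr[i + 1]):
            if cue_dt[j] <= lag and cue_dist[j] < dist and cue_bear[j] <= half:
                out[i] = 1
                break
    return out


@njit(cache=False)
def _counts_jit(cue_dt, cue_dist, cue_bear, ptr, dived, lag, dist, half):
    n = ptr.shape[0] - 1
    n_s = 0
    n_s_d = 0
    for i in range(n):
        social = False
        for j in range(ptr[i], ptr[i + 1]):
            if cue_dt[j] <= lag and cue_dist[j] < dist and cue_bear[j] <= half:
                social = True
                break
        if social:
            n_s += 1
            n_s_d += dived[i]
    return n_s, n_s_d


@njit(cache=False)
def _waic_jit(cue_dt, cue_dist, cue_bear, ptr, dived, lag_v, dist_v, half_v,
              ps0_v, ps1_v, sum_mass, sum_ll, sum_ll2):
    n = ptr.shape[0] - 1
    n_draws = lag_v.shape[0]
    for s in range(n_draws):
        lag = lag_v[s]
        dist = dist_v[s]
        half = half_v[s]
        lp0 = np.log(ps0_v[s])
        lq0 = np.log(1.0 - ps0_v[s])
        lp1 = np.log(ps1_v[s])
        lq1 = np.log(1.0 - ps1_v[s])
        for i in range(n):
            social = False
            for j in range(ptr[i], ptr[i + 1]):
                if cue_dt[j] <= lag and cue_dist[j] < dist and cue_bear[j] <= half:
                    social = True
                    break
            if social:
                ll = lp1 if dived[i] else lq1
            else:
                ll = lp0 if dived[i] else lq0
            sum_mass[i] += np.exp(ll)
            sum_ll[i] += ll
            sum_ll2[i] += ll * ll


def _labels_numpy(cue_dt, cue_dist, cue_bear, ptr, lag, dist, half):
    n = ptr.shape[0] - 1
    qual = (cue_dt <= lag) & (cue_dist < dist) & (cue_bear <= half)
    rec = np.repeat(np.arange(n), np.diff(ptr))
    out = np.zeros(n, dtype=np.uint8)
    out[rec[qual]] = 1
    return out


def _counts_numpy(cue_dt, cue_dist, cue_bear, ptr, dived, lag, dist, half):
    lab = _labels_numpy(cue_dt, cue_dist, cue_bear, ptr, lag, dist, half)
    return int(lab.sum()), int((lab & (dived > 0)).sum())


def _waic_numpy(cue_dt, cue_dist, cue_bear, ptr, dived, lag_v, dist_v, half_v,
                ps0_v, ps1_v, sum_mass, sum_ll, sum_ll2):
    d = dived.astype(bool)
    for s in range(lag_v.shape[0]):
        lab = _labels_numpy(cue_dt, cue_dist, cue_bear, ptr,
                            lag_v[s], dist_v[s], half_v[s]).astype(bool)
        p = np.where(lab, ps1_v[s], ps0_v[s])
        ll = np.where(d, np.log(p), np.log1p(-p))
        sum_mass += np.exp(ll)
        sum_ll += ll
        sum_ll2 += ll * ll


if HAVE_NUMBA:
    social_labels_kernel = _labels_jit
    social_counts_kernel = _counts_jit
    waic_accumulate_kernel = _waic_jit
else:  # pragma: no cover
    social_labels_kernel = _labels_numpy
    social_counts_kernel = _counts_numpy
    waic_accumulate_kernel = _waic_numpy
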