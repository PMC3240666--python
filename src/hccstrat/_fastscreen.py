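"""JIT-compiled single-covariate Cox screen.

The nested leave-one-out pipeline refits one univariate Cox model per
gene inside every fold; this module provides a numba kernel for that
p = 1 case (Efron or Breslow ties, damped Newton on the score equation).
It computes the same Wald statistics as the generic batched engine in
``_cox``; equivalence is asserted in the test suite.  If numba is
unavailable the caller falls back to the generic engine.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is a hard dep in CI
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True, error_model="numpy")
def _screen_kernel(Fs, group_end, members, member_off, efron,
                   max_iter, score_tol, beta_bound):
    """Per-gene damped Newton on the univariate partial-likelihood score.

    Fs : (n, G) covariate values in descending-time order.
    group_end : (K,) inclusive risk-set end index per event-time group,
        in descending-time order (ascending index).
    members / member_off : CSR layout of event positions per group.
    Returns beta, se, converged arrays of length G.
    """
    n, G = Fs.shape
    K = group_end.shape[0]
    beta_out = np.zeros(G)
    se_out = np.empty(G)
    conv_out = np.zeros(G, dtype=np.bool_)
    for g in range(G):
        x = Fs[:, g]
        xmin = x[0]
        xmax = x[0]
        for i in range(1, n):
            if x[i] < xmin:
                xmin = x[i]
            if x[i] > xmax:
                xmax = x[i]
        if xmax == xmin:
            se_out[g] = np.nan
            continue
        beta = 0.0
        U = 0.0
        I = 1.0
        ok = False
        for _ in range(max_iter):
            shift = beta * xmax if beta > 0 else beta * xmin
            U = 0.0
            I = 0.0
            s0 = 0.0
            s1 = 0.0
            s2 = 0.0
            pos = 0
            for k in range(K):
                end = group_end[k]
                while pos <= end:
                    w = np.exp(beta * x[pos] - shift)
                    s0 += w
                    wx = w * x[pos]
                    s1 += wx
                    s2 += wx * x[pos]
                    pos += 1
                d = member_off[k + 1] - member_off[k]
                t0 = 0.0
                t1 = 0.0
                t2 = 0.0
                for j in range(member_off[k], member_off[k + 1]):
                    mpos = members[j]
                    wm = np.exp(beta * x[mpos] - shift)
                    t0 += wm
                    t1 += wm * x[mpos]
                    t2 += wm * x[mpos] * x[mpos]
                    U += x[mpos]
                for l in range(d):
                    f = l / d if efron else 0.0
                    D0 = s0 - f * t0
                    D1 = s1 - f * t1
                    D2 = s2 - f * t2
                    r = D1 / D0
                    U -= r
                    I += D2 / D0 - r * r
            if not (np.isfinite(U) and np.isfinite(I)):
                ok = False
                break
            if abs(U) < score_tol:
                ok = True
                break
            if I <= 0.0:
                break
            delta = U / I
            if delta > 1.0:
                delta = 1.0
            elif delta < -1.0:
                delta = -1.0
            beta += delta
            if abs(beta) > beta_bound:
                beta = beta_bound if beta > 0 else -beta_bound
                break
        beta_out[g] = beta if np.isfinite(beta) else 0.0
        se_out[g] = 1.0 / np.sqrt(I) if (np.isfinite(I) and I > 0) \
            else np.nan
        conv_out[g] = ok
    return beta_out, se_out, conv_out


def screen_p1(F, time, event, ties="efron", max_iter=100,
              score_tol=1e-7, beta_bound=20.0):
    """Univariate Cox fits for every column of ``F`` (n x G).

    Returns (beta, se, converged); degenerate columns get se = nan and
    converged = False.
    """
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    order = np.argsort(-time, kind="stable")
    t = time[order]
    e = event[order]
    n = t.size
    change = np.nonzero(np.diff(t))[0]
    ends = np.append(change, n - 1)
    starts = np.concatenate(([0], change + 1))
    run_end = np.empty(n, dtype=np.int64)
    for s, f in zip(starts, ends):
        run_end[s:f + 1] = f
    event_pos = np.nonzero(e)[0]
    re_ev = run_end[event_pos]
    group_end, inverse = np.unique(re_ev, return_inverse=True)
    K = group_end.size
    # CSR membership per group, groups ordered by ascending index
    counts = np.bincount(inverse, minlength=K)
    member_off = np.zeros(K + 1, dtype=np.int64)
    np.cumsum(counts, out=member_off[1:])
    members = np.empty(event_pos.size, dtype=np.int64)
    fill = member_off[:-1].copy()
    for p_i, grp in zip(event_pos, inverse):
        members[fill[grp]] = p_i
        fill[grp] += 1

    Fs = np.ascontiguousarray(np.asarray(F, float)[order])
    return _screen_kernel(Fs, group_end, members, member_off,
                          ties == "efron", max_iter, score_tol, beta_bound)
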