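"""Batched Cox proportional-hazards engine.

Newton-Raphson maximisation of the partial likelihood with Efron or
Breslow handling of tied event times, vectorised over a *batch* of design
matrices that share a single right-censored outcome.  The batch axis is
what makes genome-scale univariate screening (one small Cox model per gene
or per SNP, possibly with shared adjustment covariates) affordable inside
leave-one-out loops.

Conventions
-----------
* ``X`` has shape ``(G, n, p)``: G models, n patients, p covariates each.
* Patients censored exactly at an event time are counted at risk for that
  event time.
* Convergence: ``max|score| < score_tol`` or relative log-likelihood change
  ``< ll_tol``.  A coefficient walking past ``beta_bound`` in absolute value
  signals monotone-likelihood divergence; the model is frozen and flagged
  non-converged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CoxFitError(ValueError):
    """Base class for Cox fitting failures."""


class InsufficientEventsError(CoxFitError):
    """Raised when the outcome contains no observed events."""


class DegenerateCovariateError(CoxFitError):
    """Raised when a covariate has zero variance."""


@dataclass
class _SortInfo:
    """Pre-computed risk-set structure for one outcome vector."""

    order: np.ndarray          # descending-time permutation
    time: np.ndarray           # sorted times
    event: np.ndarray          # sorted events (bool)
    n_events: int
    # events at untied event times (or all events under Breslow grouping d=1)
    single_pos: np.ndarray     # positions of untied events in sorted order
    single_riskend: np.ndarray  # inclusive risk-set end index per such event
    # events at tied event times: list of (member positions, risk-end index)
    tied_groups: list = field(default_factory=list)


def _sort_info(time, event) -> _SortInfo:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or time.shape != event.shape:
        raise ValueError("time and event must be 1-D and of equal length")
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("survival times must be finite and positive")
    ev = event.astype(bool)
    if not ev.any():
        raise InsufficientEventsError("outcome contains no events")

    order = np.argsort(-time, kind="stable")
    t = time[order]
    e = ev[order]
    n = t.size

    # inclusive last index of each tied-time run (= risk-set boundary):
    change = np.nonzero(np.diff(t))[0]
    ends = np.append(change, n - 1)
    starts = np.concatenate(([0], change + 1))
    run_end = np.empty(n, dtype=np.intp)
    for s, f in zip(starts, ends):
        run_end[s:f + 1] = f

    event_pos = np.nonzero(e)[0]
    re_ev = run_end[event_pos]
    uniq, counts = np.unique(re_ev, return_counts=True)
    single_ends = uniq[counts == 1]
    single_mask = np.isin(re_ev, single_ends)
    info = _SortInfo(
        order=order, time=t, event=e, n_events=int(e.sum()),
        single_pos=event_pos[single_mask],
        single_riskend=re_ev[single_mask],
    )
    for end in uniq[counts > 1]:
        members = event_pos[re_ev == end]
        info.tied_groups.append((members, int(end)))
    return info


def _stats(Xs, info: _SortInfo, beta, ties="efron", derivs=True):
    """Log partial likelihood and (optionally) score/information, batched.

    Xs : (G, n, p) design already in descending-time order.
    beta : (G, p).
    Returns (ll (G,), grad (G,p) | None, hess (G,p,p) | None); ``hess`` is
    the observed information (positive semi-definite).
    """
    G, n, p = Xs.shape
    eta = np.einsum("gnp,gp->gn", Xs, beta)
    c = eta.max(axis=1, keepdims=True)
    w = np.exp(eta - c)

    cs0 = np.cumsum(w, axis=1)
    if derivs:
        xw = w[..., None] * Xs
        cs1 = np.cumsum(xw, axis=1)
        xxw = xw[..., :, None] * Xs[..., None, :]
        cs2 = np.cumsum(xxw, axis=1)
        grad = np.zeros((G, p))
        hess = np.zeros((G, p, p))
    else:
        grad = hess = None

    ll = np.zeros(G)

    pos, re = info.single_pos, info.single_riskend
    if pos.size:
        S0 = cs0[:, re]                               # (G, E)
        ll += eta[:, pos].sum(axis=1) - np.log(S0).sum(axis=1)
        if derivs:
            r1 = cs1[:, re] / S0[..., None]           # (G, E, p)
            grad += Xs[:, pos].sum(axis=1) - r1.sum(axis=1)
            hess += (cs2[:, re] / S0[..., None, None]).sum(axis=1)
            hess -= np.einsum("gei,gej->gij", r1, r1)

    for members, end in info.tied_groups:
        d = members.size
        S0 = cs0[:, end]
        T0 = w[:, members].sum(axis=1)
        ll += eta[:, members].sum(axis=1)
        if derivs:
            S1 = cs1[:, end]
            S2 = cs2[:, end]
            T1 = xw[:, members].sum(axis=1)
            T2 = xxw[:, members].sum(axis=1)
            grad += Xs[:, members].sum(axis=1)
        for l in range(d):
            f = l / d if ties == "efron" else 0.0
            D0 = S0 - f * T0 if f else S0
            ll -= np.log(D0)
            if derivs:
                D1 = (S1 - f * T1) if f else S1
                D2 = (S2 - f * T2) if f else S2
                g1 = D1 / D0[:, None]
                grad -= g1
                hess += D2 / D0[:, None, None]
                hess -= g1[:, :, None] * g1[:, None, :]

    # each event contributes one raw eta and one max-shifted log-denominator;
    # restore the shift so ll is comparable across beta values
    ll -= info.n_events * c[:, 0]
    return ll, grad, hess


def _solve_newton(hess, grad, ridge):
    G, p, _ = hess.shape
    H = hess + ridge * np.eye(p)
    try:
        return np.linalg.solve(H, grad[..., None])[..., 0]
    except np.linalg.LinAlgError:
        delta = np.empty_like(grad)
        for g in range(G):
            try:
                delta[g] = np.linalg.solve(H[g], grad[g])
            except np.linalg.LinAlgError:
                scale = np.trace(H[g]) / p if p else 1.0
                delta[g] = np.linalg.solve(
                    H[g] + max(abs(scale), 1.0) * 1e-8 * np.eye(p), grad[g])
        return delta


@dataclass
class BatchFitResult:
    beta: np.ndarray        # (G, p)
    se: np.ndarray          # (G, p); nan where information is singular
    loglik: np.ndarray      # (G,)
    converged: np.ndarray   # (G,) bool
    n_iter: np.ndarray      # (G,) int
    info_matrix: np.ndarray  # (G, p, p) observed information at beta


def fit_batch(X, time, event, *, ties="efron", max_iter=50,
              score_tol=1e-7, ll_tol=1e-9, beta_bound=20.0,
              ridge=0.0, init=None, chunk_elems=1_000_000) -> BatchFitResult:
    """Fit G Cox models sharing one outcome.

    ``X`` may be ``(n, p)`` for a single model or ``(G, n, p)``.
    ``ridge`` adds a fixed L2 penalty to the information matrix only (a
    numerical stabiliser for collinear designs, not a penalised fit).
    ``init`` optionally warm-starts the Newton iteration (shape ``(p,)``
    or ``(G, p)``).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    X = np.asarray(X, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    G, n, p = X.shape
    info = _sort_info(time, event)
    Xs = X[:, info.order, :]
    if init is None:
        beta0 = np.zeros((G, p))
    else:
        beta0 = np.broadcast_to(np.asarray(init, float), (G, p)).copy()

    # chunk the batch so transient (chunk, n, p, p) arrays stay bounded
    chunk = max(1, int(chunk_elems / max(n * p * p, 1)))
    outs = []
    for lo in range(0, G, chunk):
        outs.append(_fit_chunk(Xs[lo:lo + chunk], info, ties, max_iter,
                               score_tol, ll_tol, beta_bound, ridge,
                               beta0[lo:lo + chunk]))
    beta = np.concatenate([o[0] for o in outs])
    se = np.concatenate([o[1] for o in outs])
    ll = np.concatenate([o[2] for o in outs])
    conv = np.concatenate([o[3] for o in outs])
    n_iter = np.concatenate([o[4] for o in outs])
    im = np.concatenate([o[5] for o in outs])
    return BatchFitResult(beta, se, ll, conv, n_iter, im)


def _fit_chunk(Xs, info, ties, max_iter, score_tol, ll_tol,
               beta_bound, ridge, beta0):
    G, n, p = Xs.shape
    beta = beta0.copy()
    converged = np.zeros(G, dtype=bool)
    frozen = np.zeros(G, dtype=bool)     # diverged, stop updating
    n_iter = np.zeros(G, dtype=int)
    ll_prev = np.full(G, -np.inf)
    active_idx = np.arange(G)

    for it in range(max_iter):
        Xa = Xs[active_idx]
        ba = beta[active_idx]
        with np.errstate(over="ignore", invalid="ignore"):
            ll, grad, hess = _stats(Xa, info, ba, ties=ties)
            max_score = np.abs(grad).max(axis=1) if p else np.zeros(len(ll))
            rel = np.abs(ll - ll_prev[active_idx]) / (np.abs(ll) + 1.0)
        # numerically broken models (overflowing linear predictors) are
        # frozen as non-converged rather than iterated further
        broken = ~np.isfinite(ll) | ~np.isfinite(grad).all(axis=1)
        if broken.any():
            frozen[active_idx[broken]] = True
            keep0 = ~broken
            active_idx = active_idx[keep0]
            if active_idx.size == 0:
                break
            ll, grad, hess = ll[keep0], grad[keep0], hess[keep0]
            Xa, ba = Xa[keep0], ba[keep0]
            max_score, rel = max_score[keep0], rel[keep0]
        done = (max_score < score_tol) | ((it > 0) & (rel < ll_tol))
        converged[active_idx[done]] = True
        keep = ~done
        active_idx = active_idx[keep]
        if active_idx.size == 0:
            break
        ll, grad, hess = ll[keep], grad[keep], hess[keep]
        Xa, ba = Xa[keep], ba[keep]
        ll_prev[active_idx] = ll

        delta = _solve_newton(hess, grad, ridge)
        cand = ba + delta
        # step-halving is only needed while steps are large; near the
        # optimum a full Newton step is a contraction and the ll-only
        # re-evaluations can be skipped
        big = np.abs(delta).max(axis=1) > 0.25
        if big.any():
            bidx = np.flatnonzero(big)
            step = np.ones((bidx.size, 1))
            Xb = Xa[bidx]
            cb = ba[bidx] + delta[bidx]
            ll_new, _, _ = _stats(Xb, info, cb, ties=ties, derivs=False)
            for _ in range(30):
                worse = ll_new < ll[bidx] - 1e-12
                if not worse.any():
                    break
                step[worse] *= 0.5
                cb = ba[bidx] + step * delta[bidx]
                ll_new, _, _ = _stats(Xb, info, cb, ties=ties, derivs=False)
            cand[bidx] = cb
        beta[active_idx] = cand
        n_iter[active_idx] = it + 1

        diverged = np.abs(cand).max(axis=1) > beta_bound
        if diverged.any():
            div_idx = active_idx[diverged]
            beta[div_idx] = np.clip(beta[div_idx], -beta_bound, beta_bound)
            frozen[div_idx] = True
            active_idx = active_idx[~diverged]
            if active_idx.size == 0:
                break

    ll, grad, hess = _stats(Xs, info, beta, ties=ties)
    se = np.full((G, p), np.nan)
    eye = np.eye(p)
    H = hess + ridge * eye
    with np.errstate(invalid="ignore"):
        try:
            d = np.diagonal(np.linalg.inv(H), axis1=1, axis2=2)
            se = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            for g in range(G):
                try:
                    dg = np.diag(np.linalg.inv(H[g]))
                    se[g] = np.sqrt(np.where(dg > 0, dg, np.nan))
                except np.linalg.LinAlgError:
                    pass
    return beta, se, ll, converged, n_iter, hess


def partial_loglik(X, time, event, beta, *, ties="efron") -> float:
    """Log partial likelihood of a single model at a given ``beta``.

    Exposed so tests can brute-force-maximise the very same objective.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    info = _sort_info(time, event)
    ll, _, _ = _stats(X[None, info.order, :], info, beta[None], ties=ties,
                      derivs=False)
    return float(ll[0])
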