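"""Survival-analysis primitives shared by every pipeline stage.

Cox partial-likelihood fitting (:class:`CoxPHSurvival`), genome-scale
univariate Cox screening, the Mantel-Haenszel log-rank test and the
Kaplan-Meier product-limit estimator.

Outcomes are passed around as a :class:`pandas.DataFrame` with columns
``time`` (months, positive) and ``event`` (0 = censored, 1 = failure),
indexed by patient id; :func:`check_outcome` also accepts the structured
arrays used by scikit-survival.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from ._cox import (
    CoxFitError,
    DegenerateCovariateError,
    InsufficientEventsError,
    fit_batch,
    partial_loglik,
)
from ._fastscreen import HAVE_NUMBA as _HAVE_FAST, screen_p1

__all__ = [
    "CoxPHSurvival",
    "fit_cox",
    "linear_predictor",
    "univariate_screen",
    "log_rank_test",
    "km_estimate",
    "check_outcome",
    "make_outcome",
    "LogRankResult",
    "KMCurve",
    "CoxFitError",
    "DegenerateCovariateError",
    "InsufficientEventsError",
    "partial_loglik",
]

logger = logging.getLogger(__name__)


def make_outcome(time, event, ids=None) -> pd.DataFrame:
    """Assemble a survival outcome table (time in months, event 0/1)."""
    df = pd.DataFrame({"time": np.asarray(time, float),
                       "event": np.asarray(event, int)})
    if ids is not None:
        df.index = pd.Index(ids)
    return df


def check_outcome(outcome):
    """Validate an outcome and return ``(time, event, ids)`` arrays."""
    if isinstance(outcome, pd.DataFrame):
        if not {"time", "event"} <= set(outcome.columns):
            raise ValueError("outcome needs 'time' and 'event' columns")
        time = outcome["time"].to_numpy(float)
        event = outcome["event"].to_numpy()
        ids = outcome.index.to_numpy()
    elif isinstance(outcome, np.ndarray) and outcome.dtype.names:
        names = outcome.dtype.names
        ev_name = next(n for n in names if outcome[n].dtype == bool or
                       "event" in n or "status" in n)
        t_name = next(n for n in names if n != ev_name)
        time = outcome[t_name].astype(float)
        event = outcome[ev_name]
        ids = np.arange(len(outcome))
    else:
        raise TypeError("outcome must be a DataFrame(time, event) or a "
                        "structured array")
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("survival times must be finite and positive")
    event = event.astype(int)
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return time, event, ids


class CoxPHSurvival(BaseEstimator):
    """Cox proportional-hazards model with a Newton-Raphson fitter.

    Parameters
    ----------
    ties : {"efron", "breslow"}
        Handling of tied event times.  Efron is the default.
    ridge : float
        L2 stabiliser added to the information matrix (``0`` = plain
        Newton; a tiny value rescues collinear stage variables).
    alpha_bound : float
        Absolute coefficient bound beyond which the fit is declared
        divergent (monotone likelihood) and flagged non-converged.

    Fitted attributes
    -----------------
    coef_, se_, zvalues_, pvalues_ : per-covariate inference arrays.
    loglik_ : float, log partial likelihood at the optimum.
    converged_ : bool.
    mean_ : training covariate means; :meth:`predict` returns the centred
        linear predictor ``h = (x - mean_) @ coef_`` (the relative hazard).
    """

    def __init__(self, ties="efron", ridge=0.0, alpha_bound=20.0,
                 max_iter=50):
        self.ties = ties
        self.ridge = ridge
        self.alpha_bound = alpha_bound
        self.max_iter = max_iter

    def fit(self, X, y):
        X = self._check_X(X, reset=True)
        time, event, _ = check_outcome(y)
        if len(time) != X.shape[0]:
            raise ValueError("X and outcome have different lengths")
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates contain non-finite values")
        sd = X.std(axis=0)
        if np.any(sd == 0):
            bad = np.asarray(self.feature_names_in_)[sd == 0]
            raise DegenerateCovariateError(
                f"zero-variance covariate(s): {', '.join(map(str, bad))}")
        res = fit_batch(X, time, event, ties=self.ties, ridge=self.ridge,
                        beta_bound=self.alpha_bound, max_iter=self.max_iter)
        self.coef_ = res.beta[0]
        self.se_ = res.se[0]
        self.loglik_ = float(res.loglik[0])
        self.converged_ = bool(res.converged[0])
        # monotone likelihood: a coefficient excursion beyond +-5 on the
        # per-SD scale means the partial likelihood has no interior
        # maximum in any practically meaningful sense
        if np.any(np.abs(self.coef_) * sd > 5.0):
            self.converged_ = False
        self.n_iter_ = int(res.n_iter[0])
        self.info_matrix_ = res.info_matrix[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            self.zvalues_ = self.coef_ / self.se_
            self.pvalues_ = 2.0 * sps.norm.sf(np.abs(self.zvalues_))
        self.mean_ = X.mean(axis=0)
        if not self.converged_:
            warnings.warn("Cox fit did not converge (possible monotone "
                          "likelihood)", RuntimeWarning, stacklevel=2)
        return self

    def predict(self, X) -> np.ndarray:
        """Centred linear predictor h (relative log-hazard)."""
        X = self._check_X(X, reset=False)
        return (X - self.mean_) @ self.coef_

    def _check_X(self, X, reset):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            arr = X.to_numpy(float)
        else:
            arr = np.asarray(X, float)
            if arr.ndim == 1:
                arr = arr[:, None]
            names = [f"x{i}" for i in range(arr.shape[1])]
        if reset:
            self.feature_names_in_ = np.asarray(names, dtype=object)
            self.n_features_in_ = arr.shape[1]
        else:
            if arr.shape[1] != self.n_features_in_:
                raise ValueError("feature count mismatch")
            if isinstance(X, pd.DataFrame) and \
                    list(names) != list(self.feature_names_in_):
                raise ValueError("covariate names do not match the fitted "
                                 "model")
        return arr

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef_, "se": self.se_, "z": self.zvalues_,
             "p": self.pvalues_},
            index=list(self.feature_names_in_))


def fit_cox(covariates, outcome, ties="efron", ridge=0.0) -> CoxPHSurvival:
    """Fit a multivariate Cox model; see :class:`CoxPHSurvival`."""
    return CoxPHSurvival(ties=ties, ridge=ridge).fit(covariates, outcome)


def linear_predictor(model: CoxPHSurvival, covariates) -> pd.Series:
    """Relative-hazard score h for each patient, centred at training means."""
    h = model.predict(covariates)
    idx = covariates.index if isinstance(covariates, pd.DataFrame) else None
    return pd.Series(h, index=idx, name="h")


def univariate_screen(features, outcome, adjust=None, ties="efron"):
    """Per-feature Cox Wald p-values, optionally adjusted for covariates.

    Parameters
    ----------
    features : DataFrame or array, patients x features
        Each column is fitted in its own Cox model.
    adjust : optional DataFrame/array, patients x c
        Covariates included alongside the feature in every model.

    Returns
    -------
    DataFrame indexed like ``features``' columns with columns
    ``coef, se, z, p, converged``.  Degenerate (zero-variance) or
    non-converged features receive the sentinel ``p = 1`` so the vector
    stays aligned with the input.
    """
    if isinstance(features, pd.DataFrame):
        names = features.columns
        F = features.to_numpy(float)
    else:
        F = np.asarray(features, float)
        names = pd.RangeIndex(F.shape[1])
    time, event, _ = check_outcome(outcome)
    n, G = F.shape
    if adjust is not None:
        A = adjust.to_numpy(float) if isinstance(adjust, pd.DataFrame) \
            else np.asarray(adjust, float)
        if A.ndim == 1:
            A = A[:, None]
    else:
        A = np.empty((n, 0))
    p_dim = 1 + A.shape[1]

    good = F.std(axis=0) > 0
    coef = np.zeros(G)
    se = np.full(G, np.nan)
    conv = np.zeros(G, dtype=bool)
    if good.any() and p_dim == 1 and _HAVE_FAST:
        coef, se, conv = screen_p1(F, time, event, ties=ties)
        conv = conv & (np.abs(coef) * F.std(axis=0) <= 5.0)
    elif good.any():
        X = np.empty((int(good.sum()), n, p_dim))
        X[:, :, 0] = F[:, good].T
        X[:, :, 1:] = A[None, :, :]
        init = None
        if p_dim > 1:
            # warm-start the adjusted fits at the adjustment-only optimum
            base = fit_batch(A, time, event, ties=ties)
            if base.converged[0]:
                init = np.concatenate(([0.0], base.beta[0]))
        res = fit_batch(X, time, event, ties=ties, init=init)
        coef[good] = res.beta[:, 0]
        se[good] = res.se[:, 0]
        conv[good] = res.converged & \
            (np.abs(res.beta[:, 0]) * F[:, good].std(axis=0) <= 5.0)
    n_bad = int((~good).sum())
    if n_bad:
        logger.warning("univariate screen: %d degenerate feature(s) "
                       "assigned p = 1", n_bad)
    if (~conv[good]).any():
        logger.warning("univariate screen: %d non-converged feature(s) "
                       "assigned p = 1", int((~conv[good]).sum()))

    with np.errstate(invalid="ignore", divide="ignore"):
        z = coef / se
        pvals = 2.0 * sps.norm.sf(np.abs(z))
    pvals = np.where(conv & np.isfinite(pvals), pvals, 1.0)
    z = np.where(np.isfinite(z), z, 0.0)
    return pd.DataFrame({"coef": coef, "se": se, "z": z, "p": pvals,
                         "converged": conv}, index=names)


@dataclass
class LogRankResult:
    statistic: float
    df: int
    pvalue: float
    groups: np.ndarray       # group labels in report order
    observed: np.ndarray     # events per group
    expected: np.ndarray     # expected events per group


def log_rank_test(groups, outcome) -> LogRankResult:
    """Mantel-Haenszel log-rank test across two or more groups."""
    time, event, _ = check_outcome(outcome)
    g = np.asarray(groups)
    if g.shape[0] != time.shape[0]:
        raise ValueError("groups and outcome have different lengths")
    labels, gidx = np.unique(g, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")

    order = np.argsort(time, kind="stable")
    t, e, gi = time[order], event[order], gidx[order]
    n = t.size

    observed = np.zeros(k)
    expected = np.zeros(k)
    V = np.zeros((k - 1, k - 1))

    at_risk = np.zeros(k)
    for j in range(k):
        at_risk[j] = np.sum(gi == j)

    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        block = slice(i, j)
        d_tot = int(e[block].sum())
        if d_tot > 0:
            n_tot = at_risk.sum()
            d_by_g = np.bincount(gi[block], weights=e[block].astype(float),
                                 minlength=k)
            observed += d_by_g
            expected += d_tot * at_risk / n_tot
            if n_tot > 1:
                frac = at_risk / n_tot
                mult = d_tot * (n_tot - d_tot) / (n_tot - 1)
                Vt = mult * (np.diag(frac) - np.outer(frac, frac))
                V += Vt[: k - 1, : k - 1]
        for idx in range(i, j):
            at_risk[gi[idx]] -= 1
        i = j

    diff = (observed - expected)[: k - 1]
    try:
        chi2 = float(diff @ np.linalg.solve(V, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(V) @ diff)
    chi2 = max(chi2, 0.0)
    p = float(sps.chi2.sf(chi2, k - 1))
    return LogRankResult(chi2, k - 1, p, labels, observed, expected)


@dataclass
class KMCurve:
    """Kaplan-Meier curves, one step function per group."""

    groups: np.ndarray
    tables: dict            # label -> DataFrame(time, at_risk, events,
    #                         censored, survival)

    def survival_at(self, label, t) -> float:
        tab = self.tables[label]
        s = 1.0
        for row_t, row_s in zip(tab["time"], tab["survival"]):
            if row_t <= t:
                s = row_s
            else:
                break
        return s

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for lab, tab in self.tables.items():
            part = tab.copy()
            part.insert(0, "group", lab)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)


def km_estimate(outcome, groups=None) -> KMCurve:
    """Product-limit survival estimate per group.

    Patients censored exactly at an event time count as at risk for that
    time.  ``S(0) = 1``; the returned table has one row per distinct
    observed time with the post-time survival value.
    """
    time, event, _ = check_outcome(outcome)
    if groups is None:
        groups = np.zeros(time.shape[0], dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    tables = {}
    for lab in labels:
        m = g == lab
        t, e = time[m], event[m]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        uniq = np.unique(t)
        rows = []
        s = 1.0
        n_risk = t.size
        for ut in uniq:
            here = t == ut
            d = int(e[here].sum())
            c = int((~e[here].astype(bool)).sum())
            if n_risk > 0 and d > 0:
                s *= 1.0 - d / n_risk
            rows.append((ut, n_risk, d, c, s))
            n_risk -= int(here.sum())
        tables[lab] = pd.DataFrame(
            rows, columns=["time", "at_risk", "events", "censored",
                           "survival"])
    return KMCurve(labels, tables)
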