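"""Stage 1: clinicopathologic Cox stratification into good/poor groups.

Univariate selection of significant clinicopathologic parameters, a
multivariate Cox model over the selected set, leave-one-out (LOO)
relative-hazard scores, and a median split into good and poor prognosis
strata.  Selection is redone inside every LOO fold so the held-out
patient never influences the model that scores them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .simulate import clinical_design
from .survival import (
    CoxPHSurvival,
    KMCurve,
    LogRankResult,
    check_outcome,
    km_estimate,
    log_rank_test,
    univariate_screen,
)

__all__ = [
    "ClinicalCoxStratifier", "StratumAssignment", "EmptySelectionError",
    "select_clinical_params", "loo_clinical_predictor", "dichotomize",
    "evaluate_split",
]

logger = logging.getLogger(__name__)

#: clinical columns treated as candidate prognostic parameters (age and
#: sex are nuisance covariates handled in expression preprocessing)
CANDIDATE_PARAMS = ("tumor_size", "NOTN", "log_afp", "albu",
                    "venous_infiltration", "pTNM", "AJCC")


class EmptySelectionError(RuntimeError):
    """No clinicopathologic parameter passed the univariate screen."""


class DegenerateSplitError(RuntimeError):
    """All linear-predictor values identical; no split exists."""


def _design(clinical: pd.DataFrame) -> pd.DataFrame:
    cols = set(clinical.columns)
    if {"AFP", "ALBU"} <= cols:          # raw clinical table
        return clinical_design(clinical)
    return clinical.astype(float)        # already a numeric design


def select_clinical_params(clinical, outcome, alpha: float = 0.05,
                           candidates=CANDIDATE_PARAMS,
                           ties="efron") -> list:
    """Parameters with univariate Cox Wald p < alpha, in input order."""
    design = _design(clinical)
    cand = [c for c in candidates if c in design.columns]
    if not cand:
        raise ValueError("no candidate parameters present")
    scr = univariate_screen(design[cand], outcome, ties=ties)
    selected = [c for c in cand if scr.loc[c, "p"] < alpha]
    if not selected:
        raise EmptySelectionError(
            f"no clinicopathologic parameter significant at alpha={alpha}")
    return selected


class ClinicalCoxStratifier(BaseEstimator):
    """Select-then-fit clinical Cox model producing a relative hazard.

    ``fit`` performs univariate selection at ``alpha`` followed by a
    multivariate Cox fit on the selected parameters; ``predict`` returns
    the centred linear predictor h.  A tiny ridge rescues the fit when
    collinear stage variables (pTNM, AJCC) make the information matrix
    singular.
    """

    def __init__(self, alpha=0.05, candidates=CANDIDATE_PARAMS,
                 ties="efron", ridge_fallback=1e-6):
        self.alpha = alpha
        self.candidates = candidates
        self.ties = ties
        self.ridge_fallback = ridge_fallback

    def fit(self, X, y):
        design = _design(X)
        self.selected_ = select_clinical_params(
            X, y, alpha=self.alpha, candidates=self.candidates,
            ties=self.ties)
        sub = design[self.selected_]
        try:
            model = CoxPHSurvival(ties=self.ties).fit(sub, y)
            if not np.all(np.isfinite(model.se_)):
                raise np.linalg.LinAlgError
        except (np.linalg.LinAlgError, FloatingPointError):
            model = CoxPHSurvival(ties=self.ties,
                                  ridge=self.ridge_fallback).fit(sub, y)
        self.model_ = model
        return self

    def predict(self, X) -> np.ndarray:
        design = _design(X)
        return self.model_.predict(design[self.selected_])


def loo_clinical_predictor(clinical, outcome, alpha: float = 0.05,
                           candidates=CANDIDATE_PARAMS,
                           ties="efron") -> pd.Series:
    """Leave-one-out relative hazard h for every patient.

    Selection and the multivariate fit are redone on the n-1 training
    patients of each fold; the held-out patient receives the centred
    linear predictor of that fold's model.  A fold whose screen selects
    nothing contributes the null score h = 0 with a warning.
    """
    time, event, ids = check_outcome(outcome)
    n = len(time)
    if n < 20:
        raise ValueError("leave-one-out stratification needs n >= 20")
    design = _design(clinical)
    if not np.array_equal(np.asarray(clinical.index), ids):
        raise ValueError("clinical and outcome patient ids differ")

    h = np.zeros(n)
    est = ClinicalCoxStratifier(alpha=alpha, candidates=candidates,
                                ties=ties)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            fold = est.__class__(**est.get_params()).fit(
                design.iloc[mask], outcome.iloc[mask])
            h[i] = float(fold.predict(design.iloc[[i]])[0])
        except EmptySelectionError:
            logger.warning("LOO fold %d: empty clinical selection; "
                           "h = 0 assigned", i)
            h[i] = 0.0
    return pd.Series(h, index=clinical.index, name="h")


@dataclass
class StratumAssignment:
    """Good/poor prognosis labels from a median split of h."""

    endpoint: str
    h: pd.Series
    threshold: float
    labels: pd.Series          # "good" (h < threshold or tied) / "poor"

    def group(self, label: str) -> pd.Index:
        return self.labels.index[self.labels == label]


def dichotomize(h: pd.Series, endpoint: str = "survival",
                rule: str = "median") -> StratumAssignment:
    """Split patients at the median of h; ties at the median go to good.

    Lower h = lower relative hazard = good prognosis.
    """
    if rule != "median":
        raise ValueError("only the median rule is implemented")
    hv = h.to_numpy(float)
    if not np.all(np.isfinite(hv)):
        raise ValueError("linear predictor contains non-finite values")
    thr = float(np.median(hv))
    if np.all(hv == hv[0]):
        raise DegenerateSplitError("all linear-predictor values identical")
    labels = pd.Series(np.where(hv <= thr, "good", "poor"), index=h.index,
                       name="label")
    if (labels == "poor").sum() == 0:
        raise DegenerateSplitError(
            "median split left the poor group empty (mass of ties at the "
            "median)")
    return StratumAssignment(endpoint, h.copy(), thr, labels)


def evaluate_split(assignment: StratumAssignment, outcome):
    """Log-rank test and KM curves for a good/poor assignment."""
    labels = assignment.labels.loc[outcome.index]
    lr: LogRankResult = log_rank_test(labels.to_numpy(), outcome)
    km: KMCurve = km_estimate(outcome, labels.to_numpy())
    return lr, km
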