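"""Cox engine: closed forms, brute-force oracle, lifelines cross-checks."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from hccstrat._cox import _sort_info, _stats, fit_batch
from hccstrat._fastscreen import screen_p1
from hccstrat.survival import (
    CoxPHSurvival,
    DegenerateCovariateError,
    InsufficientEventsError,
    fit_cox,
    linear_predictor,
    log_rank_test,
    make_outcome,
    univariate_screen,
)


def brute_force_loglik(x, time, event, grid):
    """Explicit no-ties partial log-likelihood on a beta grid.

    Written out from the definition (sum over events of the covariate
    term minus the log risk-set sum) independently of the package's
    engine, and vectorised over the grid only.
    """
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    lls = np.zeros(len(grid))
    for gi, b in enumerate(grid):
        ll = 0.0
        for i in np.flatnonzero(event):
            risk = time >= time[i]
            ll += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
        lls[gi] = ll
    return lls


class TestFitCox:
    def test_closed_form_single_covariate(self):
        # times (1,2,3), all events, x = (0,1,0): the score equation
        # reduces to e^(2 beta) = 2, so beta = ln(2)/2
        y = make_outcome([1, 2, 3], [1, 1, 1])
        m = fit_cox(np.array([[0.0], [1.0], [0.0]]), y)
        assert m.converged_
        assert m.coef_[0] == pytest.approx(np.log(2) / 2, abs=1e-6)

    def test_brute_force_oracle_small_n(self):
        """Newton fit agrees with grid maximisation of the explicit
        partial likelihood on random small datasets (finite-MLE cases)."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 40:
            n = int(rng.integers(4, 9))
            time = rng.uniform(0.5, 20.0, n)
            event = np.zeros(n, int)
            event[rng.choice(n, max(1, n // 2), replace=False)] = 1
            x = rng.normal(size=n)
            m = CoxPHSurvival().fit(x[:, None], make_outcome(time, event))
            if not m.converged_ or abs(m.coef_[0]) > 5:
                continue    # monotone likelihood: no finite maximiser
            grid = np.linspace(m.coef_[0] - 0.3, m.coef_[0] + 0.3, 6001)
            lls = brute_force_loglik(x, time, event, grid)
            assert abs(grid[np.argmax(lls)] - m.coef_[0]) < 1e-4
            checked += 1

    def test_matches_lifelines_with_ties(self, rng):
        n = 100
        df = pd.DataFrame({"a": rng.normal(size=n),
                           "b": rng.binomial(1, 0.4, n).astype(float)})
        time = np.maximum(np.ceil(rng.exponential(6, n)), 1.0)
        event = rng.binomial(1, 0.6, n)
        m = fit_cox(df, make_outcome(time, event))
        ll = CoxPHFitter().fit(
            pd.DataFrame({"T": time, "E": event, "a": df.a, "b": df.b}),
            "T", "E")
        np.testing.assert_allclose(m.coef_, ll.params_.values, atol=1e-6)
        np.testing.assert_allclose(m.se_, ll.standard_errors_.values,
                                   atol=1e-6)

    def test_breslow_matches_lifelines(self, rng):
        n = 60
        x = rng.normal(size=n)
        time = np.maximum(np.ceil(rng.exponential(6, n)), 1.0)
        event = rng.binomial(1, 0.6, n)
        m = fit_cox(x[:, None], make_outcome(time, event), ties="breslow")
        ll = CoxPHFitter().fit(
            pd.DataFrame({"T": time, "E": event, "x": x}), "T", "E")
        # lifelines uses Efron; Breslow must differ on tied data yet agree
        # in the absence of ties
        assert m.converged_
        t2 = rng.uniform(1, 50, n)  # no ties
        m_e = fit_cox(x[:, None], make_outcome(t2, event), ties="efron")
        m_b = fit_cox(x[:, None], make_outcome(t2, event), ties="breslow")
        assert m_e.coef_[0] == pytest.approx(m_b.coef_[0], abs=1e-9)

    def test_degenerate_covariate_rejected(self, outcome_noties):
        X = pd.DataFrame({"flat": np.ones(40)})
        with pytest.raises(DegenerateCovariateError, match="flat"):
            fit_cox(X, outcome_noties)

    def test_no_events_rejected(self):
        y = make_outcome([1, 2, 3, 4], [0, 0, 0, 0])
        with pytest.raises(InsufficientEventsError):
            fit_cox(np.arange(4.0)[:, None], y)

    def test_monotone_likelihood_flagged(self):
        # perfectly separating covariate: likelihood increases without
        # bound, the fit must stop and flag non-convergence or stop at a
        # large coefficient rather than diverge
        time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        event = np.array([1, 1, 1, 1, 1, 1])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        with pytest.warns(RuntimeWarning):
            m = fit_cox(x[:, None], make_outcome(time, event))
        assert not m.converged_
        assert abs(m.coef_[0]) <= 20.0


class TestLinearPredictor:
    def test_centred_arithmetic(self, outcome_noties):
        x = np.array([0.0, 1.0, 2.0] + [0.5] * 37)
        m = fit_cox(x[:, None], outcome_noties)
        h = m.predict(x[:, None])
        # h = (x - mean) beta: differences scale exactly with x
        np.testing.assert_allclose(h[1] - h[0], m.coef_[0], atol=1e-12)
        np.testing.assert_allclose(h[2] - h[0], 2 * m.coef_[0], atol=1e-12)
        assert h.mean() == pytest.approx(0.0, abs=1e-10)

    def test_name_mismatch_raises(self, outcome_noties, rng):
        X = pd.DataFrame({"a": rng.normal(size=40)})
        m = fit_cox(X, outcome_noties)
        with pytest.raises(ValueError, match="names"):
            m.predict(X.rename(columns={"a": "b"}))

    def test_zero_coef_gives_zero_h(self, outcome_noties, rng):
        X = pd.DataFrame({"a": rng.normal(size=40)})
        m = fit_cox(X, outcome_noties)
        m.coef_ = np.zeros_like(m.coef_)
        assert np.all(linear_predictor(m, X) == 0)


class TestScoreLogrankIdentity:
    def test_binary_covariate_no_ties(self, rng):
        """Cox score test at beta=0 equals the log-rank statistic."""
        n = 50
        x = rng.binomial(1, 0.5, n).astype(float)
        time = rng.uniform(1, 100, n)
        event = rng.binomial(1, 0.6, n)
        event[0] = 1
        info = _sort_info(time, event)
        Xs = x[None, info.order, None]
        _, grad, hess = _stats(Xs, info, np.zeros((1, 1)))
        score_chi2 = grad[0, 0] ** 2 / hess[0, 0, 0]
        lr = log_rank_test(x.astype(int), make_outcome(time, event))
        assert score_chi2 == pytest.approx(lr.statistic, abs=1e-8)


class TestFastScreen:
    def test_equivalent_to_generic_engine(self, rng):
        """The jitted p=1 kernel reproduces the batched Newton engine."""
        n, G = 70, 60
        F = rng.normal(size=(n, G))
        time = np.maximum(np.ceil(rng.exponential(8, n)), 1.0)  # ties
        event = rng.binomial(1, 0.5, n)
        event[0] = 1
        beta_f, se_f, conv_f = screen_p1(F, time, event)
        res = fit_batch(F.T[:, :, None], time, event)
        ok = conv_f & res.converged
        assert ok.mean() > 0.9
        np.testing.assert_allclose(beta_f[ok], res.beta[ok, 0], atol=1e-8)
        np.testing.assert_allclose(se_f[ok], res.se[ok, 0], atol=1e-8)


class TestUnivariateScreen:
    def test_duplicate_feature_identical_p(self, outcome_noties, rng):
        f = rng.normal(size=40)
        F = pd.DataFrame({"g1": f, "g2": f, "g3": rng.normal(size=40)})
        scr = univariate_screen(F, outcome_noties)
        assert scr.loc["g1", "p"] == scr.loc["g2", "p"]

    def test_constant_feature_sentinel(self, outcome_noties, rng):
        F = pd.DataFrame({"flat": np.ones(40),
                          "ok": rng.normal(size=40)})
        scr = univariate_screen(F, outcome_noties)
        assert scr.loc["flat", "p"] == 1.0
        assert scr.loc["ok", "p"] < 1.0

    def test_adjusted_screen_shifts_p(self, rng):
        """Adjusting for a confounder that drives the hazard weakens the
        marginal association of a correlated feature."""
        n = 150
        conf = rng.normal(size=n)
        feat = conf + rng.normal(0, 0.6, n)
        time = np.exp(3 - 0.8 * conf + rng.normal(0, 0.3, n))
        event = np.ones(n, int)
        y = make_outcome(time, event)
        p_raw = univariate_screen(feat[:, None], y)["p"].iloc[0]
        p_adj = univariate_screen(feat[:, None], y,
                                  adjust=conf[:, None])["p"].iloc[0]
        assert p_raw < 1e-4
        assert p_adj > p_raw
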