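"""Supervised-PCA Cox subclassifier: PCA algebra, selection, nesting."""

import numpy as np
import pandas as pd
import pytest

from hccstrat.simulate import SignatureBlock, SimulationConfig, \
    generate_cohort
from hccstrat.stratify import dichotomize, evaluate_split
from hccstrat.subclassify import (
    SupervisedPCACox,
    dual_tissue_predictor,
    loo_expression_predictor,
    pca_fit,
    pca_project,
    select_top_genes,
    stratified_pipeline,
)
from hccstrat.survival import make_outcome

from conftest import random_survival


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        X = np.outer(base, rng.normal(size=5))
        model = pca_fit(X, m=3)
        assert model.m == 1                      # rank reduction
        assert model.explained[0] == pytest.approx(1.0)

    def test_orthogonal_design_variances(self):
        """Two uncorrelated genes with variances 4 and 1: explained
        fractions are exactly (0.8, 0.2)."""
        # build exact data: columns with sample variance 4 and 1, zero
        # covariance and zero mean
        a = np.array([2.0, -2.0, 2.0, -2.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        X = np.column_stack([a, b])
        model = pca_fit(X, m=2)
        np.testing.assert_allclose(model.explained, [0.8, 0.2], atol=1e-12)

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(40, 25))
        model = pca_fit(X, m=6)
        G = model.loadings.T @ model.loadings
        np.testing.assert_allclose(G, np.eye(6), atol=1e-8)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(30, 10))
        m1 = pca_fit(X, m=4)
        m2 = pca_fit(X.copy(), m=4)
        np.testing.assert_array_equal(m1.loadings, m2.loadings)
        for j in range(4):
            k = np.argmax(np.abs(m1.loadings[:, j]))
            assert m1.loadings[k, j] > 0

    def test_projection_consistency(self, rng):
        X = rng.normal(size=(25, 12))
        model = pca_fit(X, m=4)
        scores = model.project(X)
        # projecting a training sample reproduces its training scores
        np.testing.assert_allclose(model.project(X[3]), scores[3],
                                   atol=1e-12)
        # the training-mean sample maps to the origin
        np.testing.assert_allclose(model.project(X.mean(0)),
                                   np.zeros(4), atol=1e-10)
        # linearity: scaling a centred sample scales its scores
        doubled = 2 * (X[3] - X.mean(0)) + X.mean(0)
        np.testing.assert_allclose(model.project(doubled), 2 * scores[3],
                                   atol=1e-10)

    def test_project_series_checks_genes(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 5)),
                         columns=list("abcde"))
        model = pca_fit(X, m=2)
        s = pd.Series(rng.normal(size=5), index=list("abcde"))
        out = pca_project(model, s)
        assert out.shape == (2,)
        with pytest.raises(KeyError):
            pca_project(model, s.drop("c"))


class TestSelectTopGenes:
    def test_k_equals_all(self, rng, outcome_noties):
        expr = pd.DataFrame(rng.normal(size=(40, 8)),
                            columns=[f"g{i}" for i in range(8)])
        sel = select_top_genes(expr, outcome_noties, K=8)
        assert sorted(sel) == sorted(expr.columns)

    def test_tie_break_by_gene_id(self, rng, outcome_noties):
        f = rng.normal(size=40)
        expr = pd.DataFrame({"zz": f, "aa": f})
        sel = select_top_genes(expr, outcome_noties, K=1)
        assert sel == ["aa"]

    def test_planted_block_recovered(self, small_cohort):
        # DFS endpoint: ~51% events, the best-powered recovery setting
        truth = small_cohort.truth
        planted = set(truth.signature_genes["tumor/good"]["genes"])
        strat = pd.Series(truth.stratum_labels)
        good = strat.index[strat == "good"]
        sel = select_top_genes(small_cohort.expr_tumor[good].T,
                               small_cohort.dfs.loc[good],
                               K=len(planted))
        assert len(planted & set(sel)) >= 0.6 * len(planted)


class TestNestedLOO:
    def test_strict_nesting_sentinel_perturbation(self, rng):
        """Fold i's trained objects are invariant to patient i's
        expression values."""
        n, G = 25, 60
        expr = pd.DataFrame(rng.normal(size=(G, n)),
                            index=[f"g{i}" for i in range(G)],
                            columns=[f"P{i}" for i in range(n)])
        y = random_survival(np.random.default_rng(5), n, ids=expr.columns)
        _, rec1 = loo_expression_predictor(expr, y, K=10, m=3)
        expr2 = expr.copy()
        expr2.iloc[:, 7] = 1e6                   # sentinel
        _, rec2 = loo_expression_predictor(expr2, y, K=10, m=3)
        assert rec1[7].selected_genes == rec2[7].selected_genes
        np.testing.assert_array_equal(rec1[7].pca.loadings,
                                      rec2[7].pca.loadings)
        np.testing.assert_allclose(rec1[7].cox.coef_, rec2[7].cox.coef_,
                                   atol=1e-10)

    def test_estimator_matches_loo_fold(self, rng):
        """The public estimator refit on n-1 patients reproduces the
        fold objects of the internal LOO loop."""
        n, G = 24, 40
        expr = pd.DataFrame(rng.normal(size=(G, n)),
                            index=[f"g{i}" for i in range(G)],
                            columns=[f"P{i}" for i in range(n)])
        y = random_survival(np.random.default_rng(2), n, ids=expr.columns)
        h, recs = loo_expression_predictor(expr, y, K=12, m=4)
        i = 5
        mask = np.ones(n, bool)
        mask[i] = False
        est = SupervisedPCACox(K=12, m=4).fit(expr.T.iloc[mask],
                                              y.iloc[mask])
        assert list(est.selected_genes_) == list(recs[i].selected_genes)
        h_i = est.predict(expr.T.iloc[[i]])[0]
        assert h_i == pytest.approx(h.iloc[i], abs=1e-10)

    def test_planted_signal_detected_within_stratum(self, small_cohort):
        truth = small_cohort.truth
        strat = pd.Series(truth.stratum_labels)
        good = strat.index[strat == "good"]
        y = small_cohort.dfs.loc[good]
        h, _ = loo_expression_predictor(small_cohort.expr_tumor[good], y,
                                        K=40, m=6, keep_records=False)
        lr, _ = evaluate_split(dichotomize(h), y)
        assert lr.pvalue < 0.01

    def test_id_mismatch_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 25)),
                            columns=[f"P{i}" for i in range(25)])
        y = random_survival(rng, 25, ids=[f"Q{i}" for i in range(25)])
        with pytest.raises(ValueError, match="ids differ"):
            loo_expression_predictor(expr, y)


class TestDualTissue:
    def test_identical_tissues_select_identical_genes(self, rng):
        n, G = 24, 30
        expr = pd.DataFrame(rng.normal(size=(G, n)),
                            index=[f"g{i}" for i in range(G)],
                            columns=[f"P{i}" for i in range(n)])
        y = random_survival(np.random.default_rng(8), n, ids=expr.columns)
        h, recs = dual_tissue_predictor(expr, expr.copy(), y, K=8, m=3)
        for r in recs:
            half = len(r.selected_genes) // 2
            assert r.selected_genes[:half] == r.selected_genes[half:]

    def test_dual_uses_twelve_pcs_by_default(self, rng):
        n, G = 30, 40
        et = pd.DataFrame(rng.normal(size=(G, n)),
                          index=[f"g{i}" for i in range(G)],
                          columns=[f"P{i}" for i in range(n)])
        en = pd.DataFrame(rng.normal(size=(G, n)), index=et.index,
                          columns=et.columns)
        y = random_survival(np.random.default_rng(9), n, ids=et.columns)
        h, recs = dual_tissue_predictor(et, en, y, K=10, m=6)
        assert max(r.m_used for r in recs) == 12


class TestSensitivityAndPipeline:
    def test_k_m_sensitivity_concordant_on_planted_signal(self):
        """Splits with K in {50, 200} and m = 5 agree with the default
        on a planted-signal stratum (label agreement >= 0.7)."""
        cfg = SimulationConfig(
            seed=77, n_patients=240, n_genes=600, n_snps=20, n_eqtl=2,
            n_csnp=0,
            signature_spec=[SignatureBlock("tumor", "good", 60, 1.2, 0.3)])
        c = generate_cohort(cfg)
        strat = pd.Series(c.truth.stratum_labels)
        good = strat.index[strat == "good"]
        y = c.survival.loc[good]
        expr = c.expr_tumor[good]
        h_ref, _ = loo_expression_predictor(expr, y, K=100, m=6,
                                            keep_records=False)
        ref = dichotomize(h_ref).labels
        for K, m in [(50, 6), (200, 6), (100, 5)]:
            h, _ = loo_expression_predictor(expr, y, K=K, m=m,
                                            keep_records=False)
            agree = (dichotomize(h).labels == ref).mean()
            assert agree >= 0.7, (K, m, agree)

    def test_stratified_pipeline_structure(self, small_cohort):
        report = stratified_pipeline(small_cohort, endpoint="survival",
                                     tissue="tumor", K=40, m=4)
        assert set(report["strata"]) == {"good", "poor"}
        for rep in report["strata"].values():
            if not rep.skipped:
                assert rep.logrank.pvalue <= 1.0
                assert set(rep.labels.unique()) <= {"good", "poor"}
        fw = report["four_way"].dropna()
        assert fw.str.match(r"(good|poor)-clinical/(good|poor)-expr").all()
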