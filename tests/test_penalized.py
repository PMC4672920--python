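import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from cismaxt import (
    AnalysisConfig,
    Layer,
    PenalizedGeneModel,
    build_windows,
    fit_enet_cv,
    fit_gene_model,
    fit_lasso_cv,
    gaussian_deviance,
    lambda_path,
    solve_at_penalty,
)
from cismaxt.penalized import CVEngine, make_folds
from conftest import make_annotations, make_matrix
from oracle import brute_force_enet, kkt_violation


def _standard_design(rng, n, p):
    X = rng.standard_normal((n, p))
    X = X - X.mean(axis=0)
    return X / X.std(axis=0)


class TestGaussianDeviance:
    def test_closed_form_fixture(self):
        # RSS_null = 5, RSS_full = 1  =>  D = 4 ln 5
        d = gaussian_deviance([1, 2, 3, 4], [1.5, 1.5, 3.5, 3.5])
        assert d == pytest.approx(4 * np.log(5), abs=1e-9)

    def test_null_prediction_gives_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert gaussian_deviance(y, np.full(4, y.mean())) == 0.0

    def test_constant_outcome_gives_zero(self):
        assert gaussian_deviance(np.ones(5), np.zeros(5)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            gaussian_deviance([1, 2], [1, 2, 3])

    def test_perfect_fit_is_finite(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.isfinite(gaussian_deviance(y, y))


class TestLambdaPath:
    def test_lambda_max_from_kkt(self, rng):
        # single feature: lambda_max = |x'y| / n, the smallest penalty with
        # an all-zero stationary point
        x = _standard_design(rng, 10, 1)
        y = 2.0 * x[:, 0] + 5.0
        path = lambda_path(x, y, l1_fraction=1.0)
        yc = y - y.mean()
        assert path[0] == pytest.approx(abs(x[:, 0] @ yc) / 10)
        coef, _ = solve_at_penalty(x, y, path[0] * 1.0001)
        assert np.all(coef == 0)

    def test_lambda_max_scales_inversely_with_l1_fraction(self, rng):
        X = _standard_design(rng, 12, 4)
        y = rng.standard_normal(12)
        full = lambda_path(X, y, l1_fraction=1.0)
        half = lambda_path(X, y, l1_fraction=0.5)
        assert half[0] == pytest.approx(2 * full[0])

    def test_geometric_spacing(self, rng):
        X = _standard_design(rng, 12, 3)
        path = lambda_path(X, rng.standard_normal(12), path_size=20,
                           min_ratio=0.01)
        ratios = path[1:] / path[:-1]
        assert np.allclose(ratios, 0.01 ** (1 / 19))
        assert np.all(np.diff(path) < 0)

    def test_empty_design_empty_path(self):
        assert lambda_path(np.empty((5, 0)), np.arange(5.0)).size == 0


class TestSolverOracle:
    @pytest.mark.parametrize("l1_fraction", [1.0, 0.6, 0.3])
    def test_matches_sign_enumeration(self, l1_fraction):
        # coordinate-descent solution at fixed penalty vs exhaustive
        # 3^p sign-pattern enumeration, plus direct KKT verification
        rng = np.random.default_rng(20)
        for _ in range(25):
            n = int(rng.integers(5, 13))
            p = int(rng.integers(1, 5))
            X = _standard_design(rng, n, p)
            beta = rng.standard_normal(p) * rng.integers(0, 2, size=p)
            y = X @ beta + rng.standard_normal(n) * 0.5
            yc = y - y.mean()
            lam_max = np.abs(X.T @ yc).max() / (n * l1_fraction)
            lam = lam_max * rng.uniform(0.05, 0.8)
            coef, _ = solve_at_penalty(X, y, lam, l1_fraction)
            expected = brute_force_enet(X, y, lam, l1_fraction)
            np.testing.assert_allclose(coef, expected, atol=1e-6)
            assert kkt_violation(X, yc, coef, lam, l1_fraction) < 1e-6

    def test_grouping_of_duplicated_features(self, rng):
        # elastic net with a ridge share splits the weight equally across
        # exact duplicates; closed form for two copies of one column:
        # beta = (c - lam*f) / (2 + lam*(1 - f)) with c = x'yc/n
        x = _standard_design(rng, 30, 1)[:, 0]
        y = 1.5 * x + rng.standard_normal(30) * 0.2
        X = np.column_stack([x, x])
        lam, f = 0.3, 0.3
        coef, _ = solve_at_penalty(X, y, lam, f)
        yc = y - y.mean()
        c = x @ yc / 30
        expected = (c - lam * f) / (2 + lam * (1 - f))
        np.testing.assert_allclose(coef, [expected, expected], atol=1e-8)


class TestCVFits:
    def test_empty_design_intercept_only(self):
        y = np.arange(8.0)
        res = fit_lasso_cv(np.empty((8, 0)), y)
        assert res.deviance == 0.0 and res.n_selected == 0
        assert res.intercept == pytest.approx(y.mean())

    def test_constant_outcome(self, rng):
        X = _standard_design(rng, 10, 3)
        res = fit_lasso_cv(X, np.ones(10))
        assert res.deviance == 0.0 and res.n_selected == 0

    def test_deviance_nonnegative_and_selection_counts(self, rng):
        X = rng.standard_normal((20, 8))
        y = X[:, 0] * 2 + rng.standard_normal(20) * 0.3
        res = fit_lasso_cv(X, y)
        assert res.deviance > 0
        assert res.n_selected == len(res.coefficients) > 0
        assert "x0" in res.coefficients

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=15)
    def test_deviance_nonnegative_fuzz(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(6, 16))
        p = int(r.integers(0, 9))
        X = r.standard_normal((n, p)) * r.uniform(0.1, 5)
        y = r.standard_normal(n) * r.uniform(0.1, 5) + r.uniform(-10, 10)
        res = fit_lasso_cv(X, y, AnalysisConfig(k_folds=min(5, n)))
        assert res.deviance >= 0.0

    def test_lasso_equals_enet_at_unit_l1_fraction(self, rng):
        X = rng.standard_normal((18, 6))
        y = X[:, 1] - X[:, 4] + rng.standard_normal(18) * 0.5
        cfg = AnalysisConfig(l1_fraction_grid=(1.0,))
        lasso = fit_lasso_cv(X, y, cfg)
        enet = fit_enet_cv(X, y, cfg)
        assert lasso.chosen_lambda == enet.chosen_lambda
        assert set(lasso.coefficients) == set(enet.coefficients)
        for k in lasso.coefficients:
            assert lasso.coefficients[k] == pytest.approx(
                enet.coefficients[k], abs=1e-8)

    def test_deviance_invariant_to_joint_relabeling(self, rng):
        # permuting samples jointly in y, X and the fold assignment is a
        # pure relabeling: every CV quantity and the deviance must match
        X = rng.standard_normal((15, 5))
        y = X[:, 0] + rng.standard_normal(15) * 0.5
        folds = make_folds(15, 5, fold_seed=3)
        perm = rng.permutation(15)
        e1 = CVEngine(X, fold_assignment=folds)
        e2 = CVEngine(X[perm], fold_assignment=folds[perm])
        r1, r2 = e1.fit(y), e2.fit(y[perm])
        assert r1["deviance"] == pytest.approx(r2["deviance"], rel=1e-10)
        assert r1["chosen_lambda"] == pytest.approx(r2["chosen_lambda"])

    def test_training_rss_monotone_along_path(self, rng):
        from cismaxt.penalized import _solve_path

        X = np.asfortranarray(_standard_design(rng, 14, 6))
        y = X[:, 0] + rng.standard_normal(14)
        yc = y - y.mean()
        path = lambda_path(X, y, path_size=25)
        coefs = _solve_path(X, yc, 1.0, path, tol=1e-10)
        rss = ((yc[:, None] - X @ coefs) ** 2).sum(axis=0)
        assert np.all(np.diff(rss) <= 1e-8)


class TestEstimator:
    def test_sklearn_protocol(self, rng):
        model = PenalizedGeneModel(method="enet", l1_fraction_grid=(0.5, 1.0))
        params = model.get_params()
        assert params["method"] == "enet"
        cloned = clone(model)
        X = rng.standard_normal((20, 4))
        y = X[:, 2] * 3 + rng.standard_normal(20) * 0.2
        cloned.fit(X, y)
        assert cloned.deviance_ > 0
        assert cloned.coef_.shape == (4,)
        assert cloned.ridge_fraction_ == pytest.approx(
            1 - cloned.chosen_l1_fraction_)

    def test_predict_on_original_scale(self, rng):
        X = rng.normal(50, 10, size=(25, 3))
        y = 0.4 * X[:, 0] + rng.standard_normal(25)
        model = PenalizedGeneModel().fit(X, y)
        pred = model.predict(X)
        # strong signal: fitted values track y well and use raw-scale X
        assert np.corrcoef(pred, y)[0, 1] > 0.9

    def test_constant_columns_get_zero_coef(self, rng):
        X = np.column_stack([np.ones(20), rng.standard_normal(20)])
        y = 2 * X[:, 1] + rng.standard_normal(20) * 0.1
        model = PenalizedGeneModel().fit(X, y)
        assert model.coef_[0] == 0.0 and model.coef_[1] != 0.0

    def test_k_folds_validation(self, rng):
        X = rng.standard_normal((4, 2))
        with pytest.raises(ValueError, match="k_folds"):
            PenalizedGeneModel(k_folds=10).fit(X, rng.standard_normal(4))


class TestFitGeneModel:
    def _toy(self, rng, n=27):
        expr = make_matrix(rng.normal(8.4, 0.6, size=(1, n)), Layer.EXPRESSION,
                           start0=5_000)
        snps = make_matrix(rng.integers(0, 3, size=(6, n)).astype(float),
                           Layer.SNP, start0=4_000)
        cpgs = make_matrix(rng.uniform(0.1, 0.9, size=(4, n)), Layer.CPG,
                           start0=6_000)
        windows = build_windows(expr.annotations, snps.annotations,
                                cpgs.annotations, window_bp=100_000)
        return expr, snps, cpgs, windows

    def test_global_design_concatenates_layers(self, rng):
        expr, snps, cpgs, windows = self._toy(rng)
        from cismaxt.penalized import assemble_design

        X, ids, layers = assemble_design(
            windows["probe0"], {Layer.SNP: snps, Layer.CPG: cpgs}, "global")
        assert X.shape[1] == 6 + 4
        assert ids == snps.feature_ids + cpgs.feature_ids

    def test_cpg_model_ignores_snp_matrix(self, rng):
        expr, snps, cpgs, windows = self._toy(rng)
        y = expr.values[0]
        r1 = fit_gene_model(windows["probe0"], {Layer.SNP: snps,
                                                Layer.CPG: cpgs}, y, "cpg",
                            "lasso")
        shuffled = make_matrix(snps.values[:, ::-1], Layer.SNP, start0=4_000)
        r2 = fit_gene_model(windows["probe0"], {Layer.SNP: shuffled,
                                                Layer.CPG: cpgs}, y, "cpg",
                            "lasso")
        assert r1.deviance == r2.deviance
        assert r1.coefficients == r2.coefficients

    def test_planted_snp_effect_detected(self):
        # strong single-SNP effect: selected with positive deviance
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            expr, snps, cpgs, windows = self._toy(rng)
            x = snps.values[2]
            y = 8.4 + 2.0 * (x - x.mean()) / x.std() + rng.normal(0, 0.3, 27)
            res = fit_gene_model(windows["probe0"], {Layer.SNP: snps}, y,
                                 "snp", "lasso")
            if res.deviance > 0 and "snp2" in res.coefficients:
                hits += 1
            assert res.n_snps_selected == res.n_selected
        assert hits == 3
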