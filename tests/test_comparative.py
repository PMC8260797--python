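import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from chemophylo import (
    PhylogeneticLogisticRegression,
    chisq_choice_test,
    parse_newick,
    pgls_fit,
    phyloglm_fit,
    select_model_bic,
    simulate_bm_traits,
    simulate_mk_presence,
    simulate_tree,
)


def gls_bruteforce(M, y, V):
    """Hand-coded GLS via explicit inverse."""
    Vi = np.linalg.inv(V)
    return np.linalg.solve(M.T @ Vi @ M, M.T @ Vi @ y)


def irls_logistic(M, y, tol=1e-12):
    """Newton-Raphson ML logistic regression (independent oracle)."""
    beta = np.zeros(M.shape[1])
    for _ in range(200):
        p = expit(M @ beta)
        H = M.T @ (M * (p * (1 - p))[:, None])
        step = np.linalg.solve(H, M.T @ (y - p))
        beta += step
        if np.abs(step).max() < tol:
            break
    return beta


def star_tree(n, depth=1.0):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return parse_newick(
            "(" + ",".join(f"t{i}:{depth}" for i in range(n)) + ");"
        )


class TestPGLS:
    def test_identity_covariance_equals_ols(self, yule10, rng):
        n = yule10.n_tips
        X = pd.DataFrame(rng.standard_normal((n, 2)),
                         index=yule10.tip_labels, columns=["x1", "x2"])
        y = pd.Series(rng.standard_normal(n), index=yule10.tip_labels)
        fit = pgls_fit(y, X, yule10, model="OLS_star")
        M = np.column_stack([np.ones(n), X.values])
        ols = np.linalg.lstsq(M, y.values, rcond=None)[0]
        np.testing.assert_allclose(fit.coef_, ols, atol=1e-10)
        resid_fit = y.values - fit.predict(X)
        resid_ols = y.values - M @ ols
        np.testing.assert_allclose(resid_fit, resid_ols, atol=1e-10)

    def test_bm_matches_bruteforce_gls(self, rng):
        tree = simulate_tree(4, 1.0, seed=9)
        cov = tree.covariance()
        X = pd.DataFrame({"x": rng.standard_normal(4)},
                         index=tree.tip_labels)
        y = pd.Series(rng.standard_normal(4), index=tree.tip_labels)
        fit = pgls_fit(y, X, tree, model="BM")
        M = np.column_stack([np.ones(4), X.values])
        np.testing.assert_allclose(
            fit.coef_, gls_bruteforce(M, y.values, cov.matrix), atol=1e-8
        )

    def test_slope_recovery_under_bm_noise(self):
        tree = simulate_tree(100, 1.0, seed=31)
        covered = 0
        n_runs = 100
        for s in range(n_runs):
            rng = np.random.default_rng(1000 + s)
            x = pd.Series(rng.standard_normal(100), index=tree.tip_labels)
            noise = simulate_bm_traits(tree, 1.0, 1.0, 0.0, 1,
                                       seed=2000 + s)["trait1"]
            y = 2.0 * x + noise
            fit = pgls_fit(y, x.to_frame("x"), tree, model="lambda_ML")
            from scipy.stats import t as tdist
            half = tdist.ppf(0.975, df=98) * fit.se_[1]
            if abs(fit.coef_[1] - 2.0) <= half:
                covered += 1
        assert covered >= 0.9 * n_runs

    def test_collinear_predictors_rejected(self, yule10, rng):
        x = rng.standard_normal(10)
        X = pd.DataFrame({"a": x, "b": 2 * x}, index=yule10.tip_labels)
        y = pd.Series(rng.standard_normal(10), index=yule10.tip_labels)
        with pytest.raises(ValueError, match="collinear"):
            pgls_fit(y, X, yule10)

    def test_label_mismatch_rejected(self, yule10, rng):
        X = pd.DataFrame({"x": rng.standard_normal(9)},
                         index=yule10.tip_labels[:9])
        y = pd.Series(rng.standard_normal(10), index=yule10.tip_labels)
        with pytest.raises(KeyError):
            pgls_fit(y, X, yule10)


class TestModelSelection:
    def test_single_fit_returned(self, yule10, rng):
        y = pd.Series(rng.standard_normal(10), index=yule10.tip_labels)
        X = pd.DataFrame({"x": rng.standard_normal(10)},
                         index=yule10.tip_labels)
        fit = pgls_fit(y, X, yule10, model="BM")
        assert select_model_bic([fit]) is fit

    def test_bic_penalty_breaks_ties(self):
        class Stub:
            def __init__(self, bic, k):
                self.bic_, self.n_params_ = bic, k

        a, b = Stub(10.0, 3), Stub(10.0, 4)
        assert select_model_bic([b, a]) is a

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_model_bic([])

    def test_bm_data_prefers_phylogenetic_model(self):
        tree = simulate_tree(100, 1.0, seed=77)
        wins = 0
        n_runs = 50
        for s in range(n_runs):
            rng = np.random.default_rng(500 + s)
            x = pd.Series(rng.standard_normal(100), index=tree.tip_labels)
            y = simulate_bm_traits(tree, 1.0, 1.0, 0.0, 1,
                                   seed=900 + s)["trait1"]
            fits = [pgls_fit(y, x.to_frame("x"), tree, model=m)
                    for m in ("OLS_star", "BM", "lambda_ML")]
            if select_model_bic(fits).model in ("BM", "lambda_ML"):
                wins += 1
        assert wins >= 0.9 * n_runs

    def test_bic_differences_invariant_to_affine_rescale(self, yule10, rng):
        x = pd.Series(rng.standard_normal(10), index=yule10.tip_labels)
        y = simulate_bm_traits(yule10, 0.8, 1.0, 0.0, 1, seed=4)["trait1"]
        deltas = []
        for scale, shift in ((1.0, 0.0), (7.3, -2.2)):
            fits = [pgls_fit(scale * y + shift, x.to_frame("x"), yule10,
                             model=m) for m in ("OLS_star", "BM")]
            deltas.append(fits[0].bic_ - fits[1].bic_)
        assert deltas[0] == pytest.approx(deltas[1], abs=1e-6)


class TestPhyloLogistic:
    def test_independence_limit_matches_irls(self):
        star = star_tree(40)
        rng = np.random.default_rng(5)
        x = rng.standard_normal(40)
        y = (rng.random(40) < expit(-0.3 + 2.0 * x)).astype(float)
        X = pd.DataFrame({"x": x}, index=star.tip_labels)
        ys = pd.Series(y, index=star.tip_labels)
        est = PhylogeneticLogisticRegression(
            tree=star, n_boot=0, alpha=np.inf
        ).fit(X, ys)
        M = np.column_stack([np.ones(40), x])
        np.testing.assert_allclose(est.coef_, irls_logistic(M, y),
                                   atol=1e-3)

    def test_estimated_alpha_near_irls_on_independent_data(self):
        star = star_tree(60)
        rng = np.random.default_rng(6)
        x = rng.standard_normal(60)
        y = (rng.random(60) < expit(0.2 + 1.5 * x)).astype(float)
        est = PhylogeneticLogisticRegression(tree=star, n_boot=0).fit(
            pd.DataFrame({"x": x}, index=star.tip_labels),
            pd.Series(y, index=star.tip_labels),
        )
        M = np.column_stack([np.ones(60), x])
        np.testing.assert_allclose(est.coef_, irls_logistic(M, y), atol=0.3)

    def test_single_class_rejected(self, yule10):
        y = pd.Series(1.0, index=yule10.tip_labels)
        X = pd.DataFrame({"x": np.arange(10.0)}, index=yule10.tip_labels)
        with pytest.raises(ValueError, match="single class"):
            phyloglm_fit(y, X, yule10, n_boot=0)

    def test_perfect_separation_capped_with_warning(self):
        star = star_tree(30)
        x = np.linspace(-2, 2, 30)
        y = (x > 0).astype(float)
        with pytest.warns(UserWarning, match="separation"):
            est = PhylogeneticLogisticRegression(
                tree=star, n_boot=0, alpha=np.inf
            ).fit(pd.DataFrame({"x": x}, index=star.tip_labels),
                  pd.Series(y, index=star.tip_labels))
        assert np.abs(est.coef_).max() <= est.beta_cap + 1e-9

    def test_bootstrap_p_sane_under_null(self):
        tree = simulate_tree(60, 1.0, seed=13)
        D = tree.distance_matrix().matrix
        q = -np.log(0.5) / D[np.triu_indices(60, 1)].mean()
        x = simulate_bm_traits(tree, 1.0, 1.0, 0.0, 1, seed=14)["trait1"]
        x = (x - x.mean()) / x.std()
        ps = []
        est = PhylogeneticLogisticRegression(tree=tree, n_boot=39)
        for s in range(10):
            y = simulate_mk_presence(tree, q / 2, q / 2, 1, 1,
                                     seed=100 + s).iloc[:, 0].astype(float)
            if y.min() == y.max():
                continue
            est.random_state = s
            est.fit(x.to_frame("x"), y)
            ps.append(est.boot_pvalues_[1])
        ps = np.array(ps)
        assert np.all((ps > 0) & (ps <= 1))
        assert ps.mean() > 0.15  # no wholesale spurious significance

    def test_detects_strong_true_effect(self):
        star = star_tree(80)
        rng = np.random.default_rng(21)
        x = rng.standard_normal(80)
        y = (rng.random(80) < expit(2.5 * x)).astype(float)
        est = PhylogeneticLogisticRegression(
            tree=star, n_boot=99, random_state=0
        ).fit(pd.DataFrame({"x": x}, index=star.tip_labels),
              pd.Series(y, index=star.tip_labels))
        assert est.boot_pvalues_[1] <= 0.05


class TestChisqChoice:
    def test_even_split_null(self):
        r = chisq_choice_test(10, 10)
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0)

    def test_fifteen_five(self):
        r = chisq_choice_test(15, 5)
        assert r.statistic == pytest.approx(5.0)
        assert r.p_value == pytest.approx(0.0253, abs=5e-4)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            chisq_choice_test(0, 0)
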