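import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirlassonet.io import Config, EdgeList
from mirlassonet.lasso import (
    MirnaLassoModel,
    cross_validate,
    extract_associations,
    fit_disease,
    fit_lasso,
    fit_lasso_path,
    kkt_max_violation,
    lambda_max,
    lambda_path,
    objective_value,
    soft_threshold,
)
from mirlassonet.netmir import build_netmir
from mirlassonet.signatures import DiseaseSignatureMatrix


def random_instance(rng, n=30, p=5, noise=0.5):
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p) * (rng.random(p) < 0.6)
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y


class TestSoftThreshold:
    @pytest.mark.parametrize("z,gamma,expected", [
        (3.0, 1.0, 2.0),
        (-0.5, 1.0, 0.0),
        (-3.0, 1.0, -2.0),
        (0.0, 0.5, 0.0),
    ])
    def test_closed_form(self, z, gamma, expected):
        assert soft_threshold(z, gamma) == expected

    @given(st.floats(-100, 100, allow_nan=False))
    def test_identity_at_zero_penalty(self, z):
        assert soft_threshold(z, 0.0) == z

    @given(st.floats(-100, 100), st.floats(0, 100))
    def test_shrinks_toward_zero(self, z, gamma):
        out = soft_threshold(z, gamma)
        assert abs(out) <= abs(z)
        assert out * z >= 0

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestFitLasso:
    def test_orthonormal_design_matches_soft_thresholded_ols(self):
        # X'X / n = I, columns centered: beta_j = S(x_j'y/n, lam/2)
        X = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        y = np.array([2.0, 1.0, -0.5, -1.5])
        ols = X.T @ y / 4
        for lam in (0.1, 0.5, 1.0, 3.0):
            intercept, beta = fit_lasso(X, y, lam, tol=1e-12, standardize=False)
            expected = soft_threshold(ols, lam / 2.0)
            np.testing.assert_allclose(beta, expected, atol=1e-10)
            assert intercept == pytest.approx(y.mean())

    @pytest.mark.parametrize("standardize", [False, True])
    def test_null_solution_at_lambda_max(self, standardize):
        rng = np.random.default_rng(0)
        X, y = random_instance(rng)
        lmax = lambda_max(X, y, standardize=standardize)
        for lam in (lmax, 1.5 * lmax):
            _, beta = fit_lasso(X, y, lam, standardize=standardize)
            np.testing.assert_array_equal(beta, np.zeros(X.shape[1]))

    def test_matches_sklearn_objective_on_correlated_design(self):
        sklearn_lasso = pytest.importorskip("sklearn.linear_model").Lasso
        rng = np.random.default_rng(42)
        base = rng.standard_normal(25)
        X = np.column_stack([base + 0.1 * rng.standard_normal(25) for _ in range(3)])
        y = X[:, 0] + 0.3 * rng.standard_normal(25)
        lam = 0.2  # model scale; effective L1 level is lam/2
        intercept, beta = fit_lasso(X, y, lam, tol=1e-12, standardize=False)
        ref = sklearn_lasso(alpha=lam / 2.0, fit_intercept=True, tol=1e-12,
                            max_iter=100000).fit(X, y)
        ours = objective_value(X, y, intercept, beta, lam, standardize=False)
        theirs = objective_value(X, y, ref.intercept_, ref.coef_, lam,
                                 standardize=False)
        assert ours <= theirs + 1e-9
        np.testing.assert_allclose(beta, ref.coef_, atol=1e-6)

    @pytest.mark.parametrize("standardize", [False, True])
    def test_kkt_conditions_hold(self, standardize):
        rng = np.random.default_rng(5)
        for _ in range(5):
            X, y = random_instance(rng, n=40, p=8)
            lam = 0.3 * lambda_max(X, y, standardize=standardize)
            tol = 1e-10
            _, beta = fit_lasso(X, y, lam, tol=tol, standardize=standardize)
            assert kkt_max_violation(X, y, beta, lam, standardize=standardize) <= 10 * tol

    def test_objective_never_increases_across_sweeps(self):
        rng = np.random.default_rng(8)
        X, y = random_instance(rng, n=30, p=10)
        trace: list[float] = []
        fit_lasso(X, y, 0.1 * lambda_max(X, y), tol=1e-10,
                  objective_trace=trace)
        assert len(trace) >= 1
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-12)

    def test_constant_column_pinned_to_zero_with_warning(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 3))
        X[:, 1] = 4.2
        y = X[:, 0] + 0.1 * rng.standard_normal(20)
        with pytest.warns(UserWarning, match="constant predictor"):
            _, beta = fit_lasso(X, y, 0.05)
        assert beta[1] == 0.0

    def test_nonconvergence_reports_last_delta(self):
        rng = np.random.default_rng(3)
        X, y = random_instance(rng)
        with pytest.raises(RuntimeError, match="did not converge"):
            fit_lasso(X, y, 1e-6, tol=1e-14, max_iter=1)

    def test_warm_start_reaches_same_solution(self):
        rng = np.random.default_rng(4)
        X, y = random_instance(rng)
        lam = 0.2 * lambda_max(X, y)
        _, cold = fit_lasso(X, y, lam, tol=1e-12)
        _, warm = fit_lasso(X, y, lam, tol=1e-12, beta0=cold)
        np.testing.assert_allclose(cold, warm, atol=1e-10)


class TestLambdaPath:
    def test_strictly_decreasing_with_exact_length(self):
        rng = np.random.default_rng(1)
        X, y = random_instance(rng)
        path = lambda_path(X, y, n_lambda=100, lambda_min_ratio=1e-3)
        assert len(path) == 100
        assert np.all(np.diff(path) < 0)
        assert path[-1] == pytest.approx(path[0] * 1e-3)

    def test_first_value_gives_null_model(self):
        rng = np.random.default_rng(6)
        X, y = random_instance(rng)
        path = lambda_path(X, y, n_lambda=10)
        _, beta = fit_lasso(X, y, path[0])
        assert np.all(beta == 0.0)

    def test_constant_response_rejected(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError, match="constant"):
            lambda_path(X, np.ones(10))

    def test_support_grows_from_path_start_to_end(self):
        rng = np.random.default_rng(12)
        X, y = random_instance(rng, n=50, p=10)
        path = lambda_path(X, y, n_lambda=30)
        _, betas = fit_lasso_path(X, y, path)
        assert np.count_nonzero(betas[0]) == 0
        assert np.count_nonzero(betas[0]) <= np.count_nonzero(betas[-1])


class TestCrossValidate:
    def test_default_folds_is_ten(self):
        import inspect
        assert inspect.signature(cross_validate).parameters["n_folds"].default == 10

    def test_noiseless_single_predictor_selects_small_lambda(self):
        rng = np.random.default_rng(21)
        X = rng.standard_normal((60, 1))
        y = X[:, 0].copy()
        path = lambda_path(X, y, n_lambda=50)
        cv = cross_validate(X, y, path, n_folds=5, seed=0)
        assert cv.index_selected > 40  # near the small-lambda end
        assert cv.mean_mse[cv.index_selected] < 1e-3

    def test_matches_manual_leave_block_out_loop(self):
        rng = np.random.default_rng(30)
        X, y = random_instance(rng, n=20, p=3)
        path = lambda_path(X, y, n_lambda=12)
        cv = cross_validate(X, y, path, n_folds=10, seed=3)

        order = np.random.default_rng(3).permutation(20)
        folds = np.array_split(order, 10)
        manual = np.zeros((10, len(path)))
        for f, test_idx in enumerate(folds):
            train = np.setdiff1d(np.arange(20), test_idx)
            ints, betas = fit_lasso_path(X[train], y[train], path)
            pred = X[test_idx] @ betas.T + ints
            manual[f] = ((pred - y[test_idx][:, None]) ** 2).mean(axis=0)
        np.testing.assert_array_equal(cv.fold_mse, manual)
        assert cv.lambda_selected == path[np.argmin(manual.mean(axis=0))]

    def test_tie_break_prefers_larger_lambda(self):
        path = np.array([1.0, 0.5, 0.1])
        # contrived: identical mean MSE across lambdas -> pick path[0]
        rng = np.random.default_rng(2)
        X = np.zeros((10, 1))
        X[:, 0] = 1e-12 * rng.standard_normal(10)  # nearly dead predictor
        y = rng.standard_normal(10)
        cv = cross_validate(X, y, path, n_folds=5, seed=0, standardize=False)
        assert cv.lambda_selected == path[cv.index_selected]
        assert cv.index_selected == int(np.argmin(cv.mean_mse))

    def test_requires_enough_rows(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="n_folds"):
            cross_validate(X, np.zeros(5), [1.0], n_folds=10)


class TestDiseaseFit:
    def _networks(self, seed=0, n=60, p=6):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(n)]
        mirnas = [f"M{j}" for j in range(p)]
        X = (rng.random((n, p)) < 0.3).astype(float)
        X[:, 0] = (rng.random(n) < 0.4).astype(float)
        direct = EdgeList.from_pairs(
            [(mirnas[j], genes[i]) for i in range(n) for j in range(p) if X[i, j]],
            directed=True,
        )
        nm = build_netmir(direct, set(), genes, mirnas)
        y = nm.values[:, 0].copy()
        flip = rng.random(n) < 0.05
        y[flip] = 1 - y[flip]
        dm = DiseaseSignatureMatrix(gene_ids=genes, disease_ids=["D1"],
                                    values=y[:, None])
        return nm, dm

    def test_planted_mirna_gets_top_positive_coefficient(self):
        nm, dm = self._networks()
        cfg = Config(n_folds=5, lambda_grid_size=40)
        res = fit_disease(nm, dm, "D1", cfg)
        assert res.beta[0] > 0
        assert np.argmax(res.beta) == 0
        assert res.lambda_selected in res.lambda_path

    def test_fixed_seed_rerun_is_bitwise_identical(self):
        nm, dm = self._networks()
        cfg = Config(n_folds=5, lambda_grid_size=40)
        r1 = fit_disease(nm, dm, "D1", cfg)
        r2 = fit_disease(nm, dm, "D1", cfg)
        np.testing.assert_array_equal(r1.beta, r2.beta)
        np.testing.assert_array_equal(r1.cv.fold_mse, r2.cv.fold_mse)
        assert r1.lambda_selected == r2.lambda_selected

    def test_zero_variance_signature_errors_with_disease_name(self):
        nm, dm = self._networks()
        dm.values[:, 0] = 1.0
        with pytest.raises(ValueError, match="D1"):
            fit_disease(nm, dm, "D1")

    def test_mismatched_gene_order_rejected(self):
        nm, dm = self._networks()
        dm2 = DiseaseSignatureMatrix(
            gene_ids=list(reversed(dm.gene_ids)), disease_ids=dm.disease_ids,
            values=dm.values[::-1],
        )
        with pytest.raises(ValueError, match="gene row"):
            MirnaLassoModel.from_networks(nm, dm2, "D1")

    def test_summary_mentions_selection(self):
        nm, dm = self._networks()
        res = fit_disease(nm, dm, "D1", Config(n_folds=5, lambda_grid_size=30))
        text = res.summary()
        assert "lambda selected" in text and "nonzero" in text


class TestPlantedSignalRecovery:
    @staticmethod
    def _planted_outrank_others(data, result) -> bool:
        """Across a run's diseases, do planted miRNAs get a better mean
        coefficient rank than non-planted ones?"""
        from scipy.stats import rankdata

        planted_ranks, other_ranks = [], []
        for fit in result.fits:
            planted = data.truth.planted[fit.disease_id]
            ranks = rankdata(-fit.beta)  # rank 1 = largest coefficient
            for m, r in zip(fit.mirna_ids, ranks):
                (planted_ranks if m in planted else other_ranks).append(r)
        return np.mean(planted_ranks) < np.mean(other_ranks)

    def test_planted_mirnas_outrank_non_planted_in_19_of_20_seeds(
            self, benchmark_runs):
        import warnings
        from mirlassonet.pipeline import run_pipeline
        from mirlassonet.synth import SynthConfig, generate_all

        wins = sum(self._planted_outrank_others(data, with_ind)
                   for data, with_ind, _ in benchmark_runs)
        for seed in range(11, 21):
            data = generate_all(SynthConfig(seed=seed))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = run_pipeline(data.expression, data.text,
                                   data.direct_targets, data.ppi, data.gold)
            wins += self._planted_outrank_others(data, res)
        assert wins >= 19


class TestExtractAssociations:
    class _FakeFit:
        def __init__(self, disease, mirnas, beta):
            self.disease_id = disease
            self.mirna_ids = mirnas
            self.beta = np.asarray(beta)

        def associations(self, keep_sign):
            out = []
            for m, b in zip(self.mirna_ids, self.beta):
                if b > 0 or (keep_sign == "both" and b != 0):
                    out.append((self.disease_id, m, float(b)))
            return out

    def test_positive_only_default(self):
        fit = self._FakeFit("D", ["m1", "m2", "m3"], [0.3, 0.0, -0.2])
        net = extract_associations([fit])
        assert net.edges == [("D", "m1", 0.3)]

    def test_keep_both_includes_negative(self):
        fit = self._FakeFit("D", ["m1", "m2", "m3"], [0.3, 0.0, -0.2])
        net = extract_associations([fit], keep_sign="both")
        assert len(net) == 2

    def test_all_zero_beta_gives_no_edges(self):
        fit = self._FakeFit("D", ["m1"], [0.0])
        assert len(extract_associations([fit])) == 0

    def test_empty_fit_list_rejected(self):
        with pytest.raises(ValueError):
            extract_associations([])
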