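"""Staged OLS decomposition: POV accounting, invariants, prediction, scales."""

import numpy as np
import pytest

from chipdecon.background import (
    BackgroundModel,
    decompose_windows,
    multiscale_decompose,
)
from chipdecon.simulate import simulate_smooth_fixture


def incremental_r2_oracle(y, X):
    """Independent pseudoinverse-based incremental R-squared, in percent.

    Stage i regresses y on an intercept plus the first i columns via pinv;
    POV_i = 100 * (R2_i - R2_{i-1}).
    """
    y = np.asarray(y, float)
    n = len(y)
    tss = np.sum((y - y.mean()) ** 2)
    r2 = [0.0]
    for i in range(1, X.shape[1] + 1):
        Z = np.column_stack([np.ones(n), X[:, :i]])
        beta = np.linalg.pinv(Z) @ y
        rss = np.sum((y - Z @ beta) ** 2)
        r2.append(1 - rss / tss)
    return 100 * np.diff(np.array(r2))


def random_instance(rng, n=200, p=5, rho=0.5):
    base = rng.standard_normal((n, p))
    X = base @ (np.eye(p) + rho * rng.random((p, p)))  # correlated predictors
    beta = rng.standard_normal(p)
    y = 3.0 + X @ beta + rng.standard_normal(n) * 2.0
    return y, X


def fit(y, X):
    names = [f"x{i}" for i in range(X.shape[1])]
    return BackgroundModel(y, dict(zip(names, X.T))).fit()


class TestSingleStageFits:
    def test_perfect_single_predictor_fit(self, rng):
        x = rng.standard_normal(100)
        res = fit(x, x.reshape(-1, 1))
        assert res.params["intercept"] == pytest.approx(0, abs=1e-10)
        assert res.params["x0"] == pytest.approx(1, abs=1e-10)
        assert res.mse_path[-1] == pytest.approx(0, abs=1e-12)
        assert res.total_pov == pytest.approx(100, abs=1e-8)

    def test_intercept_only_stage_is_sample_variance(self, rng):
        y = rng.poisson(5.0, 500).astype(float)
        res = fit(y, rng.standard_normal((500, 2)))
        assert res.mse_path[0] == pytest.approx(np.var(y, ddof=1), rel=1e-12)
        assert res.stages[0].params[0] == pytest.approx(y.mean())

    def test_degenerate_regressand_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit(np.ones(50), np.random.default_rng(0).standard_normal((50, 2)))

    def test_random_instance_matches_pseudoinverse_solver(self, rng):
        y, X = random_instance(rng, n=200, p=3)
        res = fit(y, X)
        Z = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.pinv(Z) @ y
        np.testing.assert_allclose(res.params.values, beta, rtol=1e-8)
        mse = np.sum((y - Z @ beta) ** 2) / (len(y) - 1)
        assert res.mse_path[-1] == pytest.approx(mse, rel=1e-8)


class TestStagedDecomposition:
    def test_exact_predictor_takes_all_pov(self, rng):
        x1 = rng.standard_normal(300)
        x2 = rng.standard_normal(300)
        res = fit(2 * x1, np.column_stack([x1, x2]))
        assert res.pov["x0"] == pytest.approx(100, abs=1e-8)
        assert res.pov["x1"] == pytest.approx(0, abs=1e-8)

    def test_independent_noise_has_near_zero_pov(self):
        rng = np.random.default_rng(777)
        y = rng.standard_normal(10_000)
        X = rng.standard_normal((10_000, 5))
        res = fit(y, X)
        assert np.all(res.pov.values < 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_staged_povs_equal_incremental_r2(self, seed):
        rng = np.random.default_rng(seed)
        y, X = random_instance(rng)
        res = fit(y, X)
        np.testing.assert_allclose(
            res.pov.values, incremental_r2_oracle(y, X), rtol=1e-8, atol=1e-10
        )

    def test_cross_check_against_statsmodels_full_model(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        y, X = random_instance(rng)
        res = fit(y, X)
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert res.rsquared == pytest.approx(ols.rsquared, rel=1e-10)
        np.testing.assert_allclose(res.params.values, ols.params, rtol=1e-8)

    def test_telescoping_sum_is_exact(self, rng):
        for _ in range(5):
            y, X = random_instance(rng)
            res = fit(y, X)
            assert res.pov.values.sum() == pytest.approx(res.total_pov, rel=1e-10)
            assert res.total_pov == pytest.approx(100 * res.rsquared, rel=1e-12)

    def test_total_pov_invariant_under_order_permutation(self, rng):
        y, X = random_instance(rng)
        res = fit(y, X)
        for _ in range(5):
            perm = rng.permutation(X.shape[1])
            res_p = fit(y, X[:, perm])
            assert res_p.total_pov == pytest.approx(res.total_pov, rel=1e-8)

    def test_pov_invariant_under_affine_rescaling(self, rng):
        y, X = random_instance(rng)
        res = fit(y, X)
        for j in range(X.shape[1]):
            X2 = X.copy()
            X2[:, j] = 3.7 * X2[:, j] - 11.0
            res2 = fit(y, X2)
            np.testing.assert_allclose(res2.pov.values, res.pov.values,
                                       rtol=1e-7, atol=1e-9)

    def test_collinear_predictor_gets_zero_pov(self, rng):
        y, X = random_instance(rng, p=3)
        X_dup = np.column_stack([X, X[:, 0]])  # duplicate of the first column
        res = fit(y, X_dup)
        assert res.pov["x3"] == pytest.approx(0, abs=1e-8)


class TestPrediction:
    def test_in_sample_prediction_residual_mean_zero(self, rng):
        y, X = random_instance(rng)
        res = fit(y, X)
        yhat = res.predict()
        assert np.mean(y - yhat) == pytest.approx(0, abs=1e-10)

    def test_zero_features_predict_intercept(self, rng):
        y, X = random_instance(rng)
        res = fit(y, X)
        out = res.predict(np.zeros((4, X.shape[1])))
        np.testing.assert_allclose(out, res.params["intercept"])

    def test_column_mismatch_raises(self, rng):
        y, X = random_instance(rng)
        res = fit(y, X)
        with pytest.raises(ValueError):
            res.predict(np.zeros((4, X.shape[1] + 1)))

    def test_rounding_mode(self, rng):
        y, X = random_instance(rng)
        res = fit(y, X)
        assert np.all(res.predict(round_to_int=True) == np.rint(res.predict()))


class TestMultiscale:
    def test_single_scale_consistent_with_direct_fit(self, bundle):
        from chipdecon.reads import deduplicate

        chip = deduplicate(bundle.read_sets["chip"])
        controls = {k: deduplicate(bundle.read_sets[k]) for k in ("dnase", "idna", "igg")}
        tracks = {"mappability": bundle.mappability, "gc": bundle.gc}
        direct = decompose_windows(chip, tracks, controls, bundle.sizes,
                                   width=129, exclude=())
        multi = multiscale_decompose(chip, tracks, controls, bundle.sizes,
                                     k_range=[7], exclude=())
        assert list(multi) == [129]
        np.testing.assert_allclose(multi[129].pov.values, direct.pov.values)

    def test_emitted_widths_are_powers_of_two_plus_one(self):
        sizes_tracks_reads = simulate_smooth_fixture(seed=5, length=50_000)
        sizes, tracks, rs = sizes_tracks_reads
        res = multiscale_decompose(rs["chip"], tracks,
                                   {k: rs[k] for k in ("dnase", "idna", "igg")},
                                   sizes, k_range=[3, 5, 7], exclude=())
        assert sorted(res) == [2**3 + 1, 2**5 + 1, 2**7 + 1]

    def test_width_exceeding_genome_raises(self):
        sizes, tracks, rs = simulate_smooth_fixture(seed=5, length=10_000)
        with pytest.raises(ValueError):
            multiscale_decompose(rs["chip"], tracks,
                                 {k: rs[k] for k in ("dnase", "idna", "igg")},
                                 sizes, k_range=[20], exclude=())

    def test_smooth_rate_predictability_improves_with_scale(self):
        sizes, tracks, rs = simulate_smooth_fixture(seed=2, length=300_000)
        res = multiscale_decompose(rs["chip"], tracks,
                                   {k: rs[k] for k in ("dnase", "idna", "igg")},
                                   sizes, k_range=range(3, 10), exclude=())
        totals = [res[2**k + 1].total_pov for k in range(3, 10)]
        assert np.all(np.diff(totals) > -2.0)
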