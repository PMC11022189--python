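"""Kennard-Stone partitioning, PLS calibration, metrics and baselines."""

import numpy as np
import pytest

import specfusion as sf
from specfusion.model import fit_bpnn_baseline, fit_svm_baseline

rng = np.random.default_rng(11)


def brute_force_ks_order(X):
    """Independent O(n^2)-per-step Kennard-Stone for cross-checking."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    best = (-1.0, None)
    for i in range(n):
        for j in range(i + 1, n):
            if D[i, j] > best[0]:
                best = (D[i, j], (i, j))
    order = list(best[1])
    while len(order) < n:
        cand, score = None, -1.0
        for i in range(n):
            if i in order:
                continue
            d = min(D[i, j] for j in order)
            if d > score:
                cand, score = i, d
        order.append(cand)
    return order


class TestKennardStone:
    @pytest.mark.parametrize("n,frac,n_cal,n_pred", [(63, 2 / 3, 42, 21),
                                                     (126, 4 / 5, 101, 25)])
    def test_printed_split_sizes(self, n, frac, n_cal, n_pred):
        X = rng.normal(size=(n, 5))
        s = sf.kennard_stone_split(X, frac)
        assert s.calibration_indices.size == n_cal
        assert s.prediction_indices.size == n_pred

    @pytest.mark.parametrize("n", [3, 10, 17, 63, 126, 200])
    def test_split_count_is_rounded_fraction(self, n):
        X = rng.normal(size=(n, 3))
        for frac in (0.5, 2 / 3, 0.8):
            n_cal = int(np.floor(frac * n + 0.5))
            if n_cal < 2 or n_cal >= n:
                continue
            s = sf.kennard_stone_split(X, frac)
            assert s.calibration_indices.size == n_cal
            assert s.calibration_indices.size + s.prediction_indices.size == n
            assert np.intersect1d(s.calibration_indices,
                                  s.prediction_indices).size == 0

    @pytest.mark.parametrize("n", [5, 12, 30, 50])
    def test_matches_brute_force_order(self, n):
        X = np.random.default_rng(n).normal(size=(n, 4))
        assert list(sf.kennard_stone_order(X)) == brute_force_ks_order(X)

    def test_collinear_points_seed_with_extremes(self):
        X = np.arange(10.0)[:, None]
        s = sf.kennard_stone_split(X, 0.5)
        assert {0, 9} <= set(s.calibration_indices)
        assert list(sf.kennard_stone_order(X)[:2]) == [0, 9]

    def test_degenerate_fraction_rejected(self):
        X = rng.normal(size=(10, 2))
        for frac in (0.05, 0.999):
            with pytest.raises(ValueError):
                sf.kennard_stone_split(X, frac)


class TestPLS:
    def test_full_rank_equals_least_squares(self):
        for n, p in [(15, 4), (30, 7)]:
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            res = sf.PLSCalibration(X, y, max_lv=p, cv_folds=5).fit(n_lv=p)
            A = np.column_stack([np.ones(n), X])
            beta = np.linalg.solve(A.T @ A, A.T @ y)  # normal-equations oracle
            assert np.allclose(res.predict(X), A @ beta, atol=1e-8)

    def test_exact_linear_recovery(self):
        X = rng.normal(size=(40, 3))  # three independent predictors
        y = X @ np.array([1.0, -2.0, 0.5])
        res = sf.fit_pls(X, y, max_lv=3, cv_folds=10)
        assert res.n_lv <= 3
        assert np.allclose(res.predict(X), y, atol=1e-8)

    def test_single_proportional_column(self):
        X = rng.normal(size=(20, 1))
        y = 3.0 * X[:, 0] + 1.0
        res = sf.PLSCalibration(X, y, max_lv=1, cv_folds=5).fit(n_lv=1)
        assert np.allclose(res.predict(X), y, atol=1e-10)

    def test_prediction_at_training_mean_is_y_mean(self):
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        res = sf.PLSCalibration(X, y, max_lv=3, cv_folds=5).fit(n_lv=2)
        assert np.isclose(res.predict(X.mean(axis=0)[None, :])[0], y.mean())

    def test_prediction_is_linear_in_x(self):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        res = sf.PLSCalibration(X, y, max_lv=3, cv_folds=5).fit(n_lv=2)
        xm = res.x_mean
        v = rng.normal(size=5)
        p1 = res.predict((xm + v)[None, :])[0] - res.y_mean
        p2 = res.predict((xm + 2 * v)[None, :])[0] - res.y_mean
        assert np.isclose(p2, 2 * p1)

    def test_dimension_mismatch_rejected(self):
        res = sf.fit_pls(rng.normal(size=(20, 5)), rng.normal(size=20),
                         max_lv=3, cv_folds=5)
        with pytest.raises(ValueError):
            res.predict(np.zeros((2, 4)))

    def test_matches_sklearn_pls(self):
        """Independent cross-check against sklearn's NIPALS PLS."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(30, 12))
        y = X @ rng.normal(size=12) + 0.1 * rng.normal(size=30)
        for n_lv in (1, 2, 4):
            mine = sf.PLSCalibration(X, y, max_lv=6, cv_folds=5).fit(n_lv=n_lv)
            ref = PLSRegression(n_components=n_lv, scale=False).fit(X, y)
            assert np.allclose(mine.predict(X), ref.predict(X).ravel(), atol=1e-6)

    def test_zero_variance_y_rejected(self):
        with pytest.raises(ValueError):
            sf.PLSCalibration(rng.normal(size=(20, 3)), np.ones(20), max_lv=2,
                              cv_folds=5)

    def test_infeasible_max_lv_rejected(self):
        with pytest.raises(ValueError, match=r"\["):
            sf.PLSCalibration(rng.normal(size=(10, 3)), rng.normal(size=10),
                              max_lv=9, cv_folds=5)

    def test_summary_mentions_latent_variables(self):
        res = sf.fit_pls(rng.normal(size=(20, 5)), rng.normal(size=20),
                         max_lv=3, cv_folds=5)
        assert "latent variables" in res.summary()

    def test_low_noise_fixture_calibration(self):
        """A 42-sample calibration on low-noise spectra predicts the held-out
        set with R^2 > 0.95."""
        cfg = sf.DesignConfig(seed=3, noise_sd_frac=0.001, scatter_sd=0.0,
                              baseline_jitter_frac=0.0, aliquot_rel_sd=0.0,
                              interference_sd=0.0, matrix_covariate_sd=0.0)
        study = sf.generate_dataset(cfg)
        s = study.nir[120]
        y = s.concentrations
        split = sf.kennard_stone_split(s.absorbance, 2 / 3)
        res = sf.fit_pls(s.absorbance[split.calibration_indices],
                         y[split.calibration_indices])
        report = sf.evaluate(y[split.prediction_indices],
                             res.predict(s.absorbance[split.prediction_indices]))
        assert report.r2 > 0.95


class TestEvaluate:
    def test_perfect_prediction(self):
        r = sf.evaluate([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert r.r2 == pytest.approx(1.0) and r.rmse == 0.0

    def test_shift_keeps_correlation_not_rmse(self):
        r = sf.evaluate([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
        assert r.r2 == pytest.approx(1.0) and r.rmse == pytest.approx(1.0)

    def test_rmse_arithmetic(self):
        r = sf.evaluate([0.0, 1.0, 2.0], [0.0, 1.0, 4.0])
        assert r.rmse == pytest.approx(np.sqrt(4.0 / 3.0))

    def test_r2_invariant_under_positive_affine_maps(self):
        y = rng.normal(size=30)
        pred = y + 0.3 * rng.normal(size=30)
        base = sf.evaluate(y, pred).r2
        assert sf.evaluate(y, 2.5 * pred + 7.0).r2 == pytest.approx(base)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            sf.evaluate([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_rmse_zero_iff_equal(self):
        y = rng.normal(size=10)
        assert sf.evaluate(y, y).rmse == 0.0
        assert sf.evaluate(y, y + 1e-6).rmse > 0.0


class TestBaselines:
    def test_svm_constant_target(self):
        X = rng.normal(size=(25, 4))
        model = fit_svm_baseline(X, np.full(25, 3.0))
        assert np.allclose(model.predict(X), 3.0, atol=0.2)  # epsilon-tube

    def test_svm_smoke_on_fixture(self, study):
        s = study.nir[120]
        model = fit_svm_baseline(s.absorbance, s.concentrations)
        pred = model.predict(s.absorbance)
        assert np.all(np.isfinite(pred))

    def test_bpnn_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            fit_bpnn_baseline(rng.normal(size=(20, 3)), rng.normal(size=20))

    def test_bpnn_deterministic_refit(self):
        X = rng.normal(size=(30, 4))
        y = X @ np.array([1.0, -0.5, 0.2, 0.0])
        m1 = fit_bpnn_baseline(X, y, seed=5, max_iter=200)
        m2 = fit_bpnn_baseline(X, y, seed=5, max_iter=200)
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_bpnn_fits_linear_target(self):
        X = rng.normal(size=(60, 3))
        y = X @ np.array([1.0, 2.0, -1.0])
        model = fit_bpnn_baseline(X, y, seed=0, max_iter=4000)
        rmse = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rmse < 0.5 * y.std()
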