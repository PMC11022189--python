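"""Fusion strategies: concatenation, entropy-weighted TOPSIS, MLR combiner."""

import numpy as np
import pytest

import specfusion as sf
from specfusion.spectra import SpectraValidationError

from conftest import make_set

rng = np.random.default_rng(33)


def modality_pair(n=3, p_nir=4, p_mir=5):
    concs = np.linspace(1.0, 5.0, n)
    nir = make_set(rng.normal(size=(n, p_nir)), concs=concs, reps=[1] * n)
    mir = make_set(rng.normal(size=(n, p_mir)), concs=concs, reps=[1] * n,
                   modality="MIR", unit="cm-1",
                   axis=np.arange(4000.0, 4000.0 - 4 * p_mir, -4.0))
    return nir, mir


class TestFullSpectrumFusion:
    def test_block_dimensions(self):
        nir, mir = modality_pair()
        norms = (sf.range_normalize_fit(nir), sf.range_normalize_fit(mir))
        fused = sf.fuse_full_spectrum(nir, mir, norms)
        assert fused.shape == (3, 9)

    def test_normalization_is_mandatory(self):
        nir, mir = modality_pair()
        with pytest.raises(ValueError, match="normaliz"):
            sf.fuse_full_spectrum(nir, mir, None)

    def test_fixture_grids_concatenate_to_1722_columns(self, study):
        nir, mir = sf.align_by_meta(study.nir[120], study.mir)
        norms = (sf.range_normalize_fit(nir), sf.range_normalize_fit(mir))
        fused = sf.fuse_full_spectrum(nir, mir, norms)
        assert fused.shape[1] == 821 + 901 == 1722

    def test_misaligned_samples_rejected(self):
        nir, mir = modality_pair()
        shuffled = mir.take([2, 0, 1])
        with pytest.raises(SpectraValidationError):
            sf.fuse_full_spectrum(nir, shuffled,
                                  (sf.range_normalize_fit(nir),
                                   sf.range_normalize_fit(mir)))


class TestFeatureLevelFusion:
    def test_selected_column_counts_concatenate(self):
        nir, mir = modality_pair(n=4, p_nir=30, p_mir=30)
        f_nir = sf.FeatureIndexSet("NIR", np.arange(10), "UVE_SPA")
        f_mir = sf.FeatureIndexSet("MIR", np.arange(8), "UVE_SPA")
        fused = sf.fuse_feature_level(nir, mir, f_nir, f_mir)
        assert fused.shape == (4, 18)  # 10 NIR + 8 MIR
        assert np.array_equal(fused[:, :10], nir.absorbance[:, :10])

    def test_duplicate_columns_across_modalities_kept(self):
        nir, mir = modality_pair(p_nir=5, p_mir=5)
        mir = mir.with_absorbance(nir.absorbance.copy())
        f = sf.FeatureIndexSet("NIR", np.array([1, 3]), "SPA")
        fused = sf.fuse_feature_level(nir, mir, f, f)
        assert fused.shape[1] == 4
        assert np.array_equal(fused[:, :2], fused[:, 2:])

    def test_empty_selection_impossible(self):
        with pytest.raises(Exception):
            sf.FeatureIndexSet("NIR", np.array([], dtype=int), "SPA")

    def test_out_of_bounds_indices_rejected(self):
        nir, mir = modality_pair()
        f_nir = sf.FeatureIndexSet("NIR", np.array([99]), "SPA")
        f_mir = sf.FeatureIndexSet("MIR", np.array([0]), "SPA")
        with pytest.raises(ValueError):
            sf.fuse_feature_level(nir, mir, f_nir, f_mir)


class TestEntropyTopsis:
    def test_identical_models_get_equal_weights(self):
        c = sf.CriteriaMatrix(np.array([[0.9, 0.5], [0.9, 0.5]]), (True, False))
        with pytest.warns(UserWarning):
            w = sf.entropy_topsis_weights(c)
        assert w.n == w.m == 0.5

    def test_dominant_model_gets_majority_weight(self):
        c = sf.CriteriaMatrix(np.array([[0.95, 0.2], [0.80, 0.9]]), (True, False))
        w = sf.entropy_topsis_weights(c)
        assert w.n > 0.5 > w.m

    def test_weights_always_normalized_and_nonnegative(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            c = sf.CriteriaMatrix(r.uniform(0.1, 1.0, (2, 2)), (True, False))
            w = sf.entropy_topsis_weights(c)
            assert w.n >= 0 and w.m >= 0
            assert w.n + w.m == pytest.approx(1.0, abs=1e-12)

    def test_weight_type_enforces_sum(self):
        with pytest.raises(ValueError):
            sf.TopsisWeights(0.6, 0.6)


class TestCombiners:
    def test_convex_combination_stays_within_inputs(self):
        p = sf.PredictionSet(y_nir=rng.normal(size=10), y_mir=rng.normal(size=10))
        out = sf.combine_topsis(p, sf.TopsisWeights(0.4073, 0.5927))
        assert np.all(out <= np.maximum(p.y_nir, p.y_mir) + 1e-12)
        assert np.all(out >= np.minimum(p.y_nir, p.y_mir) - 1e-12)

    def test_agreeing_predictions_pass_through(self):
        v = np.array([10.0, 10.0])
        p = sf.PredictionSet(y_nir=v, y_mir=v)
        out = sf.combine_topsis(p, sf.TopsisWeights(0.4073, 0.5927))
        assert np.allclose(out, 10.0)

    def test_equal_weight_arithmetic(self):
        p = sf.PredictionSet(y_nir=np.array([4.0]), y_mir=np.array([6.0]))
        assert sf.combine_topsis(p, sf.TopsisWeights(0.5, 0.5))[0] == 5.0

    def test_mlr_exact_recovery(self):
        y_nir, y_mir = rng.normal(size=(2, 20))
        p = sf.PredictionSet(y_nir=y_nir, y_mir=y_mir,
                             y_true=0.5 * y_nir + 0.5 * y_mir)
        c = sf.fit_mlr_combiner(p)
        assert (c.b, c.k1, c.k2) == pytest.approx((0.0, 0.5, 0.5), abs=1e-10)

    def test_mlr_matches_normal_equations_oracle(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            y_nir, y_mir, y = r.normal(size=(3, 15))
            p = sf.PredictionSet(y_nir=y_nir, y_mir=y_mir, y_true=y)
            c = sf.fit_mlr_combiner(p)
            A = np.column_stack([np.ones(15), y_nir, y_mir])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            assert np.allclose([c.b, c.k1, c.k2], beta, atol=1e-9)

    def test_collinear_predictions_warn(self):
        v = rng.normal(size=10)
        p = sf.PredictionSet(y_nir=v, y_mir=v, y_true=v)
        with pytest.warns(UserWarning, match="collinear"):
            c = sf.fit_mlr_combiner(p)
        assert np.isfinite([c.b, c.k1, c.k2]).all()

    def test_published_coefficient_instance(self):
        """The printed decision-fusion coefficients on agreeing predictions."""
        c = sf.MLRCombiner(b=-0.0013, k1=0.3566, k2=0.6058)
        p = sf.PredictionSet(y_nir=np.array([10.0]), y_mir=np.array([10.0]))
        assert sf.combine_mlr(p, c)[0] == pytest.approx(9.6227)

    def test_identity_and_zero_combiners(self):
        p = sf.PredictionSet(y_nir=np.array([1.0, 2.0]), y_mir=np.array([5.0, 6.0]))
        assert np.array_equal(sf.combine_mlr(p, sf.MLRCombiner(0.0, 1.0, 0.0)),
                              p.y_nir)
        assert np.array_equal(sf.combine_mlr(p, sf.MLRCombiner(0.0, 0.0, 0.0)),
                              [0.0, 0.0])

    def test_underdetermined_fit_rejected(self):
        p = sf.PredictionSet(y_nir=np.array([1.0, 2.0]), y_mir=np.array([2.0, 1.0]),
                             y_true=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            sf.fit_mlr_combiner(p)

    def test_decision_fusion_never_much_worse_than_worst_model(self):
        """With unbiased modality models, weighted fusion cannot exceed the
        worse single model's RMSE (sanity bound, many random draws)."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            y = r.uniform(0.5, 20.0, 40)
            p = sf.PredictionSet(y_nir=y + r.normal(0, 1.0, 40),
                                 y_mir=y + r.normal(0, 1.5, 40), y_true=y)
            w = sf.TopsisWeights(0.5, 0.5)
            fused_rmse = np.sqrt(np.mean((sf.combine_topsis(p, w) - y) ** 2))
            worst = max(np.sqrt(np.mean((p.y_nir - y) ** 2)),
                        np.sqrt(np.mean((p.y_mir - y) ** 2)))
            assert fused_rmse <= worst + 1e-9
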