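"""Piecewise direct standardization: local fits, identity/affine recovery,
locality, standard-sample selection and the window x standards grid search."""

import numpy as np
import pytest

import specfusion as sf
from specfusion.spectra import SpectraValidationError

from conftest import make_set

rng = np.random.default_rng(55)


def paired_sets(n=10, p=60, distort=None, seed=0):
    r = np.random.default_rng(seed)
    base = r.normal(size=(n, p)) + 5.0
    concs = np.linspace(1.0, 20.0, n)
    master = make_set(base, concs=concs, reps=[1] * n)
    slave_block = base if distort is None else distort(base)
    slave = make_set(slave_block, concs=concs, reps=[1] * n)
    return master, slave


class TestWindowSpec:
    def test_symmetric_construction(self):
        w = sf.WindowSpec.symmetric(9)
        assert (w.j, w.k, w.width) == (4, 4, 9)

    @pytest.mark.parametrize("width", [0, 2, 4])
    def test_even_or_zero_width_rejected(self, width):
        with pytest.raises(ValueError):
            sf.WindowSpec.symmetric(width)

    def test_asymmetric_windows_allowed(self):
        assert sf.WindowSpec(1, 3).width == 5


class TestStandardSelection:
    def test_all_samples(self):
        master, _ = paired_sets()
        assert sf.select_standard_samples(master, 10).size == 10

    def test_two_standards_are_farthest_pair(self):
        master, _ = paired_sets(seed=4)
        idx = sf.select_standard_samples(master, 2)
        X = master.absorbance
        d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        i, j = np.unravel_index(np.argmax(d), d.shape)
        assert set(idx) == {i, j}

    def test_line_of_points_spreads_evenly(self):
        block = np.linspace(0.0, 16.0, 17)[:, None] * np.ones((1, 5))
        master = make_set(block, concs=np.linspace(1, 17, 17), reps=[1] * 17)
        idx = sf.select_standard_samples(master, 4)
        assert {0, 16} <= set(idx)  # endpoints first
        interior = set(idx) - {0, 16}
        assert 8 in interior  # midpoint third
        assert interior - {8} <= {4, 12}  # then a quartile point

    def test_out_of_range_rejected(self):
        master, _ = paired_sets()
        for n_std in (0, 11):
            with pytest.raises(ValueError):
                sf.select_standard_samples(master, n_std)


class TestPDSFit:
    def test_identity_transfer(self):
        master, slave = paired_sets()
        t = sf.fit_pds(master, slave, 3, n_lv_local=None)
        fresh = make_set(rng.normal(size=(5, 60)) + 5.0)
        out = t.transform(fresh)
        assert np.abs(out.absorbance - fresh.absorbance).max() <= 1e-8
        assert out.axis == master.axis

    @pytest.mark.parametrize("width", [1, 3, 7])
    def test_global_affine_distortion_removed(self, width):
        master, slave = paired_sets(distort=lambda b: 0.7 * b - 2.0, seed=2)
        t = sf.fit_pds(master, slave, width, n_lv_local=None)
        fresh_master = rng.normal(size=(4, 60)) + 5.0
        fresh_slave = make_set(0.7 * fresh_master - 2.0)
        out = t.transform(fresh_slave)
        assert np.abs(out.absorbance - fresh_master).max() <= 1e-6

    def test_blur_distortion_needs_window(self):
        # a diagonally dominant blur has a decaying inverse, so a 5-point
        # window can deconvolve it; an extreme [1,2,1]/4 blur would not
        kernel = np.array([0.15, 0.7, 0.15])

        def blur(b):
            out = b.copy()
            out[:, 1:-1] = (b[:, :-2] * kernel[0] + b[:, 1:-1] * kernel[1]
                            + b[:, 2:] * kernel[2])
            return out

        master, slave = paired_sets(n=14, distort=blur, seed=6)
        t = sf.fit_pds(master, slave, 5, n_lv_local=None)
        fresh_master = rng.normal(size=(5, 60)) + 5.0
        fresh_slave = make_set(blur(fresh_master))
        transferred = t.transform(fresh_slave).absorbance
        resid = np.sqrt(np.mean((transferred[:, 2:-2] - fresh_master[:, 2:-2]) ** 2))
        no_transfer = np.sqrt(np.mean((fresh_slave.absorbance[:, 2:-2]
                                       - fresh_master[:, 2:-2]) ** 2))
        assert resid < 0.2 * no_transfer

    def test_locality_of_coefficients(self):
        """Perturbing slave data outside [i-j, i+k] leaves F_i unchanged."""
        master, slave = paired_sets(seed=8)
        t1 = sf.fit_pds(master, slave, 3, n_lv_local=2)
        tampered = slave.absorbance.copy()
        tampered[:, 30:] += rng.normal(size=(10, 30))  # far from wavelength 10
        t2 = sf.fit_pds(master, make_set(tampered, concs=np.linspace(1, 20, 10),
                                         reps=[1] * 10), 3, n_lv_local=2)
        assert np.allclose(t1.coefficients[10], t2.coefficients[10])
        assert np.isclose(t1.intercepts[10], t2.intercepts[10])
        assert not np.allclose(t1.coefficients[40], t2.coefficients[40])

    def test_batched_interior_matches_scalar_path(self):
        from specfusion.model import _nipals_pls1, _pls_coefficients

        master, slave = paired_sets(n=9, seed=3,
                                    distort=lambda b: 1.1 * b + 0.3)
        t = sf.fit_pds(master, slave, 5, n_lv_local=2)
        for i in (0, 1, 2, 29, 58, 59):  # edges and interior
            lo, hi = max(i - 2, 0), min(i + 3, 60)
            Xw = slave.absorbance[:, lo:hi]
            yw = master.absorbance[:, i]
            W, P, q, _ = _nipals_pls1(Xw - Xw.mean(0), yw - yw.mean(),
                                      min(2, hi - lo))
            f = _pls_coefficients(W, P, q)
            assert np.allclose(t.coefficients[i], f, atol=1e-9)

    def test_paired_standards_required(self):
        master, slave = paired_sets()
        with pytest.raises(SpectraValidationError):
            sf.PDSTransfer(master, slave.take(range(5)), 3)

    def test_single_standard_rejected(self):
        master, slave = paired_sets()
        with pytest.raises(ValueError, match="n_std"):
            sf.PDSTransfer(master.take([0]), slave.take([0]), 3)

    def test_window_wider_than_axis_rejected(self):
        master, slave = paired_sets(p=10)
        with pytest.raises(ValueError):
            sf.PDSTransfer(master, slave, 21)

    def test_axis_mismatch_on_apply(self):
        master, slave = paired_sets()
        t = sf.fit_pds(master, slave, 3)
        with pytest.raises(SpectraValidationError):
            t.transform(make_set(rng.normal(size=(2, 30))))

    def test_metadata_passes_through(self):
        master, slave = paired_sets()
        t = sf.fit_pds(master, slave, 3)
        out = t.transform(slave)
        assert out.meta == slave.meta

    def test_summary_reports_geometry(self):
        master, slave = paired_sets()
        t = sf.fit_pds(master, slave, 5)
        assert "window" in t.summary()


class TestOptimizePDS:
    def test_grid_shape_and_infeasible_cells(self):
        master, slave = paired_sets(n=20)
        y = master.concentrations

        def downstream(transferred, y_val):
            return float(np.mean(np.abs(transferred.absorbance)))

        res = sf.optimize_pds(master, slave, y, downstream)
        assert len(res.grid) == 5 * 17
        assert np.isnan(res.grid[(3, 1)])  # centering needs >= 2 standards

    def test_degenerate_surface_tie_break(self):
        master, slave = paired_sets(n=20, seed=9)  # slave == master
        y = master.concentrations

        def downstream(transferred, y_val):
            return 1.0  # flat surface: only the tie-break decides

        res = sf.optimize_pds(master, slave, y, downstream)
        assert res.best == (3, 2)  # fewest standards, narrowest window

    def test_distorted_fixture_transfer_beats_no_transfer(self, study):
        nir120, _ = sf.align_by_meta(study.nir[120], study.mir)
        slave, _ = sf.align_by_meta(study.nir[80], nir120)
        y = nir120.concentrations
        split = sf.kennard_stone_split(nir120.absorbance, 2 / 3)
        cal, pred = split.calibration_indices, split.prediction_indices
        model = sf.fit_pls(nir120.take(cal).absorbance, y[cal])

        def downstream(transferred, y_val):
            resid = y_val - model.predict(transferred.absorbance)
            return float(np.sqrt(np.mean(resid**2)))

        res = sf.optimize_pds(nir120.take(cal), slave.take(cal), y[cal],
                              downstream, n_std_range=range(2, 18, 3))
        width, n_std = res.best
        idx = sf.select_standard_samples(nir120.take(cal), n_std)
        t = sf.PDSTransfer(nir120.take(cal).take(idx), slave.take(cal).take(idx),
                           sf.WindowSpec.symmetric(width), 2).fit()
        rmse_tr = np.sqrt(np.mean(
            (y[pred] - model.predict(t.transform(slave.take(pred)).absorbance)) ** 2))
        rmse_un = np.sqrt(np.mean(
            (y[pred] - model.predict(slave.take(pred).absorbance)) ** 2))
        assert rmse_tr < rmse_un
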