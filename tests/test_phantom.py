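"""Phantom generator: geometry, forward models, noise, determinism."""

import numpy as np
import pytest

from mparamap import dti, phantom, relaxometry
from mparamap.phantom import PhantomSpec, RegionSpec


def disc(label="tumor", center=(16, 16), radius=5.0, **kw):
    return RegionSpec(label=label, center_px=center, radius_px=radius, **kw)


class TestMakePhantom:
    def test_tumor_pixels_carry_region_t2(self):
        spec = PhantomSpec(grid_shape=(32, 32), n_slices=3,
                           regions=[disc(radius=10.0, t2_ms=66.52)])
        gt = phantom.make_phantom(spec)
        tumor = gt.region_mask("tumor")
        assert np.all(gt.maps["t2_ms"].values[tumor] == 66.52)
        assert np.all(np.isnan(gt.maps["t2_ms"].values[~tumor]))

    def test_zero_regions_gives_all_background(self):
        gt = phantom.make_phantom(PhantomSpec(grid_shape=(16, 16), n_slices=2))
        assert not gt.mask.any()
        assert gt.rois.names == []
        assert np.all(np.isnan(gt.maps["t1_ms"].values))

    def test_isotropic_region_tensor_is_md_times_identity(self):
        spec = PhantomSpec(grid_shape=(32, 32),
                           regions=[disc(fa=0.0, md_um2s=800.0)])
        gt = phantom.make_phantom(spec)
        idx = np.argwhere(gt.mask)[0]
        D = gt.tensor_mm2s[tuple(idx)]
        np.testing.assert_allclose(D, 800e-6 * np.eye(3), atol=1e-15)

    def test_overlapping_regions_error_names_labels(self):
        spec = PhantomSpec(grid_shape=(32, 32), regions=[
            disc("a", (16, 14), 5.0), disc("b", (16, 18), 5.0)])
        with pytest.raises(ValueError, match="'a' and 'b' overlap"):
            phantom.make_phantom(spec)

    def test_region_outside_grid_errors(self):
        spec = PhantomSpec(grid_shape=(16, 16), regions=[disc(center=(14, 14), radius=5.0)])
        with pytest.raises(ValueError, match="outside the grid"):
            phantom.make_phantom(spec)

    def test_default_region_masks_are_disjoint_and_inside(self, gbm_truth):
        tumor = gbm_truth.region_mask("tumor")
        contra = gbm_truth.region_mask("contralateral")
        assert not np.any(tumor & contra)
        assert tumor.sum() == contra.sum()  # mirrored equal-size discs


class TestDecaySimulators:
    def test_mse_signal_matches_closed_form(self):
        spec = PhantomSpec(grid_shape=(16, 16), regions=[disc(center=(8, 8), radius=4.0, t2_ms=66.52, s0=1000.0)])
        gt = phantom.make_phantom(spec)
        series = phantom.simulate_mse(gt, te_list=[12.0])
        expected = 1000.0 * np.exp(-12.0 / 66.52)  # 834.94
        assert abs(expected - 834.94) < 0.01
        tumor = gt.region_mask("tumor")
        np.testing.assert_allclose(series.data[tumor, 0], expected, rtol=1e-12)

    def test_te_to_zero_limit_approaches_s0(self, small_truth):
        series = phantom.simulate_mse(small_truth, te_list=[1e-9, 12.0])
        tumor = small_truth.region_mask("tumor")
        np.testing.assert_allclose(series.data[tumor, 0], 1000.0, rtol=1e-9)

    def test_mge_at_te_equal_t2star_gives_1_over_e(self):
        spec = PhantomSpec(grid_shape=(16, 16), regions=[disc(center=(8, 8), radius=4.0, t2star_ms=22.75, s0=100.0)])
        gt = phantom.make_phantom(spec)
        series = phantom.simulate_mge(gt, te_list=[22.75])
        tumor = gt.region_mask("tumor")
        np.testing.assert_allclose(series.data[tumor, 0], 100.0 * np.exp(-1.0), rtol=1e-12)

    def test_default_mge_grid_spacing(self):
        te = phantom.DEFAULT_MGE_TE_MS
        assert te.size == 20
        np.testing.assert_allclose(np.diff(te), (83.86 - 2.73) / 19, atol=5e-3)

    def test_empty_te_list_errors(self, small_truth):
        with pytest.raises(ValueError, match="empty"):
            phantom.simulate_mse(small_truth, te_list=[])
        with pytest.raises(ValueError):
            phantom.simulate_satrec(small_truth, tr_list=[])

    def test_background_is_zero(self, small_truth):
        series = phantom.simulate_mse(small_truth)
        assert np.all(series.data[~small_truth.mask, :] == 0)


class TestSatRec:
    def test_tr_equal_t1_gives_saturation_fraction(self):
        spec = PhantomSpec(grid_shape=(16, 16), regions=[disc(center=(8, 8), radius=4.0, t1_ms=2574.0, s0=1.0)])
        gt = phantom.make_phantom(spec)
        series = phantom.simulate_satrec(gt, tr_list=[2574.0])
        tumor = gt.region_mask("tumor")
        np.testing.assert_allclose(series.data[tumor, 0], 1.0 - np.exp(-1.0), rtol=1e-12)

    def test_long_tr_approaches_s0(self, small_truth):
        series = phantom.simulate_satrec(small_truth, tr_list=[1e7])
        tumor = small_truth.region_mask("tumor")
        np.testing.assert_allclose(series.data[tumor, 0], 1000.0, rtol=1e-9)


class TestMtPair:
    def test_on_image_applies_transfer_fraction(self):
        spec = PhantomSpec(grid_shape=(16, 16), regions=[disc(center=(8, 8), radius=4.0, mtr_percent=15.15, s0=100.0)])
        gt = phantom.make_phantom(spec)
        off, on = phantom.simulate_mt_pair(gt)
        tumor = gt.region_mask("tumor")
        np.testing.assert_allclose(on.data[tumor, 0], 84.85, rtol=1e-12)
        np.testing.assert_allclose(off.data[tumor, 0], 100.0)

    def test_zero_mtr_means_on_equals_off(self):
        spec = PhantomSpec(grid_shape=(16, 16), regions=[disc(center=(8, 8), radius=4.0, mtr_percent=0.0)])
        gt = phantom.make_phantom(spec)
        off, on = phantom.simulate_mt_pair(gt)
        np.testing.assert_array_equal(on.data, off.data)


class TestDwiSimulator:
    def test_isotropic_signal_is_direction_independent(self):
        spec = PhantomSpec(grid_shape=(16, 16), regions=[disc(center=(8, 8), radius=4.0, fa=0.0, md_um2s=800.0, s0=1.0)])
        gt = phantom.make_phantom(spec)
        scheme = dti.default_scheme()
        series = phantom.simulate_dwi(gt, scheme)
        tumor = gt.region_mask("tumor")
        px = series.data[tumor][0]
        for b in (300.0, 1400.0):
            rows = scheme.bvals == b
            np.testing.assert_allclose(px[rows], np.exp(-b * 800e-6), rtol=1e-12)

    def test_attenuation_along_principal_axis(self):
        # eigenvalues (2, 1, 1)e-3 mm^2/s -> MD = 4/3e-3, FA = 1/sqrt(6)
        md = (4.0 / 3.0) * 1e3  # um^2/s
        fa = 1.0 / np.sqrt(6.0)
        spec = PhantomSpec(grid_shape=(16, 16), regions=[
            disc(center=(8, 8), radius=4.0, md_um2s=md, fa=fa, principal_axis=(1, 0, 0), s0=1.0)])
        gt = phantom.make_phantom(spec)
        idx = tuple(np.argwhere(gt.mask)[0])
        D = gt.tensor_mm2s[idx]
        g = np.array([1.0, 0.0, 0.0])
        s_ratio = np.exp(-1400.0 * g @ D @ g)
        np.testing.assert_allclose(s_ratio, np.exp(-2.8), atol=1e-4)

    def test_nonunit_direction_rejected(self):
        b = np.array([0.0, 300.0] + [300.0] * 6)
        g = np.vstack([[0, 0, 0], [2.0, 0, 0], dti._DEFAULT_DIRECTIONS[1:]])
        with pytest.raises(ValueError, match="unit"):
            dti.DiffusionScheme(b, g)


class TestRicianNoise:
    def test_sigma_zero_is_identity(self, small_truth):
        series = phantom.simulate_mse(small_truth)
        out = phantom.add_rician_noise(series, 0.0, seed=1)
        np.testing.assert_array_equal(out.data, series.data)

    def test_negative_sigma_errors(self, small_truth):
        series = phantom.simulate_mse(small_truth)
        with pytest.raises(ValueError):
            phantom.add_rician_noise(series, -1.0, seed=1)

    def test_zero_signal_mean_is_rayleigh(self):
        from mparamap.core import AcquisitionSeries
        data = np.zeros((100, 100, 10, 1))
        series = AcquisitionSeries(data, [1.0], "mt")
        noisy = phantom.add_rician_noise(series, 1.0, seed=7)
        assert abs(noisy.data.mean() - np.sqrt(np.pi / 2)) < 0.02 * np.sqrt(np.pi / 2)

    def test_high_snr_mean_matches_rician_expansion(self):
        from mparamap.core import AcquisitionSeries
        s, sigma = 50.0, 1.0
        data = np.full((100, 100, 10, 1), s)
        series = AcquisitionSeries(data, [1.0], "mt")
        noisy = phantom.add_rician_noise(series, sigma, seed=8)
        expected = s + sigma ** 2 / (2 * s)
        assert abs(noisy.data.mean() - expected) < 0.01 * expected

    def test_same_seed_identical_arrays(self, small_truth):
        series = phantom.simulate_mse(small_truth)
        a = phantom.add_rician_noise(series, 5.0, seed=3)
        b = phantom.add_rician_noise(series, 5.0, seed=3)
        np.testing.assert_array_equal(a.data, b.data)


class TestDeterminismAndRoundTrip:
    def test_seeded_phantom_is_bit_reproducible(self):
        spec = lambda: phantom.default_phantom_spec(noise_sigma=10.0, seed=42,
                                                    grid_shape=(24, 24), n_slices=2, radius_px=4.0)
        a = phantom.simulate_mse(phantom.make_phantom(spec()))
        b = phantom.simulate_mse(phantom.make_phantom(spec()))
        np.testing.assert_array_equal(a.data, b.data)

    def test_noiseless_mse_round_trip_recovers_t2(self, small_truth):
        series = phantom.simulate_mse(small_truth)
        pmap = relaxometry.fit_map(series, "mse", small_truth.mask)
        truth = small_truth.maps["t2_ms"].values[small_truth.mask]
        np.testing.assert_allclose(pmap.values[small_truth.mask], truth, rtol=1e-6)

    def test_noiseless_satrec_round_trip_recovers_t1(self, small_truth):
        series = phantom.simulate_satrec(small_truth)
        pmap = relaxometry.fit_map(series, "satrec", small_truth.mask)
        truth = small_truth.maps["t1_ms"].values[small_truth.mask]
        np.testing.assert_allclose(pmap.values[small_truth.mask], truth, rtol=1e-6)


class TestRegionSpecValidation:
    @pytest.mark.parametrize("kw", [
        dict(t2_ms=-1.0), dict(fa=1.0), dict(fa=-0.1), dict(mtr_percent=101.0),
        dict(md_um2s=0.0), dict(radius=0.0),
        dict(metabolite_ratios={"NAA": -0.1}),
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            disc(**kw)

    def test_study_region_values_are_consistent(self):
        ref = phantom.c6_study_regions()
        assert ref["gbm_tumor"]["t2_ms"] == 66.52
        assert ref["gbm_contralateral"]["mtr_percent"] == 30.56
        sems = phantom.c6_study_sems()
        assert set(sems) == set(ref)
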