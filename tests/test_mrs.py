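"""Basis synthesis and linear-combination spectral fitting."""

import itertools

import numpy as np
import pytest

from mparamap import mrs, phantom
from mparamap.mrs import (
    build_basis,
    default_basis,
    fit_spectrum,
    ratios_table,
    simulate_spectrum,
)

TUMOR_RATIOS = phantom.c6_study_regions()["gbm_tumor"]["metabolite_ratios"]


class TestBuildBasis:
    def test_singlet_peak_position(self, basis):
        naa = basis.column("NAA")
        peak_ppm = basis.ppm[np.argmax(naa)]
        grid_step = basis.ppm[1] - basis.ppm[0]
        assert abs(peak_ppm - 2.01) <= grid_step

    def test_unit_integrated_area(self, basis):
        for name in basis.names:
            area = np.trapezoid(basis.column(name), basis.ppm)
            assert area == pytest.approx(1.0, abs=1e-6)

    def test_empty_config_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_basis({})

    def test_negative_width_errors(self):
        with pytest.raises(ValueError):
            build_basis({"X": [(2.0, 1.0, -1.0)], "Cr": [(3.0, 1.0, 1.0)], "PCr": [(3.1, 1.0, 1.0)]})

    def test_basis_requires_creatine_entries(self):
        with pytest.raises(ValueError, match="Cr"):
            build_basis({"NAA": [(2.01, 1.0, 1.5)]})


class TestSimulateSpectrum:
    def test_unknown_metabolite_errors(self, basis):
        with pytest.raises(ValueError, match="Foo"):
            simulate_spectrum({"Foo": 1.0}, basis)

    def test_zero_ratios_leave_only_creatine(self, basis):
        spec = simulate_spectrum({}, basis)
        creatine = 0.5 * basis.column("Cr") + 0.5 * basis.column("PCr")
        np.testing.assert_allclose(spec.intensity, creatine, atol=1e-12)

    def test_linearity_in_coefficients(self, basis):
        s1 = simulate_spectrum(TUMOR_RATIOS, basis, pcr_fraction=0.5)
        doubled = {k: 2 * v for k, v in TUMOR_RATIOS.items()}
        doubled.update({"Cr": 1.0, "PCr": 1.0})
        s2 = simulate_spectrum(doubled, basis)
        np.testing.assert_allclose(s2.intensity, 2 * s1.intensity, rtol=1e-12)


class TestFitSpectrum:
    def test_tumor_profile_round_trip(self, basis):
        spec = simulate_spectrum(TUMOR_RATIOS, basis)
        fit = fit_spectrum(spec, basis, baseline_order=0)
        assert fit.valid
        assert fit.ratio("NAA") == pytest.approx(0.70, abs=1e-3)
        assert fit.ratio("mI") == pytest.approx(0.77, abs=1e-3)
        assert fit.ratio("Ala") == pytest.approx(0.25, abs=1e-3)
        assert fit.choline_pool_ratio() == pytest.approx(0.32, abs=1e-2)

    def test_zero_spectrum_is_invalid(self, basis):
        spec = mrs.Spectrum(basis.ppm, np.zeros_like(basis.ppm))
        fit = fit_spectrum(spec, basis, baseline_order=0)
        assert not fit.valid
        np.testing.assert_allclose(fit.coefficients, 0.0, atol=1e-10)

    def test_exact_recovery_of_in_basis_combinations(self, basis, rng):
        for _ in range(5):
            coeffs = {n: float(rng.uniform(0, 2)) for n in basis.names}
            y = sum(c * basis.column(n) for n, c in coeffs.items())
            fit = fit_spectrum(mrs.Spectrum(basis.ppm, y), basis, baseline_order=0)
            assert fit.residual_norm < 1e-8 * np.linalg.norm(y)

    def test_ratio_scale_invariance(self, basis):
        spec = simulate_spectrum(TUMOR_RATIOS, basis)
        fit1 = fit_spectrum(spec, basis, baseline_order=0)
        scaled = mrs.Spectrum(basis.ppm, 37.5 * spec.intensity)
        fit2 = fit_spectrum(scaled, basis, baseline_order=0)
        for name in ("NAA", "mI", "Ala"):
            assert abs(fit2.ratio(name) - fit1.ratio(name)) < 1e-9
        np.testing.assert_allclose(fit2.coefficients, 37.5 * fit1.coefficients, rtol=1e-6)

    def test_grid_mismatch_errors(self, basis):
        spec = mrs.Spectrum(basis.ppm[:-1], np.zeros(basis.ppm.size - 1))
        with pytest.raises(ValueError, match="grid"):
            fit_spectrum(spec, basis)

    def test_percent_sd_nonincreasing_in_snr(self, basis):
        # same noise realization pattern, decreasing sigma -> %SD shrinks
        sds = []
        for sigma in (4.0, 1.0, 0.25):
            spec = simulate_spectrum(TUMOR_RATIOS, basis, noise_sigma=sigma, seed=5)
            fit = fit_spectrum(spec, basis, baseline_order=0)
            sds.append(fit.percent_sd[basis.names.index("NAA")])
        assert sds[0] > sds[1] > sds[2]

    def test_monte_carlo_recovery_and_sd_filter(self, basis):
        # 50 noisy spectra: NAA ratio unbiased to 2 %, and a metabolite
        # simulated at zero concentration is excluded by the 20 % SD filter
        ratios = dict(TUMOR_RATIOS, Ala=0.0)
        naa, excluded = [], 0
        for seed in range(50):
            spec = simulate_spectrum(ratios, basis, noise_sigma=1.0, seed=3000 + seed)
            fit = fit_spectrum(spec, basis, baseline_order=0)
            naa.append(fit.ratio("NAA"))
            excluded += not fit.included[basis.names.index("Ala")]
        assert abs(np.mean(naa) - 0.70) / 0.70 < 0.02
        assert excluded >= 45

    def test_nnls_matches_active_set_brute_force(self, rng):
        # toy 4-metabolite bases: enumerate all active sets, solve the
        # unconstrained LS on each, keep feasible solutions, take best
        toy = build_basis({
            "A": [(1.0, 1.0, 8.0)], "B": [(1.2, 1.0, 8.0)],
            "Cr": [(3.0, 1.0, 8.0)], "PCr": [(3.2, 1.0, 8.0)],
        }, ppm_range=(0.5, 4.0), n_points=256)
        B = toy.spectra
        for trial in range(10):
            true_c = np.where(rng.uniform(size=4) < 0.5, 0.0, rng.uniform(0.2, 2.0, 4))
            y = B @ true_c + rng.normal(0, 0.05, B.shape[0])
            fit = fit_spectrum(mrs.Spectrum(toy.ppm, y), toy, baseline_order=-1)
            best, best_rss = None, np.inf
            for k in range(5):
                for active in itertools.combinations(range(4), k):
                    c = np.zeros(4)
                    if active:
                        sol, *_ = np.linalg.lstsq(B[:, list(active)], y, rcond=None)
                        if np.any(sol < 0):
                            continue
                        c[list(active)] = sol
                    rss = np.sum((y - B @ c) ** 2)
                    if rss < best_rss - 1e-12:
                        best_rss, best = rss, c
            np.testing.assert_allclose(fit.coefficients, best, atol=1e-6)

    def test_choline_collinearity_flag_tracks_gram_condition(self, basis):
        # at 1.5 Hz width the 0.01-0.03 ppm choline members are resolved
        # (Gram condition near 1); broad 40 Hz lines overlap heavily and
        # trip the flag at a matching condition limit
        assert basis.gram_condition() < 10
        wide_lines = {k: [(s, a, 40.0) for s, a, _ in v] for k, v in mrs.DEFAULT_BASIS_LINES.items()}
        wide = build_basis(wide_lines)
        assert wide.gram_condition() > 100
        spec = simulate_spectrum(TUMOR_RATIOS, wide)
        fit = fit_spectrum(spec, wide, baseline_order=0, condition_limit=100.0)
        assert fit.ill_conditioned
        assert not fit_spectrum(simulate_spectrum(TUMOR_RATIOS, basis), basis,
                                baseline_order=0, condition_limit=100.0).ill_conditioned
        # composite pool stays accurate even under heavy overlap
        assert fit.choline_pool_ratio() == pytest.approx(0.32, abs=1e-2)


class TestRatiosTable:
    def test_single_fit_rows_and_composite_additivity(self, basis):
        spec = simulate_spectrum(TUMOR_RATIOS, basis, sample_id="s1", region="tumor")
        fit = fit_spectrum(spec, basis, baseline_order=0)
        df = ratios_table([fit], groups={"s1": "gbm"})
        assert (df["sample"] == "s1").all()
        composite = df.loc[df["metabolite"] == "Cho+GPC+PCh", "ratio"].item()
        parts = df.loc[df["metabolite"].isin(["Cho", "GPC", "PCh"]), "ratio"].sum()
        assert composite == pytest.approx(parts, abs=1e-12)
        assert composite == pytest.approx(0.32, abs=1e-2)
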