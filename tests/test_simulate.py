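"""Forward simulators: analytic phase, off-axis recording, spectra, cohorts."""

import dataclasses

import numpy as np
import pytest

from brimphase import (CohortSpec, HologramSimConfig, SpectrumSimConfig,
                       SyntheticCellSpec, analyze_spectrum, default_cohorts,
                       draw_cohort_parameters, make_cohort,
                       simulate_brillouin_spectrum, simulate_interferogram,
                       simulate_phase_object)
from brimphase.brillouin import PeakNotFoundError, lorentzian
from brimphase.simulate import (CarrierSeparationError, ObjectOutOfFieldError,
                                SaturationError, sphere_phase)


class TestPhaseObject:
    def test_center_phase_matches_closed_form(self):
        # 2π · Δn · D / λ_Q with Δn = 0.040, D = 12 µm, λ = 632.8 nm
        spec = SyntheticCellSpec(diameter_um=12.0, n_cell=1.375,
                                 center_px=(256.0, 256.0))
        cfg = HologramSimConfig(blur_sigma_px=0.0, noise_sigma=0.0)
        pm = simulate_phase_object(spec, cfg)
        expected = 2.0 * np.pi * 0.040 * 12.0 / 0.6328
        assert pm.phi[256, 256] == pytest.approx(expected, abs=1e-9)
        assert pm.phi[256, 256] == pytest.approx(4.766, abs=1e-3)

    def test_zero_contrast_gives_zero_phase(self):
        spec = SyntheticCellSpec(n_cell=1.335, n_medium=1.335)
        pm = simulate_phase_object(spec, HologramSimConfig(blur_sigma_px=0.0))
        assert np.all(pm.phi == 0.0)

    def test_no_blur_matches_analytic_thickness_everywhere(self):
        spec = SyntheticCellSpec(diameter_um=14.0, n_cell=1.368,
                                 center_px=(250.2, 260.7))
        cfg = HologramSimConfig(blur_sigma_px=0.0, noise_sigma=0.0)
        pm = simulate_phase_object(spec, cfg)
        np.testing.assert_array_equal(pm.phi, sphere_phase(spec, cfg))

    def test_object_out_of_field(self):
        spec = SyntheticCellSpec(diameter_um=16.0, center_px=(40.0, 256.0))
        with pytest.raises(ObjectOutOfFieldError, match="out of field"):
            simulate_phase_object(spec, HologramSimConfig())

    def test_ground_truth_attached(self):
        spec = SyntheticCellSpec()
        pm = simulate_phase_object(spec, HologramSimConfig())
        assert pm.truth["diameter_um"] == spec.diameter_um


class TestInterferogram:
    def test_flat_phase_gives_pure_carrier_fringes(self, ideal_hcfg):
        from brimphase.holography import PhaseMap, demodulate

        cfg = dataclasses.replace(ideal_hcfg, background_coeffs=((0.0,),))
        flat = PhaseMap(np.zeros(cfg.shape_px), cfg.pixel_um, cfg.lambda_q_nm)
        holo = simulate_interferogram(flat, cfg, check_separation=False)
        field = demodulate(holo)
        inner = np.abs(field.wrapped_phase[30:-30, 30:-30])
        assert np.max(inner) < 1e-3

    def test_seeded_noise_is_bit_identical(self, control_cell):
        cfg = HologramSimConfig(noise_sigma=0.02, seed=11)
        pm = simulate_phase_object(control_cell, cfg)
        a = simulate_interferogram(pm, cfg)
        b = simulate_interferogram(pm, cfg)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_saturation_raises(self, control_cell):
        cfg = HologramSimConfig(noise_sigma=2.0, seed=0)
        pm = simulate_phase_object(control_cell, cfg)
        with pytest.raises(SaturationError):
            simulate_interferogram(pm, cfg)

    def test_insufficient_carrier_separation_raises(self, control_cell):
        cfg = HologramSimConfig(carrier_cycles=(8.0, 8.0))
        pm = simulate_phase_object(control_cell, cfg)
        with pytest.raises(CarrierSeparationError):
            simulate_interferogram(pm, cfg)


class TestBrillouinSimulator:
    def test_simulated_fwhm_is_linear_broadening_sum(self, ideal_scfg):
        # Γ_true + δν_instrument = 1.279 + 0.398 = 1.677 GHz
        spec = SyntheticCellSpec(nu_b_ghz=7.865, gamma_true_ghz=1.279)
        sp = simulate_brillouin_spectrum(spec, ideal_scfg)
        assert sp.truth["simulated_fwhm_ghz"] == pytest.approx(1.677)
        result = analyze_spectrum(sp, ideal_scfg.instrument_fwhm_ghz)
        assert result.gamma_measured_ghz == pytest.approx(1.677, abs=2e-3)

    def test_zero_brillouin_amplitude_leaves_only_elastic_line(self):
        spec = SyntheticCellSpec()
        cfg = SpectrumSimConfig(brillouin_amplitude=0.0, noise_model="none")
        sp = simulate_brillouin_spectrum(spec, cfg)
        freq = sp.frequency_ghz
        expected = cfg.baseline + lorentzian(
            freq, cfg.elastic_amplitude, 0.0, cfg.instrument_fwhm_ghz, 0.0)
        np.testing.assert_allclose(sp.counts, expected)
        from brimphase import locate_and_fit_peaks
        with pytest.raises(PeakNotFoundError):
            locate_and_fit_peaks(sp)

    def test_seeded_spectrum_is_identical(self):
        spec = SyntheticCellSpec()
        cfg = SpectrumSimConfig(seed=3)
        a = simulate_brillouin_spectrum(spec, cfg)
        b = simulate_brillouin_spectrum(spec, cfg)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_overlapping_peaks_flagged_not_raised(self):
        spec = SyntheticCellSpec(nu_b_ghz=1.5, gamma_true_ghz=1.279)
        sp = simulate_brillouin_spectrum(spec, SpectrumSimConfig())
        assert sp.overlap_warning

    def test_shift_beyond_half_fsr_rejected(self):
        spec = SyntheticCellSpec(nu_b_ghz=16.0)
        with pytest.raises(ValueError, match="FSR"):
            simulate_brillouin_spectrum(spec, SpectrumSimConfig())


class TestCohorts:
    def test_empty_cohort(self):
        cells = make_cohort(CohortSpec(0, "empty"))
        assert cells == []

    def test_same_seed_reproduces_cohort(self):
        spec = CohortSpec(2, "rep", seed=5)
        hcfg = HologramSimConfig(shape_px=(256, 256), carrier_cycles=(45.0, 45.0))
        a = make_cohort(spec, hcfg)
        b = make_cohort(spec, hcfg)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.interferogram.pixels,
                                          cb.interferogram.pixels)
            np.testing.assert_array_equal(ca.spectrum.counts, cb.spectrum.counts)

    def test_drawn_parameters_converge_to_population_means(self):
        # law of large numbers at n = 10^4, tolerance 3 standard errors
        spec = CohortSpec(10_000, "lln", seed=1)
        df = draw_cohort_parameters(spec)
        for col, (mean, sd) in [("diameter_um", spec.diameter_um),
                                ("nu_b_ghz", spec.nu_b_ghz),
                                ("gamma_b_ghz", spec.gamma_b_ghz)]:
            se = sd / np.sqrt(len(df))
            assert abs(df[col].mean() - mean) < 3 * se

    def test_zero_sd_draws_are_exact(self):
        spec = CohortSpec(5, "const", diameter_um=(12.0, 0.0),
                          n_cell=(1.37, 0.0), nu_b_ghz=(7.8, 0.0),
                          gamma_b_ghz=(1.2, 0.0))
        df = draw_cohort_parameters(spec)
        assert (df["diameter_um"] == 12.0).all()
        assert (df["nu_b_ghz"] == 7.8).all()

    def test_default_study_conditions(self):
        cohorts = default_cohorts()
        assert [c.n_cells for c in cohorts] == [21, 25, 26]
        assert [c.label for c in cohorts] == ["control", "nocodazole",
                                              "hypoosmotic"]
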