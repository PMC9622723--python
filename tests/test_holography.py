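"""Demodulation, unwrapping, background removal and segmentation."""

import dataclasses

import numpy as np
import pytest

from brimphase import (Interferogram, PhaseMap,
                       SyntheticCellSpec, demodulate, remove_background,
                       segment_cell, simulate_interferogram,
                       simulate_phase_object, unwrap)
from brimphase.holography import NoCarrierError, NoCellError
from brimphase.simulate import sphere_phase


@pytest.fixture(scope="module")
def sphere_pair(ideal_hcfg, control_cell):
    cfg = dataclasses.replace(ideal_hcfg, background_coeffs=((0.0,),))
    pm = simulate_phase_object(control_cell, cfg)
    holo = simulate_interferogram(pm, cfg)
    return pm, holo


class TestDemodulate:
    def test_uniform_image_has_no_carrier(self):
        interf = Interferogram(np.full((128, 128), 1000.0), 0.1, 632.8)
        with pytest.raises(NoCarrierError, match="no carrier detected"):
            demodulate(interf)

    def test_roundtrip_wrapped_phase_mod_2pi(self, sphere_pair, control_cell):
        # noise-free sphere hologram: wrapped phase matches truth mod 2π
        # away from the band-limited cell boundary
        pm, holo = sphere_pair
        field = demodulate(holo)
        rec = field.wrapped_phase
        offset = np.median(np.angle(np.exp(1j * (rec - pm.phi))))
        err = np.angle(np.exp(1j * (rec - pm.phi - offset)))
        yy, xx = np.mgrid[0:512, 0:512]
        r_um = np.hypot(yy - control_cell.center_px[0],
                        xx - control_cell.center_px[1]) * pm.pixel_um
        R = control_cell.diameter_um / 2.0
        away = ((r_um < 0.75 * R) | (r_um > 1.25 * R))
        away &= (np.maximum(np.abs(yy - 256), np.abs(xx - 256)) < 225)
        assert np.sqrt(np.mean(err[away] ** 2)) < 1e-2

    def test_roundtrip_unwrapped_away_from_edges(self, sphere_pair, control_cell):
        # end-to-end oracle: recovered φ equals input within 1e-3 rad RMS
        # away from the image border and the cell boundary
        pm, holo = sphere_pair
        rec = unwrap(demodulate(holo)).phi
        rec = rec - np.median(rec[pm.phi == 0])
        err = rec - pm.phi
        yy, xx = np.mgrid[0:pm.shape[0], 0:pm.shape[1]]
        r_um = np.hypot(yy - control_cell.center_px[0],
                        xx - control_cell.center_px[1]) * pm.pixel_um
        R = control_cell.diameter_um / 2.0
        away = ((r_um < 0.75 * R) | (r_um > 1.25 * R))
        away &= (np.maximum(np.abs(yy - 256), np.abs(xx - 256)) < 225)
        assert np.sqrt(np.mean(err[away] ** 2)) < 1e-3

    def test_sideband_hint_selects_carrier(self, sphere_pair, ideal_hcfg):
        pm, holo = sphere_pair
        field = demodulate(holo, sideband_hint=ideal_hcfg.carrier_cycles)
        assert field.carrier_cycles == ideal_hcfg.carrier_cycles


class TestUnwrap:
    def test_plane_recovered_up_to_2pi_offset(self):
        yy, xx = np.mgrid[0:64, 0:64]
        plane = 10.0 * (xx / 63.0)  # 10 rad span
        wrapped = np.angle(np.exp(1j * plane))
        out = unwrap(wrapped, pixel_um=0.1, lambda_q_nm=632.8).phi
        offset = out[0, 0] - plane[0, 0]
        assert offset == pytest.approx(2 * np.pi * round(offset / (2 * np.pi)), abs=1e-9)
        np.testing.assert_allclose(out - offset, plane, atol=1e-9)

    def test_output_congruent_mod_2pi_everywhere(self, rng):
        from scipy.ndimage import gaussian_filter

        surface = gaussian_filter(rng.normal(0, 6.0, (96, 96)), 6)
        wrapped = np.angle(np.exp(1j * surface))
        out = unwrap(wrapped, pixel_um=0.1, lambda_q_nm=632.8).phi
        err = np.angle(np.exp(1j * (out - wrapped)))
        assert np.max(np.abs(err)) < 1e-9

    def test_spherical_cap_phase_recovered(self, ideal_hcfg):
        spec = SyntheticCellSpec(diameter_um=12.0, n_cell=1.375,
                                 center_px=(256.0, 256.0))
        pm = simulate_phase_object(spec, ideal_hcfg)  # peak 4.766 rad
        wrapped = np.angle(np.exp(1j * pm.phi))
        out = unwrap(wrapped, pixel_um=0.1, lambda_q_nm=632.8).phi
        out -= np.median(out[pm.phi == 0])
        np.testing.assert_allclose(out, pm.phi, atol=1e-3)

    def test_zero_input_zero_output(self):
        out = unwrap(np.zeros((32, 32)), pixel_um=0.1, lambda_q_nm=632.8)
        assert np.all(out.phi == 0.0)
        assert not out.residues_detected


class TestRemoveBackground:
    def _phase(self, phi):
        return PhaseMap(phi, 0.1, 632.8)

    def test_pure_polynomial_removed_to_zero(self):
        yy, xx = np.mgrid[0:128, 0:128]
        xn, yn = xx / 127 * 2 - 1, yy / 127 * 2 - 1
        surface = 0.5 + 0.3 * xn - 0.2 * yn + 0.4 * xn * yn + 0.1 * xn**2
        mask = np.zeros((128, 128), dtype=bool)
        mask[40:60, 40:60] = True  # pretend-cell region, excluded from fit
        out = remove_background(self._phase(surface), mask, poly_order=2)
        np.testing.assert_allclose(out.phi, 0.0, atol=1e-6)

    def test_simulated_background_coeffs_recovered(self, control_cell, ideal_hcfg):
        # forward-model oracle: cell phase emerges once the simulated
        # polynomial background is fitted away
        pm = simulate_phase_object(control_cell, ideal_hcfg)
        holo = simulate_interferogram(pm, ideal_hcfg)  # default tilted bg
        rec = unwrap(demodulate(holo))
        yy, xx = np.mgrid[0:512, 0:512]
        r_um = np.hypot(yy - control_cell.center_px[0],
                        xx - control_cell.center_px[1]) * 0.1
        mask = r_um < 0.65 * control_cell.diameter_um
        out = remove_background(rec, mask, poly_order=2)
        err = out.phi - pm.phi
        sel = (~mask) & (np.maximum(np.abs(yy - 256), np.abs(xx - 256)) < 225)
        assert np.sqrt(np.mean(err[sel] ** 2)) < 1e-2

    def test_order_zero_subtracts_background_mean(self):
        phi = np.full((64, 64), 3.0)
        mask = np.zeros((64, 64), dtype=bool)
        out = remove_background(self._phase(phi), mask, poly_order=0)
        np.testing.assert_allclose(out.phi, 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        # least-squares subtraction is a projection: applying it twice
        # with the same mask changes nothing
        yy, xx = np.mgrid[0:128, 0:128]
        phi = 0.4 * (xx / 127.0) + rng.normal(0, 0.05, (128, 128))
        phi[50:70, 50:70] += 3.0
        mask = np.zeros((128, 128), dtype=bool)
        mask[45:75, 45:75] = True
        once = remove_background(self._phase(phi), mask, poly_order=2)
        twice = remove_background(once, mask, poly_order=2)
        rms = np.sqrt(np.mean((twice.phi - once.phi) ** 2))
        assert rms < 1e-6

    def test_insufficient_background_pixels(self):
        phi = np.zeros((16, 16))
        mask = np.ones((16, 16), dtype=bool)
        mask[0, 0] = False
        with pytest.raises(ValueError, match="insufficient background"):
            remove_background(self._phase(phi), mask, poly_order=2)


class TestSegmentation:
    def test_mask_overlaps_true_disc(self, ideal_results, control_cell):
        mask = ideal_results.mask
        yy, xx = np.mgrid[0:512, 0:512]
        r_um = np.hypot(yy - control_cell.center_px[0],
                        xx - control_cell.center_px[1]) * 0.1
        true_disc = r_um < control_cell.diameter_um / 2.0
        iou = (mask & true_disc).sum() / (mask | true_disc).sum()
        assert iou >= 0.95

    def test_flat_phase_has_no_cell(self):
        with pytest.raises(NoCellError, match="no cell found"):
            segment_cell(PhaseMap(np.zeros((64, 64)), 0.1, 632.8))

    def test_two_objects_keeps_larger_integrated_phase(self, ideal_hcfg):
        cfg = dataclasses.replace(ideal_hcfg, shape_px=(512, 512))
        big = SyntheticCellSpec(diameter_um=13.0, n_cell=1.372,
                                center_px=(150.0, 150.0))
        small = SyntheticCellSpec(diameter_um=9.0, n_cell=1.360,
                                  center_px=(370.0, 370.0))
        phi = sphere_phase(big, cfg) + sphere_phase(small, cfg)
        mask = segment_cell(PhaseMap(phi, cfg.pixel_um, cfg.lambda_q_nm))
        assert mask[150, 150] and not mask[370, 370]
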