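import numpy as np
import pytest

from brimphase import (AnalysisConfig, HologramSimConfig, SingleCellModel,
                       SpectrumSimConfig, SyntheticCellSpec,
                       simulate_brillouin_spectrum, simulate_interferogram,
                       simulate_phase_object)
from brimphase.constants import InstrumentCalibration


@pytest.fixture(scope="session")
def ideal_hcfg():
    """Noise-free, blur-free hologram recording."""
    return HologramSimConfig(blur_sigma_px=0.0, noise_sigma=0.0)


@pytest.fixture(scope="session")
def ideal_scfg():
    return SpectrumSimConfig(noise_model="none")


@pytest.fixture(scope="session")
def control_cell():
    """A control-like cell: D = 12.9 µm, n = 1.371, ν_B = 7.865 GHz."""
    return SyntheticCellSpec(diameter_um=12.9, n_cell=1.371,
                             center_px=(255.5, 256.3),
                             nu_b_ghz=7.865, gamma_true_ghz=1.279)


@pytest.fixture(scope="session")
def uncalibrated_config():
    """Analysis config with the bead-derived diameter divisor disabled,
    matching blur-free simulations where no boundary inflation occurs."""
    return AnalysisConfig(
        calibration=InstrumentCalibration(hough_calibration_factor=1.0))


@pytest.fixture(scope="session")
def ideal_results(control_cell, ideal_hcfg, ideal_scfg, uncalibrated_config):
    """Full pipeline run on a noise-free, blur-free simulated pair.

    Session-scoped: several tests assert different recovery properties on
    the same (deterministic) result.
    """
    phase = simulate_phase_object(control_cell, ideal_hcfg)
    holo = simulate_interferogram(phase, ideal_hcfg)
    spectrum = simulate_brillouin_spectrum(control_cell, ideal_scfg)
    return SingleCellModel(holo, spectrum, uncalibrated_config).fit()


@pytest.fixture(scope="session")
def realistic_results(control_cell):
    """Pipeline run with the default (blurred, noisy, calibrated) study
    conditions."""
    hcfg = HologramSimConfig(seed=7)
    scfg = SpectrumSimConfig(seed=7)
    phase = simulate_phase_object(control_cell, hcfg)
    holo = simulate_interferogram(phase, hcfg)
    spectrum = simulate_brillouin_spectrum(control_cell, scfg)
    return SingleCellModel(holo, spectrum).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
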