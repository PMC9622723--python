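"""Physical constants, instrument calibration values and unit conversions.

All internal arithmetic uses a micron-coherent unit set (µm, pg, GHz, nm)
in which the refractive-index increment conversion is exact:
1 mL/g = 1 µm³/pg.  Reported quantities are g/mL, pg, µm³, GPa, Pa·s, %.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

# --- exact unit conversions (kept in one place, tested) -------------------
GHZ_TO_HZ = 1.0e9
NM_TO_M = 1.0e-9
NM_TO_UM = 1.0e-3
G_PER_ML_TO_KG_PER_M3 = 1.0e3
PA_TO_GPA = 1.0e-9
ML_PER_G_TO_UM3_PER_PG = 1.0  # 1 mL/g == 1 µm³/pg, exactly


@dataclass(frozen=True)
class PhysicalConstants:
    """Material constants of the two-component (dry + fluid) cell model.

    Parameters
    ----------
    alpha_ml_per_g : refractive-index increment of intracellular protein,
        ~0.2 mL/g, nearly composition independent.
    rho_dry_pg_per_um3 : average mass density of protein, 1.37 g/mL.
    rho_fluid_pg_per_um3 : density of the cytoplasmic fluid phase, ~water.
    n_medium : refractive index of the imaging medium.
    lambda_q_nm : quantitative-phase-imaging illumination wavelength.
    lambda_b_nm : Brillouin excitation wavelength.
    """

    alpha_ml_per_g: float = 0.2
    rho_dry_pg_per_um3: float = 1.37
    rho_fluid_pg_per_um3: float = 1.0
    n_medium: float = 1.335
    lambda_q_nm: float = 632.8
    lambda_b_nm: float = 532.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if not self.rho_dry_pg_per_um3 > self.rho_fluid_pg_per_um3:
            raise ValueError("rho_dry must exceed rho_fluid")


@dataclass(frozen=True)
class InstrumentCalibration:
    """Fixed spectrometer/objective calibration values.

    hough_calibration_factor : divisor applied to the raw circular-Hough
        diameter; fixed at 1.08 from polystyrene-bead size standards whose
        diameter the uncalibrated transform overestimates by ~8% (point-
        spread-function blur).
    instrument_fwhm_ghz : FWHM of the spectrometer response (unsaturated
        elastic line), subtracted linearly from fitted Brillouin linewidths.
    fsr_ghz : free spectral range of the VIPA etalon; anchors the
        pixel-to-GHz dispersion calibration.
    """

    hough_calibration_factor: float = 1.08
    instrument_fwhm_ghz: float = 0.398
    fsr_ghz: float = 29.95

    def __post_init__(self) -> None:
        if not self.hough_calibration_factor > 0:
            raise ValueError("hough_calibration_factor must be positive")
        if self.instrument_fwhm_ghz < 0:
            raise ValueError("instrument_fwhm_ghz must be non-negative")
        if not self.fsr_ghz > 0:
            raise ValueError("fsr_ghz must be positive")
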