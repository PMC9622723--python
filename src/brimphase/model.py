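"""Model/results layer: a single acquisition pair in, fifteen biophysical
parameters out.

``SingleCellModel`` is built from one off-axis interferogram and one
Brillouin spectrum (plus a configuration of physical and instrument
constants); ``fit()`` runs the full chain — demodulation, unwrapping,
segmentation, background removal, sphere fitting, QPI parameters,
spectral fitting, viscoelastic combination — and returns a
``SingleCellResults`` carrying every intermediate product, the parameter
vector and a formatted summary table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage import morphology

from . import brillouin as brl
from . import geometry, holography, qpi, viscoelastic
from .constants import InstrumentCalibration, PhysicalConstants

logger = logging.getLogger(__name__)

#: canonical order of the fifteen reported parameters
PARAM_COLUMNS = [
    "diameter_um",
    "refractive_index",
    "dry_mass_pg",
    "fluid_volume_um3",
    "dry_volume_um3",
    "cell_volume_um3",
    "density_g_per_ml",
    "water_mass_pct",
    "water_volume_pct",
    "brillouin_shift_ghz",
    "brillouin_linewidth_ghz",
    "longitudinal_modulus_gpa",
    "longitudinal_viscosity_pa_s",
    "loss_modulus_gpa",
    "loss_tangent",
]

#: display precision mirroring the per-parameter report convention
PARAM_DECIMALS = {
    "diameter_um": 1,
    "refractive_index": 3,
    "dry_mass_pg": 0,
    "fluid_volume_um3": 0,
    "dry_volume_um3": 0,
    "cell_volume_um3": 0,
    "density_g_per_ml": 3,
    "water_mass_pct": 1,
    "water_volume_pct": 1,
    "brillouin_shift_ghz": 3,
    "brillouin_linewidth_ghz": 3,
    "longitudinal_modulus_gpa": 3,
    "longitudinal_viscosity_pa_s": 4,
    "loss_modulus_gpa": 2,
    "loss_tangent": 2,
}


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage that raised it."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"[{stage}] {original}")


@dataclass(frozen=True)
class AnalysisConfig:
    """Resolved configuration: physical constants, instrument calibration
    and processing options."""

    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    calibration: InstrumentCalibration = field(default_factory=InstrumentCalibration)
    poly_order: int = 2
    crop_frac: float = 0.175
    fft_window: bool = False
    radius_range_um: tuple[float, float] = (4.0, 10.0)
    dry_mass_domain: str = "mask"
    edge_exclusion: float = 0.1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["radius_range_um"] = list(self.radius_range_um)
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        consts = PhysicalConstants(**raw.pop("constants", {}))
        calib = InstrumentCalibration(**raw.pop("calibration", {}))
        if "radius_range_um" in raw:
            raw["radius_range_um"] = tuple(raw["radius_range_um"])
        return cls(constants=consts, calibration=calib, **raw)


@dataclass
class SingleCellResults:
    """Fitted per-cell record with all intermediate products."""

    phase: holography.PhaseMap
    mask: np.ndarray
    sphere: geometry.SphereFit
    biophysics: qpi.CellBiophysics
    brillouin: brl.BrillouinResult
    viscoelastic: viscoelastic.ViscoelasticResult
    config: AnalysisConfig
    provenance: dict = field(default_factory=dict)

    @property
    def params(self) -> pd.Series:
        b, br, v = self.biophysics, self.brillouin, self.viscoelastic
        return pd.Series({
            "diameter_um": b.diameter_um,
            "refractive_index": b.n_cell_mean,
            "dry_mass_pg": b.m_dry_pg,
            "fluid_volume_um3": b.v_fluid_um3,
            "dry_volume_um3": b.v_dry_um3,
            "cell_volume_um3": b.v_cell_um3,
            "density_g_per_ml": b.rho_g_per_ml,
            "water_mass_pct": b.u_h2o_pct,
            "water_volume_pct": b.theta_h2o_pct,
            "brillouin_shift_ghz": br.nu_b_ghz,
            "brillouin_linewidth_ghz": br.gamma_b_ghz,
            "longitudinal_modulus_gpa": v.m_prime_gpa,
            "longitudinal_viscosity_pa_s": v.eta_pa_s,
            "loss_modulus_gpa": v.m_dprime_gpa,
            "loss_tangent": v.loss_tangent,
        })[PARAM_COLUMNS]

    def to_record(self) -> dict:
        rec = {k: float(v) for k, v in self.params.items()}
        rec["fluid_mass_pg"] = self.biophysics.m_fluid_pg
        rec["snr_db"] = self.brillouin.snr_db
        rec["accumulator_score"] = self.sphere.accumulator_score
        rec.update(self.provenance)
        return rec

    def summary(self) -> str:
        lines = ["Single-cell biophysical parameters", "=" * 42]
        for name in PARAM_COLUMNS:
            value = self.params[name]
            lines.append(f"{name:<28s} {value:>12.{PARAM_DECIMALS[name]}f}")
        lines.append("-" * 42)
        lines.append(f"{'spectrum SNR (dB)':<28s} {self.brillouin.snr_db:>12.1f}")
        lines.append(f"{'Hough score':<28s} {self.sphere.accumulator_score:>12.3f}")
        return "\n".join(lines)


class SingleCellModel:
    """One paired acquisition (hologram + Brillouin spectrum).

    Parameters
    ----------
    interferogram : raw off-axis frame with grid metadata.
    spectrum : Brillouin spectrum with a calibrated (or calibratable)
        dispersion axis.
    config : analysis configuration; defaults are the instrument values
        this pipeline was built around.
    mask : optional externally supplied cell mask (True = cell), which
        replaces automatic segmentation to reproduce a manual workflow.
    """

    def __init__(
        self,
        interferogram: holography.Interferogram,
        spectrum: brl.BrillouinSpectrum,
        config: AnalysisConfig | None = None,
        mask: np.ndarray | None = None,
    ):
        self.interferogram = interferogram
        self.spectrum = spectrum
        self.config = config or AnalysisConfig()
        self.mask = None if mask is None else np.asarray(mask, dtype=bool)

    @classmethod
    def from_files(
        cls,
        hologram_path: str | Path,
        spectrum_path: str | Path,
        config: AnalysisConfig | None = None,
        pixel_um: float = 0.1,
        dispersion_coeffs: np.ndarray | None = None,
        mask_path: str | Path | None = None,
    ) -> "SingleCellModel":
        from . import io

        config = config or AnalysisConfig()
        try:
            interf = io.read_interferogram(hologram_path, pixel_um,
                                           config.constants.lambda_q_nm)
        except (OSError, ValueError) as exc:
            raise StageError("read_hologram", exc) from exc
        try:
            spectrum = io.read_spectrum_csv(spectrum_path, dispersion_coeffs,
                                            config.calibration.fsr_ghz)
        except (OSError, ValueError) as exc:
            raise StageError("read_spectrum", exc) from exc
        mask = io.read_mask(mask_path) if mask_path else None
        model = cls(interf, spectrum, config, mask=mask)
        model._paths = {"hologram": str(hologram_path), "spectrum": str(spectrum_path)}
        return model

    def _stage(self, name: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc
        logger.info("stage %-18s %6.1f ms", name, 1e3 * (time.perf_counter() - t0))
        return out

    def fit(self) -> SingleCellResults:
        cfg = self.config
        field_ = self._stage("demodulate", holography.demodulate,
                             self.interferogram, crop_frac=cfg.crop_frac,
                             window=cfg.fft_window)
        phase0 = self._stage("unwrap", holography.unwrap, field_)
        phase0.truth = self.interferogram.truth

        if self.mask is not None:
            mask0 = self.mask
        else:
            mask0 = self._stage("segment", holography.segment_cell, phase0)
        # dilate before the background fit so cell-edge tails are excluded
        bg_mask = morphology.dilation(mask0, morphology.disk(5))
        phase = self._stage("background", holography.remove_background,
                            phase0, bg_mask, cfg.poly_order)
        mask = (self.mask if self.mask is not None
                else self._stage("segment", holography.segment_cell, phase))
        phase.mask = mask

        sphere = self._stage(
            "fit_sphere", geometry.fit_sphere, phase,
            radius_range_um=cfg.radius_range_um,
            calibration_factor=cfg.calibration.hough_calibration_factor,
        )
        bio = self._stage("qpi_params", qpi.cell_biophysics, phase, sphere,
                          mask, cfg.constants, cfg.dry_mass_domain)
        bres = self._stage("brillouin", brl.analyze_spectrum, self.spectrum,
                           cfg.calibration.instrument_fwhm_ghz)
        visc = self._stage(
            "viscoelastic", viscoelastic.viscoelastic_params,
            bio.rho_g_per_ml, bres.nu_b_ghz, bres.gamma_b_ghz,
            bio.n_cell_mean, cfg.constants.lambda_b_nm,
        )
        provenance = {"config_hash": cfg.hash()}
        provenance.update(getattr(self, "_paths", {}))
        return SingleCellResults(
            phase=phase, mask=mask, sphere=sphere, biophysics=bio,
            brillouin=bres, viscoelastic=visc, config=cfg,
            provenance=provenance,
        )


def rounded_table(df: pd.DataFrame) -> pd.DataFrame:
    """Display-precision copy of a cohort table (full precision is the
    canonical on-disk representation)."""
    out = df.copy()
    for col, dec in PARAM_DECIMALS.items():
        if col in out:
            out[col] = out[col].round(dec)
    return out
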