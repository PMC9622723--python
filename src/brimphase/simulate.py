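"""Forward simulators: interferograms of spherical phase objects, VIPA
Brillouin spectra, and seeded synthetic cohorts.

Every analysis stage of the package is testable against these simulators,
which generate the exact signal models the analysis inverts: a spherical
cell of known diameter and refractive index on a tilted-fringe carrier
with polynomial phase background, and a Brillouin spectrum of an elastic
line plus a Stokes/anti-Stokes Lorentzian pair on a polynomial dispersion
axis.  All simulators are pure functions of (spec, config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from numpy.polynomial import polynomial as npoly
from scipy import ndimage

from .brillouin import BrillouinSpectrum, lorentzian
from .holography import Interferogram, PhaseMap

UINT16_MAX = 65535


class ObjectOutOfFieldError(ValueError):
    pass


class SaturationError(ValueError):
    pass


class CarrierSeparationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Ground truth for one simulated cell."""

    diameter_um: float = 12.9
    n_cell: float = 1.371
    center_px: tuple[float, float] = (256.0, 256.0)
    n_medium: float = 1.335
    nu_b_ghz: float = 7.865
    gamma_true_ghz: float = 1.279

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be positive")
        if self.n_cell < self.n_medium:
            raise ValueError("n_cell must be >= n_medium")
        if not self.gamma_true_ghz > 0:
            raise ValueError("gamma_true_ghz must be positive")

    def truth_dict(self) -> dict:
        return {
            "diameter_um": self.diameter_um,
            "n_cell": self.n_cell,
            "center_px": list(self.center_px),
            "n_medium": self.n_medium,
            "nu_b_ghz": self.nu_b_ghz,
            "gamma_true_ghz": self.gamma_true_ghz,
        }


@dataclass(frozen=True)
class HologramSimConfig:
    """Off-axis recording geometry and noise for the hologram simulator.

    The carrier is expressed in cycles per field (row, col); the default
    places the sideband near half the Nyquist radius so that the default
    demodulation crop window clears the DC autocorrelation halo.
    """

    shape_px: tuple[int, int] = (512, 512)
    pixel_um: float = 0.1
    lambda_q_nm: float = 632.8
    carrier_cycles: tuple[float, float] = (90.0, 90.0)
    background_coeffs: tuple[tuple[float, ...], ...] = ((0.0, 0.4), (0.3, 0.15))
    # 4.5 px (0.45 µm) reproduces the ~8% diameter overestimate measured on
    # 10 µm microsphere standards, the bias the 1.08 divisor corrects
    blur_sigma_px: float = 4.5
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_um > 0:
            raise ValueError("pixel_um must be positive")
        if self.blur_sigma_px < 0 or self.noise_sigma < 0:
            raise ValueError("blur and noise must be non-negative")


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Detector geometry, dispersion and noise for the spectrum simulator.

    Default amplitudes give a peak SNR near 32 dB under Poisson noise:
    the noise floor past the Brillouin peaks is the shot noise of their
    own Lorentzian tails plus a 25-count detector baseline.
    """

    n_px: int = 512
    dispersion_coeffs: tuple[float, ...] | None = None  # default: linear, FSR across frame
    fsr_ghz: float = 29.95
    instrument_fwhm_ghz: float = 0.398
    elastic_amplitude: float = 150000.0
    brillouin_amplitude: float = 50000.0
    baseline: float = 25.0
    noise_model: str = "poisson"  # "poisson" | "gaussian" | "none"
    gaussian_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fsr_ghz > 0:
            raise ValueError("fsr_ghz must be positive")
        if self.instrument_fwhm_ghz < 0:
            raise ValueError("instrument_fwhm_ghz must be non-negative")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError("noise_model must be poisson, gaussian or none")

    def coeffs(self) -> np.ndarray:
        """Resolved dispersion polynomial (power series, pixel → GHz)."""
        if self.dispersion_coeffs is not None:
            c = np.asarray(self.dispersion_coeffs, dtype=float)
        else:
            slope = self.fsr_ghz / self.n_px
            c = np.array([-slope * (self.n_px / 2.0), slope])
        f = npoly.polyval(np.arange(self.n_px), c)
        if not (np.all(np.diff(f) > 0) or np.all(np.diff(f) < 0)):
            raise ValueError("dispersion must be strictly monotone")
        return c


# ---------------------------------------------------------------------------
# phase object and interferogram
# ---------------------------------------------------------------------------

def sphere_phase(
    spec: SyntheticCellSpec, cfg: HologramSimConfig
) -> np.ndarray:
    """Analytic spherical-cap phase (no blur): φ = (2π/λ_Q)·Δn·h."""
    yy, xx = np.mgrid[0:cfg.shape_px[0], 0:cfg.shape_px[1]]
    r_um = np.hypot(yy - spec.center_px[0], xx - spec.center_px[1]) * cfg.pixel_um
    R = spec.diameter_um / 2.0
    h = np.zeros(cfg.shape_px, dtype=float)
    inside = r_um < R
    h[inside] = 2.0 * np.sqrt(R * R - r_um[inside] ** 2)
    lam_um = cfg.lambda_q_nm * 1e-3
    return (2.0 * np.pi / lam_um) * (spec.n_cell - spec.n_medium) * h


def simulate_phase_object(
    spec: SyntheticCellSpec, cfg: HologramSimConfig
) -> PhaseMap:
    """Ground-truth phase map of a spherical cell, optionally PSF-blurred.

    Raises ``ObjectOutOfFieldError`` unless the sphere fits in the field
    with a margin of at least 10% of its diameter.
    """
    margin_px = 1.1 * (spec.diameter_um / 2.0) / cfg.pixel_um
    r0, c0 = spec.center_px
    if (r0 - margin_px < 0 or c0 - margin_px < 0
            or r0 + margin_px > cfg.shape_px[0] or c0 + margin_px > cfg.shape_px[1]):
        raise ObjectOutOfFieldError("object out of field")
    phi = sphere_phase(spec, cfg)
    if cfg.blur_sigma_px > 0:
        phi = ndimage.gaussian_filter(phi, cfg.blur_sigma_px, mode="constant")
    return PhaseMap(phi, cfg.pixel_um, cfg.lambda_q_nm, truth=spec.truth_dict())


def _background_phase(cfg: HologramSimConfig) -> np.ndarray:
    yy, xx = np.mgrid[0:cfg.shape_px[0], 0:cfg.shape_px[1]]
    xn = 2.0 * xx / (cfg.shape_px[1] - 1) - 1.0
    yn = 2.0 * yy / (cfg.shape_px[0] - 1) - 1.0
    c = np.asarray(cfg.background_coeffs, dtype=float)
    return npoly.polyval2d(xn, yn, c)


def _object_bandwidth_cycles(phi: np.ndarray) -> float:
    """Radius (cycles/field) enclosing 98% of the spectral energy of e^{iφ}
    with the DC fringe-free carrier removed."""
    spec = np.fft.fftshift(np.fft.fft2(np.exp(1j * phi)))
    power = np.abs(spec) ** 2
    n_r, n_c = phi.shape
    yy, xx = np.mgrid[0:n_r, 0:n_c]
    rad = np.hypot(yy - n_r // 2, xx - n_c // 2)
    order = np.argsort(rad.ravel())
    cum = np.cumsum(power.ravel()[order])
    k = int(np.searchsorted(cum, 0.98 * cum[-1]))
    return float(rad.ravel()[order][min(k, len(cum) - 1)])


def simulate_interferogram(
    phase: PhaseMap, cfg: HologramSimConfig, check_separation: bool = True
) -> Interferogram:
    """Off-axis recording of a phase map.

    I = A_r² + A_s² + 2·A_r·A_s·cos(2π(f·x)/N + φ + φ_bg) + noise, scaled
    and quantized to the 16-bit range; a saturated pixel raises
    ``SaturationError``.  The carrier must exceed three times the object
    bandwidth for the sideband to separate from DC.
    """
    n_r, n_c = phase.shape
    f_r, f_c = cfg.carrier_cycles
    if check_separation:
        bw = _object_bandwidth_cycles(phase.phi + _background_phase(cfg))
        if np.hypot(f_r, f_c) < 3.0 * bw:
            raise CarrierSeparationError(
                f"carrier ({np.hypot(f_r, f_c):.1f} cycles) below 3x object "
                f"bandwidth ({bw:.1f} cycles)"
            )
    yy, xx = np.mgrid[0:n_r, 0:n_c]
    total_phase = phase.phi + _background_phase(cfg)
    fringes = np.cos(2.0 * np.pi * (f_r * yy / n_r + f_c * xx / n_c) + total_phase)
    intensity = 1.0 + fringes  # A_r = A_s, visibility 1; range [0, 2]
    counts = intensity * 15000.0  # fringe amplitude 15000 counts
    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_sigma > 0:
        counts = counts + rng.normal(0.0, cfg.noise_sigma * 15000.0, counts.shape)
    counts = np.clip(np.rint(counts), 0, None)
    if np.any(counts >= UINT16_MAX):
        raise SaturationError("saturated pixel in simulated interferogram")
    return Interferogram(counts, cfg.pixel_um, cfg.lambda_q_nm, truth=phase.truth)


# ---------------------------------------------------------------------------
# Brillouin spectrum
# ---------------------------------------------------------------------------

def simulate_brillouin_spectrum(
    spec: SyntheticCellSpec, cfg: SpectrumSimConfig
) -> BrillouinSpectrum:
    """Elastic line at 0 GHz plus a Stokes/anti-Stokes pair at ±ν_B.

    The simulated Brillouin FWHM is ``gamma_true + instrument_fwhm``
    (linear broadening, the exact inverse of the linear linewidth
    correction applied by the analysis).  Overlapping peaks set
    ``overlap_warning`` instead of raising.
    """
    if not spec.nu_b_ghz < cfg.fsr_ghz / 2.0:
        raise ValueError("nu_b_ghz must be below FSR/2")
    coeffs = cfg.coeffs()
    freq = npoly.polyval(np.arange(cfg.n_px), coeffs)
    fwhm = spec.gamma_true_ghz + cfg.instrument_fwhm_ghz
    expected = np.full(cfg.n_px, float(cfg.baseline))
    expected += lorentzian(freq, cfg.elastic_amplitude, 0.0, cfg.instrument_fwhm_ghz, 0.0)
    if cfg.brillouin_amplitude > 0:
        for sign in (-1.0, 1.0):
            expected += lorentzian(freq, cfg.brillouin_amplitude,
                                   sign * spec.nu_b_ghz, fwhm, 0.0)
    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_model == "poisson":
        counts = rng.poisson(expected).astype(float)
    elif cfg.noise_model == "gaussian":
        counts = np.clip(expected + rng.normal(0.0, cfg.gaussian_sigma, cfg.n_px), 0, None)
    else:
        counts = expected
    overlap = spec.nu_b_ghz < (fwhm + cfg.instrument_fwhm_ghz)
    truth = spec.truth_dict() | {
        "simulated_fwhm_ghz": fwhm,
        "instrument_fwhm_ghz": cfg.instrument_fwhm_ghz,
    }
    return BrillouinSpectrum(counts, coeffs, cfg.fsr_ghz, truth=truth,
                             overlap_warning=bool(overlap))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Population-level distribution of a simulated condition.

    Per-cell parameters are drawn from independent normals truncated (by
    resampling) to physically admissible ranges.
    """

    n_cells: int
    label: str
    diameter_um: tuple[float, float] = (12.9, 1.8)  # (mean, SD)
    n_cell: tuple[float, float] = (1.371, 0.005)
    nu_b_ghz: tuple[float, float] = (7.865, 0.049)
    gamma_b_ghz: tuple[float, float] = (1.279, 0.072)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("diameter_um", "n_cell", "nu_b_ghz", "gamma_b_ghz"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} SD must be >= 0")


def default_cohorts() -> list[CohortSpec]:
    """The three study conditions: control, tubulin disrupter (nocodazole)
    and hypoosmotic shock, with N = 21, 25 and 26 cells."""
    return [
        CohortSpec(21, "control", (12.9, 1.8), (1.371, 0.005), (7.865, 0.049),
                   (1.279, 0.072), seed=1),
        CohortSpec(25, "nocodazole", (13.5, 1.7), (1.367, 0.007), (7.904, 0.084),
                   (1.281, 0.085), seed=2),
        CohortSpec(26, "hypoosmotic", (14.5, 1.7), (1.361, 0.007), (7.687, 0.145),
                   (1.038, 0.161), seed=3),
    ]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def draw_cohort_parameters(
    spec: CohortSpec,
    n_medium: float = 1.335,
    fsr_ghz: float = 29.95,
) -> pd.DataFrame:
    """Ground-truth per-cell parameter draws for a cohort (no rendering).

    Deterministic under ``spec.seed``; used by :func:`make_cohort` and
    directly for parameter-level statistical studies.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for _ in range(spec.n_cells):
        rows.append({
            "diameter_um": _truncated_normal(rng, *spec.diameter_um, 5.0, 25.0),
            "n_cell": _truncated_normal(rng, *spec.n_cell, n_medium + 0.005, 1.45),
            "nu_b_ghz": _truncated_normal(rng, *spec.nu_b_ghz, 2.0, fsr_ghz / 2.0 - 3.0),
            "gamma_b_ghz": _truncated_normal(rng, *spec.gamma_b_ghz, 0.2, 4.0),
        })
    df = pd.DataFrame(rows, columns=["diameter_um", "n_cell", "nu_b_ghz", "gamma_b_ghz"])
    df.insert(0, "condition", spec.label)
    return df


@dataclass
class SimulatedCell:
    """One paired synthetic acquisition with its ground truth."""

    interferogram: Interferogram
    spectrum: BrillouinSpectrum
    spec: SyntheticCellSpec
    condition: str


def make_cohort(
    spec: CohortSpec,
    hcfg: HologramSimConfig | None = None,
    scfg: SpectrumSimConfig | None = None,
) -> list[SimulatedCell]:
    """Render a cohort of paired (interferogram, spectrum) acquisitions.

    Per-cell seeds and sub-pixel center jitter derive deterministically
    from ``spec.seed``.
    """
    hcfg = hcfg or HologramSimConfig()
    scfg = scfg or SpectrumSimConfig()
    params = draw_cohort_parameters(spec, fsr_ghz=scfg.fsr_ghz)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0_FFEE]))
    cells: list[SimulatedCell] = []
    for i, row in params.iterrows():
        center = (hcfg.shape_px[0] / 2.0 + rng.uniform(-5, 5),
                  hcfg.shape_px[1] / 2.0 + rng.uniform(-5, 5))
        cell_spec = SyntheticCellSpec(
            diameter_um=row["diameter_um"], n_cell=row["n_cell"],
            center_px=center, nu_b_ghz=row["nu_b_ghz"],
            gamma_true_ghz=row["gamma_b_ghz"],
        )
        seed_h = int(rng.integers(0, 2**31 - 1))
        seed_s = int(rng.integers(0, 2**31 - 1))
        phase = simulate_phase_object(cell_spec, replace(hcfg, seed=seed_h))
        holo = simulate_interferogram(phase, replace(hcfg, seed=seed_h))
        spectrum = simulate_brillouin_spectrum(cell_spec, replace(scfg, seed=seed_s))
        cells.append(SimulatedCell(holo, spectrum, cell_spec, spec.label))
    return cells


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def write_interferogram_tiff(path: str | Path, interf: Interferogram) -> None:
    tifffile.imwrite(str(path), interf.pixels.astype(np.uint16))


def write_spectrum_csv(path: str | Path, spectrum: BrillouinSpectrum) -> None:
    pd.DataFrame({
        "pixel": np.arange(spectrum.n_px),
        "counts": spectrum.counts,
    }).to_csv(path, index=False)


def write_truth_json(path: str | Path, cell: SimulatedCell,
                     scfg: SpectrumSimConfig | None = None) -> None:
    payload = {
        "condition": cell.condition,
        "truth": cell.spec.truth_dict(),
        "dispersion_coeffs": [float(c) for c in cell.spectrum.dispersion_coeffs],
        "fsr_ghz": cell.spectrum.fsr_ghz,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_cohort(
    out_dir: str | Path,
    cells: list[SimulatedCell],
    scfg: SpectrumSimConfig | None = None,
) -> list[dict]:
    """Write a cohort as TIFF + CSV + JSON triplets; returns a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, cell in enumerate(cells):
        stem = f"{cell.condition}_{i:03d}"
        write_interferogram_tiff(out / f"{stem}_holo.tif", cell.interferogram)
        write_spectrum_csv(out / f"{stem}_spec.csv", cell.spectrum)
        write_truth_json(out / f"{stem}_truth.json", cell, scfg)
        manifest.append({
            "condition": cell.condition,
            "hologram": f"{stem}_holo.tif",
            "spectrum": f"{stem}_spec.csv",
            "truth": f"{stem}_truth.json",
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
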