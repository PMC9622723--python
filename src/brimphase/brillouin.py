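"""Brillouin spectrum analysis: dispersion calibration, Lorentzian peak
fitting, shift and linewidth extraction, SNR.

A VIPA spectrometer maps optical frequency to detector position, with
adjacent elastic orders one free spectral range (FSR) apart.  The
Brillouin shift ν_B is half the distance between the Stokes and
anti-Stokes peak centers on the calibrated GHz axis; the linewidth Γ_B is
the Lorentzian FWHM corrected for instrument broadening by linear
subtraction of the spectrometer response (0.398 GHz here).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import optimize, signal

logger = logging.getLogger(__name__)

SNR_CAP_DB = 100.0  # reported for effectively noise-free spectra


class PeakNotFoundError(ValueError):
    """Raised when a required spectral peak cannot be located."""


class FitError(RuntimeError):
    """Raised when a Lorentzian least-squares fit fails to converge."""


@dataclass
class BrillouinSpectrum:
    """1-D spectrum (counts vs. detector pixel) with dispersion metadata.

    ``dispersion_coeffs`` are power-series coefficients c such that
    frequency_ghz(px) = Σ c[k]·px^k, strictly monotone over the support,
    with the elastic line defining 0 GHz (Stokes negative, anti-Stokes
    positive).
    """

    counts: np.ndarray
    dispersion_coeffs: np.ndarray | None
    fsr_ghz: float
    truth: dict | None = field(default=None, repr=False)
    overlap_warning: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 and self.counts.ndim != 1:
            raise ValueError("counts must be 1-D (or a 2-D frame to be reduced)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not self.fsr_ghz > 0:
            raise ValueError("fsr_ghz must be positive")
        if self.dispersion_coeffs is not None:
            self.dispersion_coeffs = np.asarray(self.dispersion_coeffs, dtype=float)
            px = np.arange(len(self.counts))
            f = npoly.polyval(px, self.dispersion_coeffs)
            if not (np.all(np.diff(f) > 0) or np.all(np.diff(f) < 0)):
                raise ValueError("dispersion must be strictly monotone")

    @property
    def n_px(self) -> int:
        return len(self.counts)

    @property
    def frequency_ghz(self) -> np.ndarray:
        if self.dispersion_coeffs is None:
            raise ValueError("spectrum has no dispersion calibration")
        return npoly.polyval(np.arange(self.n_px), self.dispersion_coeffs)


def reduce_frame(
    frame: np.ndarray, sum_axis: int = 0, band: tuple[int, int] | None = None
) -> np.ndarray:
    """Reduce a 2-D camera frame to a 1-D spectrum by summing along the
    non-dispersive axis, optionally over a row/column band."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if band is not None:
        sl = [slice(None), slice(None)]
        sl[sum_axis] = slice(band[0], band[1])
        frame = frame[tuple(sl)]
    return frame.sum(axis=sum_axis)


@dataclass(frozen=True)
class LorentzianPeak:
    center_ghz: float
    fwhm_ghz: float
    amplitude: float
    offset: float
    residual_norm: float

    def __post_init__(self) -> None:
        if not self.fwhm_ghz > 0:
            raise ValueError("fwhm must be positive")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class BrillouinResult:
    nu_b_ghz: float
    gamma_b_ghz: float
    gamma_measured_ghz: float
    snr_db: float
    stokes: LorentzianPeak
    antistokes: LorentzianPeak

    def to_dict(self) -> dict:
        return {
            "nu_b_ghz": self.nu_b_ghz,
            "gamma_b_ghz": self.gamma_b_ghz,
            "gamma_measured_ghz": self.gamma_measured_ghz,
            "snr_db": self.snr_db,
            "stokes": vars(self.stokes) | {},
            "antistokes": vars(self.antistokes) | {},
        }


def lorentzian(f: np.ndarray, amplitude: float, center: float, fwhm: float,
               offset: float) -> np.ndarray:
    """L(f) = A·(Γ/2)² / ((f − c)² + (Γ/2)²) + offset."""
    hw = fwhm / 2.0
    return amplitude * hw**2 / ((f - center) ** 2 + hw**2) + offset


# ---------------------------------------------------------------------------
# dispersion calibration
# ---------------------------------------------------------------------------

def pixel_to_ghz(
    elastic_peak_pixels: np.ndarray,
    fsr_ghz: float,
    degree: int | None = None,
) -> np.ndarray:
    """Dispersion polynomial from the pixel positions of adjacent elastic
    orders, which are exactly one FSR apart.

    The first anchor defines the 0 GHz origin.  The default degree is
    quadratic when three or more anchors are available, linear for two.
    Returns power-series coefficients for ``numpy.polynomial.polynomial``.
    """
    px = np.asarray(elastic_peak_pixels, dtype=float)
    if px.size < 2:
        raise ValueError("at least 2 elastic-order positions are required")
    if np.unique(px).size != px.size:
        raise ValueError("elastic-order anchor pixels must be distinct")
    order = np.argsort(px)
    px = px[order]
    ghz = fsr_ghz * np.arange(px.size, dtype=float)
    if degree is None:
        degree = 2 if px.size >= 3 else 1
    degree = min(degree, px.size - 1)
    series = np.polynomial.Polynomial.fit(px, ghz, deg=degree)
    return series.convert().coef


# ---------------------------------------------------------------------------
# peak location and fitting
# ---------------------------------------------------------------------------

def _fit_window(freq: np.ndarray, counts: np.ndarray, i_peak: int,
                width_px: float) -> LorentzianPeak:
    """Least-squares Lorentzian fit in a window of 3× the peak width.

    The model includes a linear baseline, which absorbs the sloping tail
    of the neighbouring (much brighter) elastic line.
    """
    half = max(4, int(round(1.5 * width_px)))
    lo, hi = max(0, i_peak - half), min(len(counts), i_peak + half + 1)
    f, c = freq[lo:hi], counts[lo:hi]
    offset0 = float(c.min())
    amp0 = float(counts[i_peak] - offset0)
    dfreq = abs(np.median(np.diff(freq)))
    fwhm0 = max(width_px * dfreq, 2.0 * dfreq)

    def model(ff, amplitude, center, fwhm, offset, slope):
        return lorentzian(ff, amplitude, center, fwhm, offset) + slope * (ff - freq[i_peak])

    p0 = [max(amp0, 1e-9), freq[i_peak], fwhm0, offset0, 0.0]
    try:
        popt, _ = optimize.curve_fit(
            model, f, c, p0=p0,
            bounds=([0.0, f.min(), dfreq * 0.2, -np.inf, -np.inf],
                    [np.inf, f.max(), (f.max() - f.min()) * 4.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - rare
        raise FitError(f"Lorentzian fit did not converge: {exc}") from exc
    resid = float(np.linalg.norm(c - model(f, *popt)))
    return LorentzianPeak(center_ghz=float(popt[1]), fwhm_ghz=float(popt[2]),
                          amplitude=float(popt[0]), offset=float(popt[3]),
                          residual_norm=resid)


def locate_and_fit_peaks(
    spectrum: BrillouinSpectrum,
    prominence_frac: float = 0.02,
) -> tuple[LorentzianPeak, LorentzianPeak, LorentzianPeak]:
    """Locate the elastic, Stokes and anti-Stokes lines and fit each with
    an independent Lorentzian.

    Peaks are found by a local-maximum search with a prominence threshold
    (fraction of the spectrum's dynamic range); the elastic line is the
    most prominent peak, Stokes the strongest peak below it in frequency,
    anti-Stokes the strongest above.  Returns (stokes, antistokes,
    elastic).
    """
    counts = spectrum.counts
    freq = spectrum.frequency_ghz
    prom = prominence_frac * float(np.ptp(counts))
    if prom <= 0:
        raise PeakNotFoundError("peak not found: flat spectrum")
    idx, props = signal.find_peaks(counts, prominence=prom, width=1)
    if idx.size == 0:
        raise PeakNotFoundError("peak not found")
    widths = props["widths"]
    i_el = idx[int(np.argmax(props["prominences"]))]
    f_el = freq[i_el]

    def _strongest(side_mask: np.ndarray, label: str) -> tuple[int, float]:
        cand = np.flatnonzero(side_mask)
        if cand.size == 0:
            raise PeakNotFoundError(f"peak not found: {label}")
        j = cand[int(np.argmax(props["prominences"][cand]))]
        return int(idx[j]), float(widths[j])

    min_sep = 3.0 * abs(np.median(np.diff(freq)))
    i_s, w_s = _strongest(freq[idx] < f_el - min_sep, "Stokes")
    i_a, w_a = _strongest(freq[idx] > f_el + min_sep, "anti-Stokes")
    i_e = int(i_el)
    w_e = float(widths[int(np.argmax(props["prominences"]))])

    stokes = _fit_window(freq, counts, i_s, w_s)
    antistokes = _fit_window(freq, counts, i_a, w_a)
    elastic = _fit_window(freq, counts, i_e, w_e)
    return stokes, antistokes, elastic


def brillouin_shift(stokes: LorentzianPeak, antistokes: LorentzianPeak) -> float:
    """ν_B = |c_antistokes − c_stokes| / 2 (half-distance rule)."""
    nu = abs(antistokes.center_ghz - stokes.center_ghz) / 2.0
    if nu < 1e-6:
        warnings.warn("coincident Stokes/anti-Stokes centers: shift ~ 0 is implausible")
    return nu


def correct_linewidth(gamma_measured_ghz: float, instrument_fwhm_ghz: float = 0.398) -> float:
    """Linear instrument-response correction Γ_B = Γ_measured − δν."""
    if instrument_fwhm_ghz < 0:
        raise ValueError("instrument FWHM must be non-negative")
    gamma = gamma_measured_ghz - instrument_fwhm_ghz
    if gamma <= 0:
        raise ValueError("linewidth below instrument response")
    return gamma


def spectrum_snr(
    spectrum: BrillouinSpectrum,
    peaks: tuple[LorentzianPeak, ...],
    exclusion_fwhm: float = 3.0,
    cap_db: float = SNR_CAP_DB,
) -> float:
    """SNR in dB: 10·log10(mean Brillouin amplitude / residual SD).

    The noise SD is estimated from first differences of the counts in a
    peak-free window — the region beyond the outermost fitted peak on each
    side, at least ``exclusion_fwhm`` of its FWHMs from its center:
    SD = std(Δcounts)/√2, which cancels smooth Lorentzian tails.
    Noise-free spectra are capped at ``cap_db``.  This is this package's
    fixed SNR definition.
    """
    freq = spectrum.frequency_ghz
    lo_edge = min(pk.center_ghz - exclusion_fwhm * pk.fwhm_ghz for pk in peaks)
    hi_edge = max(pk.center_ghz + exclusion_fwhm * pk.fwhm_ghz for pk in peaks)
    keep = (freq < lo_edge) | (freq > hi_edge)
    if keep.sum() < 8:
        raise ValueError("empty peak-free window for SNR estimation")
    sd = float(np.std(np.diff(spectrum.counts[keep]))) / np.sqrt(2.0)
    brillouin_amp = float(np.mean([pk.amplitude for pk in peaks[:2]]))
    if sd <= 0 or brillouin_amp / sd > 10 ** (cap_db / 10.0):
        return cap_db
    return 10.0 * np.log10(brillouin_amp / sd)


def relative_change(before: float, after: float) -> float:
    """Percent change 100·(after − before)/before."""
    if before == 0:
        raise ValueError("reference value must be non-zero")
    return 100.0 * (after - before) / before


def analyze_spectrum(
    spectrum: BrillouinSpectrum,
    instrument_fwhm_ghz: float = 0.398,
) -> BrillouinResult:
    """Full spectral chain: locate/fit peaks, shift, corrected linewidth, SNR."""
    stokes, antistokes, elastic = locate_and_fit_peaks(spectrum)
    nu = brillouin_shift(stokes, antistokes)
    gamma_measured = 0.5 * (stokes.fwhm_ghz + antistokes.fwhm_ghz)
    gamma = correct_linewidth(gamma_measured, instrument_fwhm_ghz)
    snr = spectrum_snr(spectrum, (stokes, antistokes, elastic))
    logger.info("brillouin: nu_B=%.4f GHz, Gamma_B=%.4f GHz, SNR=%.1f dB",
                nu, gamma, snr)
    return BrillouinResult(nu_b_ghz=nu, gamma_b_ghz=gamma,
                           gamma_measured_ghz=gamma_measured, snr_db=snr,
                           stokes=stokes, antistokes=antistokes)
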