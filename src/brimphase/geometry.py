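"""Spherical-cell geometry: circular Hough fitting of the cell boundary,
the calibrated diameter, and the projected thickness map.

A freshly plated cell is assumed spherical, so a single circle (center,
radius) fixes its 3-D geometry and the projected thickness along the
optical axis is h(x, y) = 2·sqrt(R² − r²).  The raw Hough diameter is
divided by a fixed calibration factor (default 1.08) because the
point-spread-function blur of the objective systematically inflates the
apparent boundary, a bias quantified with microsphere size standards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.transform import hough_circle

from .holography import PhaseMap

logger = logging.getLogger(__name__)


class NoCircleError(ValueError):
    """Raised when the Hough accumulator contains no credible circle."""


@dataclass(frozen=True)
class SphereFit:
    """Fitted circle with sub-pixel center and calibrated diameter."""

    center_px: tuple[float, float]  # (row, col)
    diameter_raw_um: float
    calibration_factor: float
    accumulator_score: float

    @property
    def diameter_um(self) -> float:
        return self.diameter_raw_um / self.calibration_factor

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    def to_dict(self) -> dict:
        return {
            "center_px": list(self.center_px),
            "diameter_raw_um": self.diameter_raw_um,
            "diameter_um": self.diameter_um,
            "calibration_factor": self.calibration_factor,
            "accumulator_score": self.accumulator_score,
        }


@dataclass
class ThicknessMap:
    """Projected sphere thickness h(x, y) in µm on the phase grid."""

    h: np.ndarray
    pixel_um: float
    fit: SphereFit


def _kasa_circle(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float, float]:
    """Algebraic least-squares circle through boundary points."""
    A = np.column_stack([2.0 * rows, 2.0 * cols, np.ones_like(rows)])
    b = rows**2 + cols**2
    (cr, cc, d), *_ = np.linalg.lstsq(A, b, rcond=None)
    radius = float(np.sqrt(d + cr**2 + cc**2))
    return float(cr), float(cc), radius


def fit_sphere(
    phase: PhaseMap,
    radius_range_um: tuple[float, float] = (4.0, 10.0),
    calibration_factor: float = 1.08,
    score_threshold: float = 0.2,
    edge_level_frac: float = 0.05,
) -> SphereFit:
    """Circular Hough transform on the cell's phase profile.

    The boundary is taken as the contour where the phase crosses
    ``edge_level_frac`` of its maximum — the apparent outline of the cell
    in the phase image.  Point-spread-function blur pushes this low-level
    contour *outward*, which is exactly the diameter overestimate the
    calibration divisor corrects (gradient-ridge detectors move inward
    under blur and would not reproduce that bias).  The Hough accumulator
    over integer radii spanning ``radius_range_um`` provides a robust
    initial circle; boundary points near it are then refined with an
    algebraic least-squares circle fit for sub-pixel center and radius,
    and the raw diameter is divided by ``calibration_factor``.

    Ties among equal accumulator maxima break deterministically toward the
    largest radius, then the topmost-leftmost center.
    """
    lo, hi = radius_range_um
    if not 0 < lo < hi:
        raise ValueError("radius range must satisfy 0 < min < max")
    phi_max = phase.phi.max()
    if phi_max <= 0:
        raise NoCircleError("no circle found: flat phase")
    binary = phase.phi > edge_level_frac * phi_max
    edges = binary ^ ndimage.binary_erosion(binary)

    r_lo = max(2, int(np.floor(lo / phase.pixel_um)))
    r_hi = int(np.ceil(hi / phase.pixel_um))
    radii = np.arange(r_lo, r_hi + 1)
    acc = hough_circle(edges, radii, normalize=True)

    # per-radius best score; prefer larger radius on ties
    flat_scores = acc.reshape(len(radii), -1).max(axis=1)
    best_score = flat_scores.max()
    if best_score < score_threshold:
        raise NoCircleError(f"no circle above score threshold ({best_score:.3f})")
    k = int(np.flatnonzero(flat_scores == best_score)[-1])
    plane = acc[k]
    # topmost-leftmost among tied centers
    idx = np.flatnonzero(plane.ravel() == plane.max())[0]
    pk_r, pk_c = np.unravel_index(idx, plane.shape)

    # sub-pixel refinement: least-squares circle on marching-squares
    # contour points (exact level crossings) near the Hough circle
    cr, cc, radius_px = float(pk_r), float(pk_c), float(radii[k])
    contours = measure.find_contours(phase.phi, edge_level_frac * phi_max)
    if contours:
        pts = np.concatenate(contours, axis=0)
        dist = np.hypot(pts[:, 0] - pk_r, pts[:, 1] - pk_c)
        near = pts[np.abs(dist - radii[k]) <= 4.0]
        if len(near) >= 6:
            cr, cc, radius_px = _kasa_circle(near[:, 0], near[:, 1])
    fit = SphereFit(
        center_px=(cr, cc),
        diameter_raw_um=2.0 * radius_px * phase.pixel_um,
        calibration_factor=calibration_factor,
        accumulator_score=float(best_score),
    )
    logger.info(
        "fit_sphere: center=(%.2f, %.2f) px, D_raw=%.3f µm, D=%.3f µm, score=%.3f",
        *fit.center_px, fit.diameter_raw_um, fit.diameter_um, fit.accumulator_score,
    )
    return fit


def thickness_map(fit: SphereFit, shape: tuple[int, int], pixel_um: float) -> ThicknessMap:
    """Projected thickness h = 2·sqrt(R² − r²) inside the fitted disc."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    r_um = np.hypot(yy - fit.center_px[0], xx - fit.center_px[1]) * pixel_um
    R = fit.radius_um
    inside = r_um < R
    h = np.zeros(shape, dtype=float)
    h[inside] = 2.0 * np.sqrt(R * R - r_um[inside] ** 2)
    return ThicknessMap(h=h, pixel_um=pixel_um, fit=fit)
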