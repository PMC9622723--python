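"""Biophysical parameters from the phase map: refractive index, dry mass,
and the two-component (dry + fluid) mixture model.

The phase delay of a spherical cell factorizes as
φ = (2π/λ_Q)·Δn·h, so the known thickness map h(x, y) turns the phase
image into a refractive-index map.  The integrated phase gives the dry
(non-aqueous) mass through the refractive-index increment α, and the
mixture model splits the cell volume into a protein-like dry compartment
(ρ_dry = 1.37 pg/µm³) and a water-like fluid compartment, yielding the
absolute density and the water content by mass and by volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .constants import NM_TO_UM, PhysicalConstants
from .geometry import SphereFit, ThicknessMap
from .holography import PhaseMap


class MixtureResult(NamedTuple):
    v_cell_um3: float
    v_dry_um3: float
    v_fluid_um3: float
    m_fluid_pg: float
    rho_g_per_ml: float
    u_h2o_pct: float
    theta_h2o_pct: float


@dataclass(frozen=True)
class CellBiophysics:
    """The nine QPI-derived whole-cell quantities (plus the fluid mass)."""

    diameter_um: float
    v_cell_um3: float
    n_cell_mean: float
    m_dry_pg: float
    v_dry_um3: float
    v_fluid_um3: float
    m_fluid_pg: float
    rho_g_per_ml: float
    u_h2o_pct: float
    theta_h2o_pct: float


def ri_map(phase: PhaseMap, thick: ThicknessMap) -> np.ndarray:
    """Refractive-index contrast Δn = (λ_Q/2π)·φ/h where h > 0, NaN outside."""
    if phase.shape != thick.h.shape:
        raise ValueError("phase and thickness grids differ")
    lam_um = phase.lambda_q_nm * NM_TO_UM
    with np.errstate(divide="ignore", invalid="ignore"):
        dn = (lam_um / (2.0 * np.pi)) * phase.phi / thick.h
    dn[thick.h <= 0] = np.nan
    return dn


def mean_ri(
    dn: np.ndarray,
    fit: SphereFit,
    consts: PhysicalConstants,
    pixel_um: float,
    edge_exclusion: float = 0.1,
) -> float:
    """Mean cell refractive index n̄ = ⟨Δn⟩ + n_medium.

    The average runs over pixels with r ≤ (1 − edge_exclusion)·R, i.e. a
    band of width R/10 inside the fitted boundary is excluded to avoid
    edge artifacts.
    """
    yy, xx = np.mgrid[0:dn.shape[0], 0:dn.shape[1]]
    r_um = np.hypot(yy - fit.center_px[0], xx - fit.center_px[1]) * pixel_um
    keep = (r_um <= (1.0 - edge_exclusion) * fit.radius_um) & np.isfinite(dn)
    if not keep.any():
        raise ValueError("no valid interior pixels after edge exclusion")
    return float(np.mean(dn[keep]) + consts.n_medium)


def dry_mass(phase: PhaseMap, mask: np.ndarray, consts: PhysicalConstants) -> float:
    """Dry mass m_dry = (λ_Q / 2πα) ∬ φ dA in picograms.

    λ_Q enters in µm and α in µm³/pg (numerically equal to mL/g), so with
    the pixel area in µm² the result is directly in pg.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != phase.shape:
        raise ValueError("mask shape must match phase")
    lam_um = phase.lambda_q_nm * NM_TO_UM
    alpha_um3_per_pg = consts.alpha_ml_per_g  # exact unit identity
    integral = float(np.sum(phase.phi[mask])) * phase.pixel_um**2
    m = lam_um / (2.0 * np.pi * alpha_um3_per_pg) * integral
    if m < 0:
        warnings.warn("negative integrated phase: dry mass is noise-dominated")
    return m


def mixture_model(
    diameter_um: float, m_dry_pg: float, consts: PhysicalConstants
) -> MixtureResult:
    """Two-component decomposition of the cell.

    V_cell = (4/3)π(D/2)³;  V_dry = m_dry/ρ_dry;  V_fluid = V_cell − V_dry;
    m_fluid = ρ_fluid·V_fluid;  ρ = (m_dry + m_fluid)/V_cell;
    θ_H2O = 100·V_fluid/V_cell;  u_H2O = 100·m_fluid/(m_fluid + m_dry).
    """
    if not diameter_um > 0:
        raise ValueError("diameter must be positive")
    v_cell = (4.0 / 3.0) * np.pi * (diameter_um / 2.0) ** 3
    v_dry = m_dry_pg / consts.rho_dry_pg_per_um3
    if v_dry > v_cell:
        raise ValueError("dry volume exceeds cell volume")
    v_fluid = v_cell - v_dry
    m_fluid = consts.rho_fluid_pg_per_um3 * v_fluid
    rho = (m_dry_pg + m_fluid) / v_cell  # pg/µm³ == g/mL
    theta = 100.0 * v_fluid / v_cell
    total_mass = m_fluid + m_dry_pg
    u = 100.0 * m_fluid / total_mass if total_mass > 0 else 100.0
    return MixtureResult(v_cell, v_dry, v_fluid, m_fluid, rho, u, theta)


def cell_biophysics(
    phase: PhaseMap,
    fit: SphereFit,
    mask: np.ndarray,
    consts: PhysicalConstants,
    dry_mass_domain: str = "mask",
    mask_dilation_px: int = 12,
) -> CellBiophysics:
    """Full QPI parameter set for one cell.

    ``dry_mass_domain`` selects the integration domain for the dry-mass
    integral: the segmentation mask dilated by ``mask_dilation_px``
    (default; a generous crop that captures the low-phase rim the
    threshold-based mask clips, as a manual crop would) or the fitted
    disc.  Background pixels swept in contribute only their ≈0 residual
    phase.
    """
    thick = _thickness_for(phase, fit)
    dn = ri_map(phase, thick)
    n_mean = mean_ri(dn, fit, consts, phase.pixel_um)
    if dry_mass_domain == "mask":
        domain = np.asarray(mask, dtype=bool)
        if mask_dilation_px > 0:
            domain = ndimage.binary_dilation(
                domain, structure=np.ones((3, 3)), iterations=mask_dilation_px)
    elif dry_mass_domain == "disc":
        domain = thick.h > 0
    else:
        raise ValueError("dry_mass_domain must be 'mask' or 'disc'")
    m_dry = dry_mass(phase, domain, consts)
    mix = mixture_model(fit.diameter_um, m_dry, consts)
    return CellBiophysics(
        diameter_um=fit.diameter_um,
        v_cell_um3=mix.v_cell_um3,
        n_cell_mean=n_mean,
        m_dry_pg=m_dry,
        v_dry_um3=mix.v_dry_um3,
        v_fluid_um3=mix.v_fluid_um3,
        m_fluid_pg=mix.m_fluid_pg,
        rho_g_per_ml=mix.rho_g_per_ml,
        u_h2o_pct=mix.u_h2o_pct,
        theta_h2o_pct=mix.theta_h2o_pct,
    )


def _thickness_for(phase: PhaseMap, fit: SphereFit) -> ThicknessMap:
    from .geometry import thickness_map

    return thickness_map(fit, phase.shape, phase.pixel_um)
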