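"""Longitudinal viscoelastic moduli from Brillouin and QPI quantities.

At GHz frequencies the acoustic response of the cell is characterized by
the complex longitudinal modulus M = M′ + iM″:

    M′  = ρ (ν_B λ_B / 2n̄)²          (storage)
    M″  = ρ Γ_B ν_B (λ_B / 2n̄)²      (loss)
    η   = M″ / (2π ν_B)               (longitudinal viscosity)
    tanφ = M″ / M′                    (loss tangent)

with ρ the mass density and n̄ the mean refractive index measured by QPI,
so no literature assumption for either is needed.  Unit conversions
(g/mL → kg/m³, GHz → Hz, nm → m, Pa → GPa) are centralized in
:mod:`brimphase.constants`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import G_PER_ML_TO_KG_PER_M3, GHZ_TO_HZ, NM_TO_M, PA_TO_GPA


@dataclass(frozen=True)
class ViscoelasticResult:
    m_prime_gpa: float
    m_dprime_gpa: float
    eta_pa_s: float
    loss_tangent: float

    @property
    def complex_modulus_gpa(self) -> complex:
        return complex(self.m_prime_gpa, self.m_dprime_gpa)


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


def longitudinal_modulus(
    rho_g_per_ml: float, nu_b_ghz: float, n_cell: float, lambda_b_nm: float
) -> float:
    """Storage modulus M′ = ρ·(ν_B·λ_B/(2n̄))² in GPa."""
    _check_positive(rho_g_per_ml=rho_g_per_ml, n_cell=n_cell, lambda_b_nm=lambda_b_nm)
    if nu_b_ghz < 0:
        raise ValueError("nu_b_ghz must be non-negative")
    if nu_b_ghz == 0:
        warnings.warn("nu_B = 0: nonphysical, M' = 0")
    v = nu_b_ghz * GHZ_TO_HZ * lambda_b_nm * NM_TO_M / (2.0 * n_cell)
    return rho_g_per_ml * G_PER_ML_TO_KG_PER_M3 * v * v * PA_TO_GPA


def loss_modulus(
    rho_g_per_ml: float,
    gamma_b_ghz: float,
    nu_b_ghz: float,
    n_cell: float,
    lambda_b_nm: float,
) -> float:
    """Loss modulus M″ = ρ·Γ_B·ν_B·(λ_B/(2n̄))² in GPa."""
    _check_positive(rho_g_per_ml=rho_g_per_ml, nu_b_ghz=nu_b_ghz,
                    n_cell=n_cell, lambda_b_nm=lambda_b_nm)
    if gamma_b_ghz < 0:
        raise ValueError("gamma_b_ghz must be non-negative")
    scale = lambda_b_nm * NM_TO_M / (2.0 * n_cell)
    return (rho_g_per_ml * G_PER_ML_TO_KG_PER_M3
            * gamma_b_ghz * GHZ_TO_HZ * nu_b_ghz * GHZ_TO_HZ
            * scale * scale * PA_TO_GPA)


def longitudinal_viscosity(m_dprime_gpa: float, nu_b_ghz: float) -> float:
    """η = M″/(2π·ν_B) in Pa·s."""
    if not nu_b_ghz > 0:
        raise ValueError("nu_b_ghz must be positive")
    return m_dprime_gpa / PA_TO_GPA / (2.0 * np.pi * nu_b_ghz * GHZ_TO_HZ)


def loss_tangent(m_prime_gpa: float, m_dprime_gpa: float) -> float:
    """tanφ = M″/M′."""
    if not m_prime_gpa > 0:
        raise ValueError("m_prime must be positive")
    return m_dprime_gpa / m_prime_gpa


def viscoelastic_params(
    rho_g_per_ml: float,
    nu_b_ghz: float,
    gamma_b_ghz: float,
    n_cell: float,
    lambda_b_nm: float = 532.0,
) -> ViscoelasticResult:
    """All four viscoelastic quantities; the identities tanφ·M′ = M″ and
    2π·ν_B·η = M″ hold exactly by construction."""
    m_prime = longitudinal_modulus(rho_g_per_ml, nu_b_ghz, n_cell, lambda_b_nm)
    m_dprime = loss_modulus(rho_g_per_ml, gamma_b_ghz, nu_b_ghz, n_cell, lambda_b_nm)
    return ViscoelasticResult(
        m_prime_gpa=m_prime,
        m_dprime_gpa=m_dprime,
        eta_pa_s=longitudinal_viscosity(m_dprime, nu_b_ghz),
        loss_tangent=loss_tangent(m_prime, m_dprime),
    )
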