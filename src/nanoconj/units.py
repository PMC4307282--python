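"""Unit conversions and physical constants.

Interface units follow laboratory convention (nm for sizes, ug/mL for
protein concentrations, g and mL for the colloid); SI is used internally.
All conversions in the package route through this module.
"""

import math

AVOGADRO = 6.02214076e23  # mol^-1 (exact, SI 2019)

GOLD_DENSITY_KG_M3 = 19300.0

#: protein partial specific volume, cm^3/g — the standard value for
#: globular proteins, used for MW -> sphere-equivalent diameter
PARTIAL_SPECIFIC_VOLUME_CM3_G = 0.73

NM_TO_M = 1e-9
M3_TO_NM3 = 1e27
CM3_TO_NM3 = 1e21


def sphere_volume_m3(diameter_nm: float) -> float:
    """Volume of a sphere of the given diameter (nm), in m^3: (pi/6) d^3."""
    from .exceptions import DomainError

    if diameter_nm <= 0:
        raise DomainError(f"diameter must be positive, got {diameter_nm} nm")
    d_m = diameter_nm * NM_TO_M
    return math.pi / 6.0 * d_m**3


def ug_per_ml_to_nM(c_ug_per_ml: float, molecular_weight_kda: float) -> float:
    """Convert a mass concentration (ug/mL == mg/L) to nmol/L.

    c [mg/L] / MW [g/mol] gives mmol/L; x1e6 gives nM.
    """
    from .exceptions import DomainError

    if molecular_weight_kda <= 0:
        raise DomainError("molecular weight must be positive")
    return c_ug_per_ml / (molecular_weight_kda * 1000.0) * 1e6


def nM_to_ug_per_ml(c_nM: float, molecular_weight_kda: float) -> float:
    """Inverse of :func:`ug_per_ml_to_nM`."""
    from .exceptions import DomainError

    if molecular_weight_kda <= 0:
        raise DomainError("molecular weight must be positive")
    return c_nM * (molecular_weight_kda * 1000.0) / 1e6


def per_ml_to_nM(n_per_ml: float) -> float:
    """Particle number concentration (mL^-1) to molar concentration (nM)."""
    return n_per_ml * 1000.0 / AVOGADRO * 1e9
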