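"""Colloid arithmetic: per-particle mass and number/molar concentration.

A gold sol is described by the TEM mean diameter, the bulk density of gold
and the total gold mass concentration of the preparation. Treating every
particle as a sphere at the mean diameter, the chain

    volume -> mass of one particle -> particles per mL -> particle molarity

converts the synthesis-recipe quantities into the receptor concentration
[R0] needed for stoichiometry. A post-centrifugation concentration factor
(pellet redissolved in a smaller volume) multiplies the number
concentration when requested.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import units
from .exceptions import DomainError, InsufficientDataError

__all__ = [
    "ParticleBatch",
    "SizeSample",
    "SizeSummary",
    "sphere_volume",
    "particle_mass",
    "number_concentration",
    "molar_concentration",
    "size_summary",
]


@dataclass(frozen=True)
class ParticleBatch:
    """Physical description of a nanoparticle preparation.

    Parameters
    ----------
    diameter_nm
        Mean particle diameter from electron microscopy.
    density_kg_m3
        Bulk density of the particle material (gold by default).
    gold_mass_concentration_g_l
        Total metal mass per litre of sol.
    concentration_factor
        Enrichment after pelleting and redissolution (>= 1); the five-fold
        value corresponds to resuspending the pellet in one fifth of the
        original volume.
    """

    diameter_nm: float
    density_kg_m3: float = units.GOLD_DENSITY_KG_M3
    gold_mass_concentration_g_l: float = 0.05
    concentration_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise DomainError("diameter must be positive")
        if self.density_kg_m3 <= 0:
            raise DomainError("density must be positive")
        if self.gold_mass_concentration_g_l < 0:
            raise DomainError("gold mass concentration must be nonnegative")
        if self.concentration_factor < 1:
            raise DomainError("concentration factor must be >= 1")


@dataclass(frozen=True)
class SizeSample:
    """Raw TEM measurements: diameters (nm) and optional axial ratios.

    Axial ratios are normalized to >= 1 (major over minor axis).
    """

    diameters_nm: Sequence[float]
    axial_ratios: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.diameters_nm):
            raise DomainError("all diameters must be positive")
        if self.axial_ratios is not None:
            if any(a <= 0 for a in self.axial_ratios):
                raise DomainError("axial ratios must be positive")
            normalized = tuple(a if a >= 1 else 1.0 / a for a in self.axial_ratios)
            object.__setattr__(self, "axial_ratios", normalized)


@dataclass(frozen=True)
class SizeSummary:
    mean_diameter_nm: float
    sd_diameter_nm: float
    n: int
    mean_axial_ratio: Optional[float] = None
    sd_axial_ratio: Optional[float] = None


def sphere_volume(diameter_nm: float) -> float:
    """Particle volume (m^3) of a sphere with the given diameter (nm)."""
    return units.sphere_volume_m3(diameter_nm)


def particle_mass(batch: ParticleBatch) -> float:
    """Mass of a single particle in grams: volume x density."""
    v_m3 = sphere_volume(batch.diameter_nm)
    return v_m3 * batch.density_kg_m3 * 1000.0  # kg -> g


def number_concentration(batch: ParticleBatch, apply_factor: bool = False) -> float:
    """Particles per millilitre of sol.

    Total gold mass per mL divided by the mass of one particle; multiplied
    by the concentration factor when ``apply_factor`` is set.
    """
    m_g = particle_mass(batch)
    if m_g <= 0:
        raise DomainError("particle mass must be positive")
    n_per_ml = (batch.gold_mass_concentration_g_l / 1000.0) / m_g
    if apply_factor:
        n_per_ml *= batch.concentration_factor
    return n_per_ml


def molar_concentration(batch: ParticleBatch, apply_factor: bool = False) -> float:
    """Particle molar concentration in nM (number per litre / Avogadro)."""
    return units.per_ml_to_nM(number_concentration(batch, apply_factor=apply_factor))


def size_summary(sample: SizeSample) -> SizeSummary:
    """Mean and sample (n-1) standard deviation of diameters and, if
    present, axial ratios."""
    d = list(sample.diameters_nm)
    if len(d) < 2:
        raise InsufficientDataError("need at least 2 diameter measurements")
    mean_a = sd_a = None
    if sample.axial_ratios is not None:
        a = list(sample.axial_ratios)
        if len(a) < 2:
            raise InsufficientDataError("need at least 2 axial-ratio measurements")
        mean_a = statistics.fmean(a)
        sd_a = statistics.stdev(a)
    return SizeSummary(
        mean_diameter_nm=statistics.fmean(d),
        sd_diameter_nm=statistics.stdev(d),
        n=len(d),
        mean_axial_ratio=mean_a,
        sd_axial_ratio=sd_a,
    )
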