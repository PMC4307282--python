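"""Analytic monolayer-capacity estimate for a spherical particle.

A globular protein occupies a circular footprint on the particle surface.
Placing the footprint disks on the mid-layer sphere of radius R + r_p
(through the protein centers) and allowing an ideal hexagonal packing
fraction, the capacity is

    capacity = floor( phi * 4*pi*(R + r_p)^2 / (pi * r_p^2) )

which replaces explicit geometric placement of structural models. Measured
site counts are compared with this capacity to judge whether adsorption is
consistent with a single protein layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

from . import units
from .binding import ProteinSpec
from .exceptions import DomainError

__all__ = [
    "PackingModel",
    "footprint_from_mw",
    "monolayer_capacity",
    "monolayer_consistency",
    "sphere_count_from_octant",
    "HEXAGONAL_PACKING_FRACTION",
]

#: ideal packing fraction of equal circles in the plane (hexagonal lattice)
HEXAGONAL_PACKING_FRACTION = 0.9069


@dataclass(frozen=True)
class PackingModel:
    """Geometry of the monolayer: particle diameter, protein footprint
    diameter (both nm) and the in-plane packing fraction."""

    particle_diameter_nm: float
    protein_footprint_nm: float
    packing_fraction: float = HEXAGONAL_PACKING_FRACTION

    def __post_init__(self) -> None:
        if self.particle_diameter_nm <= 0 or self.protein_footprint_nm <= 0:
            raise DomainError("diameters must be positive")
        if not (0 < self.packing_fraction <= 1):
            raise DomainError("packing fraction must be in (0, 1]")


def footprint_from_mw(protein: ProteinSpec) -> float:
    """Sphere-equivalent footprint diameter (nm) from molecular weight.

    Uses the molecular volume MW*vbar/N_A with partial specific volume
    vbar = 0.73 cm^3/g: d = 2 * (3 * V / (4*pi))^(1/3). Applied only when
    no explicit footprint is supplied (non-globular proteins such as IgG
    should override it).
    """
    if protein.footprint_diameter_nm is not None:
        return protein.footprint_diameter_nm
    v_cm3 = (
        protein.molecular_weight_kda
        * 1000.0
        * units.PARTIAL_SPECIFIC_VOLUME_CM3_G
        / units.AVOGADRO
    )
    v_nm3 = v_cm3 * units.CM3_TO_NM3
    return 2.0 * (3.0 * v_nm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def monolayer_capacity(model: PackingModel, mid_layer: bool = True) -> int:
    """Number of footprint disks fitting in one layer on the particle.

    With ``mid_layer`` (default) the disks tile the sphere of radius
    R + r_p carrying the protein centers; without it, the bare particle
    surface is divided (available for comparison).
    """
    r_particle = model.particle_diameter_nm / 2.0
    r_p = model.protein_footprint_nm / 2.0
    radius = r_particle + r_p if mid_layer else r_particle
    area = 4.0 * math.pi * radius**2
    per_protein = math.pi * r_p**2
    return int(math.floor(model.packing_fraction * area / per_protein))


def monolayer_consistency(
    measured_n: float,
    model: PackingModel,
    band: Tuple[float, float] = (0.5, 1.5),
    mid_layer: bool = True,
) -> Tuple[float, str]:
    """Compare a measured site count with the analytic capacity.

    Returns (ratio, verdict): "monolayer-consistent" when the ratio lies
    inside ``band``, "sub-monolayer" below it, "multilayer-suspect" above.
    The generous band absorbs non-ideal packing and orientational effects.
    """
    if measured_n <= 0:
        raise DomainError("measured N must be positive")
    capacity = monolayer_capacity(model, mid_layer=mid_layer)
    ratio = measured_n / capacity
    if ratio < band[0]:
        verdict = "sub-monolayer"
    elif ratio > band[1]:
        verdict = "multilayer-suspect"
    else:
        verdict = "monolayer-consistent"
    return ratio, verdict


def sphere_count_from_octant(per_octant: int) -> int:
    """Scale a per-octant placement count (1/8 of the sphere surface) to
    the full sphere."""
    if per_octant < 0:
        raise DomainError("count must be nonnegative")
    return 8 * per_octant
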