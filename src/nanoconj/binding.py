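"""Mass-balance stoichiometry: from fluorescence differences to molecules
bound per particle.

The bound fraction of added protein follows from comparing calibration and
supernatant fluorescence at the same nominal concentration,

    (C0 - C_unbound)/C0 = (F0 - F)/F0,

and the per-particle stoichiometry from scaling by the molar ratio of
ligand to particles,

    RL = [(F0 - F)/F0] * [L0]/[R0].

``build_isotherm`` runs the full chain: invert supernatant readings through
the calibration curve, enforce mass conservation, convert to molar units and
divide by the particle concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import units
from .calibration import CalibrationCurve, FluorescenceSeries, invert_concentration
from .exceptions import DomainError, PairingError
from .particles import ParticleBatch, molar_concentration

__all__ = [
    "ProteinSpec",
    "BindingPoint",
    "bound_fraction",
    "molecules_per_particle",
    "mass_to_molar",
    "build_isotherm",
    "isotherm_to_dataframe",
]

#: saturation diagnostic: RL within this relative tolerance of the running
#: maximum over two successive concentrations is flagged "saturated"
DEFAULT_SATURATION_TOL = 0.05


@dataclass(frozen=True)
class ProteinSpec:
    """A protein ligand: name, molecular weight (kD), optional adsorption
    footprint diameter (nm) and PDB accession (metadata only)."""

    name: str
    molecular_weight_kda: float
    footprint_diameter_nm: Optional[float] = None
    pdb_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.molecular_weight_kda <= 0:
            raise DomainError("molecular weight must be positive")
        if self.footprint_diameter_nm is not None and self.footprint_diameter_nm <= 0:
            raise DomainError("footprint diameter must be positive")

    @property
    def inverse_mw(self) -> float:
        return 1.0 / self.molecular_weight_kda


@dataclass(frozen=True)
class BindingPoint:
    """One added-concentration condition of the binding experiment."""

    added_ug_ml: float          # C0 == [L0] on the mass scale
    added_nM: float             # [L0]
    f0: float
    f: float
    unbound_ug_ml: float        # C_unbound == [L] on the mass scale
    unbound_nM: float           # [L]
    bound_ug_ml: float          # C_conjugated = C0 - C_unbound
    bound_nM: float
    rl: float                   # molecules per particle
    censored: bool = False      # unbound below detection limit
    clamped: bool = False       # F > F0 noise clamped to zero binding
    saturated: bool = False


def bound_fraction(f0: float, f: float) -> Tuple[float, bool]:
    """Fraction of added protein bound, (F0 - F)/F0, clamped to [0, 1].

    Returns ``(fraction, clamped)``; the flag is set when noise pushed the
    raw value outside [0, 1] (e.g. F > F0).
    """
    if f0 <= 0:
        raise DomainError("F0 must be positive")
    raw = (f0 - f) / f0
    if raw < 0.0:
        return 0.0, True
    if raw > 1.0:
        return 1.0, True
    return raw, False


def molecules_per_particle(
    f0: float, f: float, l0_nM: float, r0_nM: float
) -> float:
    """RL = bound fraction x [L0]/[R0] (molecules per particle)."""
    if r0_nM <= 0:
        raise DomainError("[R0] must be positive")
    frac, _ = bound_fraction(f0, f)
    return frac * l0_nM / r0_nM


def mass_to_molar(c_ug_ml: float, protein: ProteinSpec) -> float:
    """ug/mL -> nM for the given protein."""
    return units.ug_per_ml_to_nM(c_ug_ml, protein.molecular_weight_kda)


def build_isotherm(
    curve: CalibrationCurve,
    samples: FluorescenceSeries,
    protein: ProteinSpec,
    batch: ParticleBatch,
    f0_series: Optional[FluorescenceSeries] = None,
    r0_nM: Optional[float] = None,
    apply_factor: bool = True,
    saturation_tol: float = DEFAULT_SATURATION_TOL,
) -> List[BindingPoint]:
    """Per-concentration binding points from supernatant readings.

    For each design concentration the supernatant intensity is inverted to
    the unbound concentration (0 with a censoring flag when below the
    detection limit — there, virtually all added protein is adsorbed), the
    bound amount follows by mass balance, and RL by division with the
    particle molarity [R0] (concentration factor applied by default).

    ``f0_series`` optionally supplies measured calibration intensities F0
    paired by concentration; otherwise F0 is taken from the fitted curve.
    Points above the calibration valid range are dropped.
    """
    if r0_nM is None:
        r0_nM = molar_concentration(batch, apply_factor=apply_factor)
    if r0_nM <= 0:
        raise DomainError("[R0] must be positive")

    c_samp, f_samp = samples.replicate_means()
    if len(c_samp) == 0:
        raise PairingError("samples series is empty")

    f0_map = None
    if f0_series is not None:
        c0, f0_vals = f0_series.replicate_means()
        f0_map = dict(zip(c0.tolist(), f0_vals.tolist()))

    lo, hi = curve.valid_range_ug_ml
    points: List[BindingPoint] = []
    for c0_i, f_i in zip(c_samp, f_samp):
        if c0_i > hi or c0_i <= 0:
            continue
        if f0_map is not None:
            if c0_i not in f0_map:
                raise PairingError(
                    f"no calibration reading F0 at {c0_i} ug/mL"
                )
            f0_i = f0_map[c0_i]
        else:
            f0_i = float(curve.predict(c0_i))
        inv = invert_concentration(curve, f_i)
        unbound = min(inv.concentration_ug_ml, c0_i)  # mass conservation
        clamped = inv.concentration_ug_ml > c0_i
        bound = c0_i - unbound
        l0_nM = mass_to_molar(c0_i, protein)
        unbound_nM = mass_to_molar(unbound, protein)
        bound_nM = l0_nM - unbound_nM
        points.append(
            BindingPoint(
                added_ug_ml=float(c0_i),
                added_nM=l0_nM,
                f0=f0_i,
                f=float(f_i),
                unbound_ug_ml=unbound,
                unbound_nM=unbound_nM,
                bound_ug_ml=bound,
                bound_nM=bound_nM,
                rl=bound_nM / r0_nM,
                censored=inv.censored,
                clamped=clamped,
            )
        )
    points.sort(key=lambda p: p.added_ug_ml)
    return _flag_saturation(points, saturation_tol)


def _flag_saturation(
    points: List[BindingPoint], tol: float
) -> List[BindingPoint]:
    """Flag points whose RL stays within ``tol`` of the running maximum over
    two successive concentrations (reporting diagnostic only)."""
    out: List[BindingPoint] = []
    running_max = 0.0
    streak = 0
    for p in points:
        running_max = max(running_max, p.rl)
        near_max = running_max > 0 and p.rl >= (1.0 - tol) * running_max
        streak = streak + 1 if near_max else 0
        out.append(
            BindingPoint(**{**p.__dict__, "saturated": streak >= 2})
        )
    return out


def isotherm_to_dataframe(points: List[BindingPoint]) -> pd.DataFrame:
    """Tabular isotherm in the documented CSV layout."""
    return pd.DataFrame(
        {
            "L0_ug_ml": [p.added_ug_ml for p in points],
            "L0_nM": [p.added_nM for p in points],
            "F0": [p.f0 for p in points],
            "F": [p.f for p in points],
            "C_unbound_ug_ml": [p.unbound_ug_ml for p in points],
            "C_bound_ug_ml": [p.bound_ug_ml for p in points],
            "L_free_nM": [p.unbound_nM for p in points],
            "RL": [p.rl for p in points],
            "censored": [p.censored for p in points],
            "saturated": [p.saturated for p in points],
        }
    )
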