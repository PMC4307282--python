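"""Run configuration loaded from JSON or YAML.

Example document::

    particle:
      diameter_nm: 24
      density_kg_m3: 19300
      gold_g_per_l: 0.05
      concentration_factor: 5
    proteins:
      - name: BSA
        molecular_weight_kda: 66
        footprint_nm: null        # optional; derived from MW when absent
        calibration_csv: calib_bsa.csv
        samples_csv: samples_bsa.csv
    options:
      range_limit_ug_ml: 125
      detection_limit_ug_ml: 0.5
      window_ug_ml: [16, 125]
      packing_fraction: 0.9069
      apply_concentration_factor: true
    output_dir: out
    seed: 1
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple

import yaml

from .calibration import DEFAULT_DETECTION_LIMIT_UG_ML, DEFAULT_RANGE_LIMIT_UG_ML
from .packing import HEXAGONAL_PACKING_FRACTION
from .particles import ParticleBatch
from .scatchard import DEFAULT_WINDOW_UG_ML

__all__ = ["ProteinConfig", "AnalysisOptions", "RunConfig", "load_config"]


@dataclass(frozen=True)
class ProteinConfig:
    name: str
    molecular_weight_kda: float
    calibration_csv: Optional[str] = None
    samples_csv: Optional[str] = None
    footprint_nm: Optional[float] = None


@dataclass(frozen=True)
class AnalysisOptions:
    range_limit_ug_ml: float = DEFAULT_RANGE_LIMIT_UG_ML
    detection_limit_ug_ml: float = DEFAULT_DETECTION_LIMIT_UG_ML
    window_ug_ml: Tuple[float, float] = DEFAULT_WINDOW_UG_ML
    k_low: Optional[int] = None
    k_high: Optional[int] = None
    packing_fraction: float = HEXAGONAL_PACKING_FRACTION
    apply_concentration_factor: bool = True
    consistency_band: Tuple[float, float] = (0.5, 1.5)
    force_zero_intercept: bool = False


@dataclass(frozen=True)
class RunConfig:
    particle: ParticleBatch
    proteins: List[ProteinConfig]
    options: AnalysisOptions = field(default_factory=AnalysisOptions)
    output_dir: str = "out"
    seed: int = 0


def _load_document(path: Path) -> Dict[str, Any]:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_config(path) -> RunConfig:
    """Parse a JSON/YAML config document; field errors name their path."""
    path = Path(path)
    doc = _load_document(path)
    try:
        pb = doc["particle"]
        particle = ParticleBatch(
            diameter_nm=float(pb["diameter_nm"]),
            density_kg_m3=float(pb.get("density_kg_m3", 19300.0)),
            gold_mass_concentration_g_l=float(pb.get("gold_g_per_l", 0.05)),
            concentration_factor=float(pb.get("concentration_factor", 5.0)),
        )
    except KeyError as e:
        raise ValueError(f"config field particle.{e.args[0]} missing") from e
    proteins = []
    for i, p in enumerate(doc.get("proteins", [])):
        try:
            proteins.append(
                ProteinConfig(
                    name=str(p["name"]),
                    molecular_weight_kda=float(p["molecular_weight_kda"]),
                    calibration_csv=p.get("calibration_csv"),
                    samples_csv=p.get("samples_csv"),
                    footprint_nm=p.get("footprint_nm"),
                )
            )
        except KeyError as e:
            raise ValueError(f"config field proteins[{i}].{e.args[0]} missing") from e
    opts = doc.get("options", {}) or {}
    window = tuple(opts.get("window_ug_ml", DEFAULT_WINDOW_UG_ML))
    options = AnalysisOptions(
        range_limit_ug_ml=float(opts.get("range_limit_ug_ml", DEFAULT_RANGE_LIMIT_UG_ML)),
        detection_limit_ug_ml=float(
            opts.get("detection_limit_ug_ml", DEFAULT_DETECTION_LIMIT_UG_ML)
        ),
        window_ug_ml=(float(window[0]), float(window[1])),
        k_low=opts.get("k_low"),
        k_high=opts.get("k_high"),
        packing_fraction=float(opts.get("packing_fraction", HEXAGONAL_PACKING_FRACTION)),
        apply_concentration_factor=bool(opts.get("apply_concentration_factor", True)),
        consistency_band=tuple(opts.get("consistency_band", (0.5, 1.5))),
        force_zero_intercept=bool(opts.get("force_zero_intercept", False)),
    )
    return RunConfig(
        particle=particle,
        proteins=proteins,
        options=options,
        output_dir=str(doc.get("output_dir", "out")),
        seed=int(doc.get("seed", 0)),
    )
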