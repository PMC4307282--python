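"""Linear fluorescence calibration and inverse prediction.

Tryptophan emission at 350 nm grows linearly with protein concentration
over the working range of the assay; the calibration is fitted in the same
chemical matrix as the samples (the particle-free supernatant) so that
ionic-environment effects cancel. Readings are inverted back to unbound
protein concentrations, with left-censoring at the detection limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateFitError,
    InsufficientDataError,
    UnusableCurveError,
)

__all__ = [
    "FluorescenceSeries",
    "CalibrationCurve",
    "InvertedConcentration",
    "fit_calibration",
    "invert_concentration",
    "compare_matrix_slopes",
    "DEFAULT_RANGE_LIMIT_UG_ML",
    "DEFAULT_DETECTION_LIMIT_UG_ML",
]

#: calibration validity ceiling (ug/mL): above it the absolute fluorescence
#: error exceeds the calibration/sample difference
DEFAULT_RANGE_LIMIT_UG_ML = 125.0

#: smallest unbound concentration the readout resolves (ug/mL)
DEFAULT_DETECTION_LIMIT_UG_ML = 0.5

CSV_COLUMNS = ["protein", "matrix", "added_ug_per_ml", "intensity_350nm", "replicate"]


@dataclass(frozen=True)
class FluorescenceSeries:
    """Fluorescence-vs-concentration readings for one protein in one matrix.

    ``concentrations_ug_ml``, ``intensities`` and ``replicates`` are
    parallel sequences, one entry per reading (replicates appear as
    repeated concentrations).
    """

    protein_name: str
    concentrations_ug_ml: Sequence[float]
    intensities: Sequence[float]
    replicates: Optional[Sequence[int]] = None
    matrix: str = "supernatant"

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_ug_ml, dtype=float)
        f = np.asarray(self.intensities, dtype=float)
        if c.shape != f.shape:
            raise ValueError("concentrations and intensities must align")
        if np.any(c < 0) or np.any(f < 0):
            raise ValueError("concentrations and intensities must be nonnegative")
        object.__setattr__(self, "concentrations_ug_ml", c)
        object.__setattr__(self, "intensities", f)
        if self.replicates is None:
            object.__setattr__(self, "replicates", np.zeros(c.shape, dtype=int))
        else:
            object.__setattr__(
                self, "replicates", np.asarray(self.replicates, dtype=int)
            )

    def replicate_means(self) -> Tuple[np.ndarray, np.ndarray]:
        """Mean intensity per distinct concentration, both sorted by
        concentration."""
        df = pd.DataFrame(
            {"c": self.concentrations_ug_ml, "f": self.intensities}
        )
        g = df.groupby("c", sort=True)["f"].mean()
        return g.index.to_numpy(), g.to_numpy()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": self.protein_name,
                "matrix": self.matrix,
                "added_ug_per_ml": self.concentrations_ug_ml,
                "intensity_350nm": self.intensities,
                "replicate": self.replicates,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "list[FluorescenceSeries]":
        """Split a long-format table into one series per (protein, matrix)."""
        missing = set(CSV_COLUMNS[:4]) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        out = []
        for (protein, matrix), grp in df.groupby(["protein", "matrix"], sort=False):
            reps = grp["replicate"] if "replicate" in grp else None
            out.append(
                cls(
                    protein_name=str(protein),
                    concentrations_ug_ml=grp["added_ug_per_ml"].to_numpy(float),
                    intensities=grp["intensity_350nm"].to_numpy(float),
                    replicates=None if reps is None else reps.to_numpy(int),
                    matrix=str(matrix),
                )
            )
        return out

    @classmethod
    def from_csv(cls, path) -> "list[FluorescenceSeries]":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted line intensity = slope * c + intercept with its working range."""

    slope: float
    intercept: float
    correlation_r: float
    valid_range_ug_ml: Tuple[float, float]
    detection_limit_ug_ml: float = DEFAULT_DETECTION_LIMIT_UG_ML
    n_points: int = 0

    def predict(self, c_ug_ml):
        return self.slope * np.asarray(c_ug_ml, dtype=float) + self.intercept


@dataclass(frozen=True)
class InvertedConcentration:
    concentration_ug_ml: float
    censored: bool  # True when below the detection limit (reported as 0)


def fit_calibration(
    series: FluorescenceSeries,
    range_limit: float = DEFAULT_RANGE_LIMIT_UG_ML,
    detection_limit: float = DEFAULT_DETECTION_LIMIT_UG_ML,
    force_zero_intercept: bool = False,
) -> CalibrationCurve:
    """Ordinary least-squares calibration line over [0, range_limit].

    Replicates are averaged per concentration before fitting; points above
    the range limit are excluded (at high intensity the absolute
    measurement error dominates).
    """
    c, f = series.replicate_means()
    keep = c <= range_limit
    c, f = c[keep], f[keep]
    if len(np.unique(c)) < 2:
        raise InsufficientDataError(
            "need >= 2 distinct concentrations within the range limit"
        )
    if np.ptp(c) == 0:
        raise DegenerateFitError("zero concentration variance")
    if force_zero_intercept:
        slope = float(np.dot(c, f) / np.dot(c, c))
        intercept = 0.0
        r = float(stats.pearsonr(c, f).statistic) if len(c) > 2 else 1.0
    else:
        res = stats.linregress(c, f)
        slope, intercept, r = float(res.slope), float(res.intercept), float(res.rvalue)
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        correlation_r=r,
        valid_range_ug_ml=(float(c.min()), float(min(c.max(), range_limit))),
        detection_limit_ug_ml=detection_limit,
        n_points=len(c),
    )


def invert_concentration(
    curve: CalibrationCurve, intensity: float
) -> InvertedConcentration:
    """Invert a fluorescence reading to a concentration (ug/mL).

    Values below the detection limit (including negative inversions from
    background noise) are reported as 0 with the censoring flag set.
    """
    if curve.slope <= 0:
        raise UnusableCurveError("calibration slope must be positive")
    c = (intensity - curve.intercept) / curve.slope
    if c < curve.detection_limit_ug_ml:
        return InvertedConcentration(0.0, True)
    return InvertedConcentration(float(c), False)


def compare_matrix_slopes(
    series_list: Iterable[FluorescenceSeries],
    reference_matrix: str = "supernatant",
    **fit_kwargs,
) -> pd.DataFrame:
    """Calibration slope per matrix and relative deviation from the
    reference (supernatant) slope, in percent."""
    rows = []
    for s in series_list:
        curve = fit_calibration(s, **fit_kwargs)
        rows.append(
            {"protein": s.protein_name, "matrix": s.matrix, "slope": curve.slope,
             "correlation_r": curve.correlation_r}
        )
    df = pd.DataFrame(rows)
    if reference_matrix not in set(df["matrix"]):
        raise InsufficientDataError(f"no series in reference matrix {reference_matrix!r}")
    ref = df.loc[df["matrix"] == reference_matrix, "slope"].mean()
    df["relative_deviation_pct"] = (df["slope"] - ref) / ref * 100.0
    return df
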