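"""Scatchard analysis with two affinity regimes.

For a single class of N independent sites the bound-per-particle amount RL
and free ligand [L] obey

    RL/[L] = (N - RL)/K_D,

a straight line in (RL, RL/[L]) with slope -1/K_D and x-intercept N.
Adsorption on a crowded particle surface is anti-cooperative: the apparent
affinity falls as coverage rises and the Scatchard cloud bends convexly.
The curve is summarized by two tangent lines — a low-coverage regime giving
K_D^(1) and a near-saturation regime giving K_D^(2) and, from its
x-intercept, the site count N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .binding import BindingPoint, ProteinSpec
from .exceptions import DegenerateFitError, DomainError, InsufficientDataError

__all__ = [
    "ScatchardResult",
    "scatchard_transform",
    "select_analysis_window",
    "two_regime_fit",
    "cooperativity_diagnostic",
    "capacity_vs_inverse_mw",
    "DEFAULT_WINDOW_UG_ML",
]

#: concentration window [lower, upper) retained for the Scatchard fits:
#: below, the unbound signal is too close to background; at and above the
#: upper bound, binding has saturated / the calibration ceiling is reached
DEFAULT_WINDOW_UG_ML = (16.0, 125.0)


@dataclass(frozen=True)
class ScatchardResult:
    """Two-regime Scatchard summary for one protein.

    ``kd1_nM`` is the low-coverage dissociation constant, ``kd2_nM`` the
    near-saturation one; ``n_sites`` comes from the x-intercept of the
    near-saturation line. For anti-cooperative binding kd1 <= kd2.
    """

    kd1_nM: float
    kd2_nM: float
    n_sites: float
    regime_split: Tuple[int, int]  # (points in low regime, points in high regime)
    r_low: float
    r_high: float
    curvature_sign: str  # anti-cooperative | cooperative | linear


def scatchard_transform(
    points: Sequence[BindingPoint],
) -> Tuple[np.ndarray, np.ndarray]:
    """Map binding points to Scatchard coordinates (x=RL, y=RL/[L]).

    Censored points ([L] reported 0) are excluded: the ratio is undefined.
    """
    xs, ys = [], []
    for p in points:
        if p.censored or p.unbound_nM <= 0:
            continue
        xs.append(p.rl)
        ys.append(p.rl / p.unbound_nM)
    if not xs:
        raise InsufficientDataError("all points censored; Scatchard undefined")
    return np.asarray(xs), np.asarray(ys)


def select_analysis_window(
    points: Sequence[BindingPoint],
    lower: float = DEFAULT_WINDOW_UG_ML[0],
    upper: float = DEFAULT_WINDOW_UG_ML[1],
) -> List[BindingPoint]:
    """Retain points with lower <= L0 < upper (ug/mL)."""
    if lower >= upper:
        raise DomainError("window bounds must satisfy lower < upper")
    kept = [p for p in points if lower <= p.added_ug_ml < upper]
    if not kept:
        raise InsufficientDataError("no points inside the analysis window")
    return kept


def _regime_line(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """OLS line for one regime; returns (slope, intercept, r)."""
    if len(x) < 2:
        raise InsufficientDataError("need >= 2 points per regime")
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero RL variance in regime")
    if len(x) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return float(slope), float(y[0] - slope * x[0]), 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def two_regime_fit(
    x: np.ndarray,
    y: np.ndarray,
    k_low: Optional[int] = None,
    k_high: Optional[int] = None,
) -> ScatchardResult:
    """Fit the two tangent lines of the Scatchard curve.

    Points are ranked by RL; the lowest ``k_low`` form the low-coverage
    regime and the highest ``k_high`` the near-saturation regime. By
    default each regime takes ceil(n/2) points, so for odd n the middle
    point belongs to both. K_D in each regime is the negative reciprocal of
    the OLS slope; N is the x-intercept of the near-saturation line only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise InsufficientDataError("need >= 3 Scatchard points")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if k_low is None:
        k_low = math.ceil(n / 2)
    if k_high is None:
        k_high = math.ceil(n / 2)
    if k_low < 2 or k_high < 2 or k_low > n or k_high > n:
        raise InsufficientDataError("each regime needs 2..n points")

    s1, i1, r1 = _regime_line(x[:k_low], y[:k_low])
    s2, i2, r2 = _regime_line(x[n - k_high:], y[n - k_high:])
    if s1 >= 0 or s2 >= 0:
        raise DegenerateFitError(
            "Scatchard regime slope must be negative (got "
            f"{s1:.3g}, {s2:.3g})"
        )
    kd1 = -1.0 / s1
    kd2 = -1.0 / s2
    n_sites = -i2 / s2  # x-intercept of the near-saturation line
    return ScatchardResult(
        kd1_nM=kd1,
        kd2_nM=kd2,
        n_sites=float(n_sites),
        regime_split=(k_low, k_high),
        r_low=r1,
        r_high=r2,
        curvature_sign=cooperativity_diagnostic(x, y) if n >= 4 else "linear",
    )


def cooperativity_diagnostic(x: np.ndarray, y: np.ndarray, t_threshold: float = 2.0) -> str:
    """Classify Scatchard curvature by the sign of the quadratic term.

    A parabola is fitted to (RL, RL/[L]) after scaling both axes to unit
    maximum; a convex cloud (positive quadratic coefficient) signals
    anti-cooperative adsorption, concave signals cooperative, and a
    coefficient indistinguishable from zero (|t| < ``t_threshold``, or an
    exactly linear cloud) is reported as linear.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise InsufficientDataError("need >= 4 points for curvature")
    xs = x / np.max(np.abs(x))
    ys = y / np.max(np.abs(y))
    X = np.column_stack([xs**2, xs, np.ones_like(xs)])
    coef, residuals, *_ = np.linalg.lstsq(X, ys, rcond=None)
    a = coef[0]
    if abs(a) < 1e-8:
        return "linear"
    dof = len(x) - 3
    if dof > 0:
        rss = float(np.sum((ys - X @ coef) ** 2))
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = math.sqrt(cov[0, 0])
        if se > 0 and abs(a) / se < t_threshold:
            return "linear"
    return "anti-cooperative" if a > 0 else "cooperative"


def capacity_vs_inverse_mw(
    results: Sequence[Tuple[ProteinSpec, ScatchardResult]],
) -> Tuple[float, float, float]:
    """OLS of the site count N on 1/MW across proteins.

    The monolayer picture predicts N proportional to the reciprocal
    molecular weight (surface area shared among footprints that scale with
    MW^(2/3), approximately linear in 1/MW over the studied range).
    Returns (slope in molecules*kD, intercept, Pearson r).
    """
    if len(results) < 3:
        raise InsufficientDataError("need >= 3 proteins for the correlation")
    inv_mw = np.array([p.inverse_mw for p, _ in results])
    n = np.array([r.n_sites for _, r in results])
    res = stats.linregress(inv_mw, n)
    return float(res.slope), float(res.intercept), float(res.rvalue)
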