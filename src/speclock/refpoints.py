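"""Time-to-speciation reference points from steepness-classified hybrid zones.

Hybrid zones are classified by cline width into *shallow* (> 50 km, typical
of freely admixing subspecies-level lineages), *steep* (10–50 km) and
*very steep* (< 10 km, typical of reproductively isolated species).  A
bivariate confidence ellipse is fitted to each extreme class in
(log divergence time, log width) space; the divergence time at the
x-maximum of the shallow ellipse marks the age above which reproductive
isolation is presumed complete, the x-minimum of the very-steep ellipse
the age below which it is presumed incomplete.

The *half-time to speciation* inverts the log-log regression of width on
time at a pivot width (30 km by default, the approximate species/
subspecies transition in anurans), with a Fieller-style confidence
interval from the mean-response band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import AnalysisRow, SpeclockError

__all__ = [
    "SteepnessClass",
    "ConfidenceEllipse",
    "ReferencePoints",
    "HalfTimeEstimate",
    "classify_steepness",
    "fit_confidence_ellipse",
    "ellipse_x_extremes",
    "derive_reference_points",
    "half_time",
]

SHALLOW = "shallow"
STEEP = "steep"
VERY_STEEP = "very_steep"
STEEPNESS_CLASSES = (SHALLOW, STEEP, VERY_STEEP)


def classify_steepness(width_km: float) -> str:
    """Three-way width classification; the 10 and 50 km boundaries are steep."""
    if not width_km > 0:
        raise SpeclockError("width must be positive")
    if width_km > 50.0:
        return SHALLOW
    if width_km < 10.0:
        return VERY_STEEP
    return STEEP


@dataclass(frozen=True)
class ConfidenceEllipse:
    center: np.ndarray  # (x, y) = (log T, log w) by default
    covariance: np.ndarray  # 2x2 SPD scatter
    radius: float
    level: float
    n: int


def _mvt_scatter(x: np.ndarray, df: float = 7.0, tol: float = 1e-8, maxiter: int = 500):
    """EM location/scatter of a bivariate t with fixed df (robust estimator)."""
    n = x.shape[0]
    mu = x.mean(axis=0)
    s = np.cov(x, rowvar=False, bias=True)
    for _ in range(maxiter):
        d = x - mu
        inv = np.linalg.inv(s)
        d2 = np.einsum("ij,jk,ik->i", d, inv, d)
        w = (df + 2.0) / (df + d2)
        mu_new = (w[:, None] * x).sum(axis=0) / w.sum()
        d = x - mu_new
        s_new = (w[:, None] * d).T @ d / n
        if np.max(np.abs(s_new - s)) < tol * max(1.0, np.max(np.abs(s))) and np.max(
            np.abs(mu_new - mu)
        ) < tol:
            mu, s = mu_new, s_new
            break
        mu, s = mu_new, s_new
    return mu, s


def fit_confidence_ellipse(
    points: np.ndarray,
    level: float = 0.95,
    estimator: str = "mvt",
    t_df: float = 7.0,
) -> ConfidenceEllipse:
    """Fit a confidence ellipse to a 2-d point cloud.

    ``estimator="sample"`` uses the sample mean and (n-1)-denominator
    covariance; ``"mvt"`` (default) uses the robust EM scatter of a
    bivariate t distribution with ``t_df`` degrees of freedom.  The radius
    is sqrt(2 * F_q(level; 2, n - 1)), so the ellipse boundary is the
    level-set of squared Mahalanobis distance at that quantile.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 3:
        raise SpeclockError("ellipse requires >= 3 bivariate points")
    n = x.shape[0]
    if estimator == "sample":
        center = x.mean(axis=0)
        cov = np.cov(x, rowvar=False)
    elif estimator == "mvt":
        center, cov = _mvt_scatter(x, df=t_df)
    else:
        raise SpeclockError(f"unknown ellipse estimator {estimator!r}")
    det = np.linalg.det(cov)
    scale = max(np.abs(cov).max(), 1e-300)
    if not np.isfinite(det) or det <= 1e-12 * scale**2:
        raise SpeclockError("degenerate ellipse: singular scatter (collinear points?)")
    radius = math.sqrt(2.0 * stats.f.ppf(level, 2, n - 1))
    return ConfidenceEllipse(center=center, covariance=cov, radius=radius, level=level, n=n)


def ellipse_x_extremes(ellipse: ConfidenceEllipse) -> tuple[float, float]:
    """The x-coordinates of the vertical-tangent points of the ellipse.

    For boundary {c + r L u : |u| = 1}, the extreme x values are
    c_x -/+ r * sqrt(Sigma_xx) regardless of the correlation.
    """
    half = ellipse.radius * math.sqrt(ellipse.covariance[0, 0])
    return (float(ellipse.center[0] - half), float(ellipse.center[0] + half))


@dataclass(frozen=True)
class ReferencePoints:
    t_incomplete_ma: float
    t_complete_ma: float
    n_shallow: int
    n_very_steep: int


def derive_reference_points(
    rows: Sequence[AnalysisRow],
    level: float = 0.95,
    estimator: str = "mvt",
    min_markers: int = 3,
    scale: str = "log",
) -> ReferencePoints:
    """Reference divergence times from the shallow and very-steep classes.

    Rows (normally a group's dataset B) are filtered to multi-marker
    average widths (``n_markers_max >= min_markers``), classified by
    steepness, and an ellipse is fitted per extreme class in
    (log T, log w).  t_complete is the x-maximum of the shallow ellipse,
    t_incomplete the x-minimum of the very-steep ellipse, both
    back-transformed to Ma.
    """
    use = [r for r in rows if r.n_markers_max >= min_markers]
    by_class: dict[str, list[AnalysisRow]] = {c: [] for c in STEEPNESS_CLASSES}
    for r in use:
        by_class[classify_steepness(r.width_km)].append(r)
    for cls in (SHALLOW, VERY_STEEP):
        if len(by_class[cls]) < 3:
            raise SpeclockError(
                f"insufficient rows in class {cls!r}: "
                f"{len(by_class[cls])} < 3 after the marker filter"
            )

    def pts(rows_: list[AnalysisRow]) -> np.ndarray:
        x = np.array([[r.divergence_time_ma, r.width_km] for r in rows_], dtype=float)
        return np.log(x) if scale == "log" else x

    ell_shallow = fit_confidence_ellipse(pts(by_class[SHALLOW]), level, estimator)
    ell_steepest = fit_confidence_ellipse(pts(by_class[VERY_STEEP]), level, estimator)
    _, x_max = ellipse_x_extremes(ell_shallow)
    x_min, _ = ellipse_x_extremes(ell_steepest)
    if scale == "log":
        x_max, x_min = math.exp(x_max), math.exp(x_min)
    return ReferencePoints(
        t_incomplete_ma=x_min,
        t_complete_ma=x_max,
        n_shallow=ell_shallow.n,
        n_very_steep=ell_steepest.n,
    )


@dataclass(frozen=True)
class HalfTimeEstimate:
    t_half_ma: float
    ci_low: float
    ci_high: float
    pivot_width_km: float
    slope: float
    slope_t: float
    reliable: bool


def half_time(
    rows: Sequence[AnalysisRow],
    pivot_width_km: float = 30.0,
    level: float = 0.95,
) -> HalfTimeEstimate:
    """Divergence time at which the fitted width crosses the pivot width.

    Ordinary least squares of log w on log T; the point estimate inverts
    the fitted line at w = pivot, and the confidence interval inverts the
    mean-response confidence band at that width (a Fieller-style
    interval).  A slope with |t| < 2 flags the estimate unreliable.
    """
    if len(rows) < 4:
        raise SpeclockError("half_time requires >= 4 rows")
    x = np.log([r.divergence_time_ma for r in rows])
    y = np.log([r.width_km for r in rows])
    n = x.size
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0:
        raise SpeclockError("zero variance in divergence time")
    b = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    a = float(y.mean() - b * xbar)
    resid = y - (a + b * x)
    s2 = float(resid @ resid) / (n - 2)
    se_b = math.sqrt(s2 / sxx) if s2 > 0 else 0.0
    slope_t = b / se_b if se_b > 0 else math.inf * np.sign(b)
    y0 = math.log(pivot_width_km)
    x_hat = (y0 - a) / b
    tq = stats.t.ppf(0.5 + level / 2.0, n - 2)
    # solve (a + b x - y0)^2 = tq^2 s^2 (1/n + (x - xbar)^2 / sxx) for x
    g = tq**2 * s2 / sxx
    A = b**2 - g
    B = 2 * b * (a - y0) + 2 * g * xbar
    C = (a - y0) ** 2 - tq**2 * s2 / n - g * xbar**2
    reliable = abs(slope_t) >= 2 and A > 0
    if A > 0:
        disc = max(0.0, B**2 - 4 * A * C)
        r1 = (-B - math.sqrt(disc)) / (2 * A)
        r2 = (-B + math.sqrt(disc)) / (2 * A)
        lo, hi = min(r1, r2), max(r1, r2)
    else:  # band never closes around the crossing: unbounded interval
        lo, hi = -math.inf, math.inf
    return HalfTimeEstimate(
        t_half_ma=math.exp(x_hat),
        ci_low=math.exp(lo) if math.isfinite(lo) else 0.0,
        ci_high=math.exp(hi) if math.isfinite(hi) else math.inf,
        pivot_width_km=pivot_width_km,
        slope=b,
        slope_t=float(slope_t),
        reliable=bool(reliable),
    )
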