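"""Isotopic-niche summaries in (d13C, d15N) space.

The standard ellipse area (SEA) is pi times the product of the square roots
of the sample-covariance eigenvalues, covering roughly 40% of bivariate
normal data; SEA_c applies the (n-1)/(n-2) small-sample correction. Hull
area is the area of the 2-D convex hull of all individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "NicheSummary",
    "standard_ellipse_area",
    "convex_hull_area",
    "niche_summary",
]


@dataclass(frozen=True)
class NicheSummary:
    n: int
    sea: float
    sea_c: float
    hull_area: float


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (d13C, d15N) pairs")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite values")
    return pts


def standard_ellipse_area(points) -> tuple[float, float]:
    """Return (SEA, SEA_c) in per-mil squared. Needs n >= 3 non-collinear points."""
    pts = _as_points(points)
    n = pts.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points for an ellipse, got {n}")
    cov = np.cov(pts.T, ddof=1)
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals[0] <= 1e-12 * max(eigvals[1], 1.0):
        raise ValueError(
            "points are (near-)collinear: covariance has a zero eigenvalue, "
            "so no ellipse area is defined"
        )
    sea = float(np.pi * np.sqrt(eigvals[0] * eigvals[1]))
    sea_c = sea * (n - 1) / (n - 2)
    return sea, sea_c


def convex_hull_area(points) -> float:
    """Area of the 2-D convex hull of all points (n >= 3)."""
    pts = _as_points(points)
    if pts.shape[0] < 3:
        raise ValueError(f"need at least 3 points for a hull, got {pts.shape[0]}")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError(f"degenerate point set: {exc}") from exc
    return float(hull.volume)  # in 2-D, .volume is the enclosed area


def niche_summary(points) -> NicheSummary:
    pts = _as_points(points)
    sea, sea_c = standard_ellipse_area(pts)
    return NicheSummary(
        n=pts.shape[0], sea=sea, sea_c=sea_c, hull_area=convex_hull_area(pts)
    )
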