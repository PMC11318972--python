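"""Total curvature of bare terminals.

The total curvature of a space curve is the arc-length integral of its
(unsigned Frenet) curvature, integral of kappa(s) ds from the terminal's
branching node to its tip.  For a closed curve forming a full loop this
equals 2*pi.  Because the Frenet curvature kappa = |T'(s)| is non-negative
in 3D, the integral itself is non-negative; terminals with total curvature
above pi/6 (30 degrees) are classed as high-curvature ("curled"), the rest
as low-curvature ("linear").

The estimator fits an interpolating cubic B-spline through the skeleton
points, evaluates derivatives on an oversampled parameter grid and applies
composite Simpson integration.  Polylines too short (or too degenerate) for
a cubic fit fall back to the discrete turning-angle sum, which is also the
independent oracle used in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson
from scipy.interpolate import splev, splprep

from .errors import ValidationError

HIGH_CURVATURE_THRESHOLD = np.pi / 6  # radians

__all__ = [
    "CurvatureResult",
    "total_curvature",
    "turning_angle_total",
    "classify_curvature",
    "curvature_class_proportions",
    "HIGH_CURVATURE_THRESHOLD",
]


@dataclass
class CurvatureResult:
    terminal_id: int
    total_curvature: float
    curvature_class: str  # "high" | "low"
    n_points: int
    method: str  # "spline" | "polyline"


def _dedup(points: np.ndarray, tol: float = 1e-3) -> np.ndarray:
    """Drop near-zero-length segments (< ``tol`` µm) before fitting."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return pts
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg >= tol])
    if not keep.all():
        warnings.warn(
            f"removed {int((~keep).sum())} near-duplicate points before spline fit",
            stacklevel=3,
        )
        # never drop the final point: replace the last kept with it
        pts = pts[keep]
        tail = np.asarray(points, dtype=float)[-1]
        if np.linalg.norm(pts[-1] - tail) >= tol:
            pts = np.vstack([pts, tail])
    return pts


def turning_angle_total(points) -> float:
    """Discrete total curvature: sum of angles between consecutive segments."""
    pts = np.asarray(points, dtype=float)
    v = np.diff(pts, axis=0)
    norms = np.linalg.norm(v, axis=1)
    v = v[norms > 0]
    norms = norms[norms > 0]
    if len(v) < 2:
        return 0.0
    u = v / norms[:, None]
    dots = np.clip(np.einsum("ij,ij->i", u[:-1], u[1:]), -1.0, 1.0)
    return float(np.arccos(dots).sum())


def total_curvature(polyline, oversample: int = 10) -> float:
    """Total curvature (radians) of a 3D polyline by spline integration.

    ``oversample`` controls the evaluation grid (``oversample`` x the number
    of input points).  Polylines with fewer than 4 distinct points, or whose
    spline fit degenerates (e.g. perfectly collinear samples), use the
    discrete turning-angle fallback.
    """
    pts = _dedup(polyline)
    if len(pts) < 2:
        raise ValidationError("total_curvature requires at least 2 distinct points")
    if oversample < 2:
        raise ValidationError("oversample must be >= 2")
    if len(pts) < 4:
        return turning_angle_total(pts)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tck, _ = splprep(pts.T, s=0, k=3)
    except (ValueError, TypeError, np.linalg.LinAlgError):
        return turning_angle_total(pts)
    u = np.linspace(0.0, 1.0, len(pts) * oversample + 1)
    d1 = np.asarray(splev(u, tck, der=1)).T
    d2 = np.asarray(splev(u, tck, der=2)).T
    speed = np.linalg.norm(d1, axis=1)
    if np.any(speed < 1e-12):
        return turning_angle_total(pts)
    cross = np.cross(d1, d2)
    kappa = np.linalg.norm(cross, axis=1) / speed**3
    # integrate kappa ds = kappa |r'(u)| du over the parameter grid
    value = float(simpson(kappa * speed, x=u))
    if not np.isfinite(value):
        return turning_angle_total(pts)
    return value


def classify_curvature(total: float, threshold: float = HIGH_CURVATURE_THRESHOLD) -> str:
    """"high" iff the total curvature strictly exceeds the threshold."""
    if total < 0:
        raise ValidationError("total curvature cannot be negative")
    return "high" if total > threshold else "low"


def curvature_class_proportions(terminals) -> tuple[float, float]:
    """(fraction_low, fraction_high) over a collection of terminals.

    Accepts either :class:`CurvatureResult`-like objects (``curvature_class``
    attribute) or raw total-curvature values.
    """
    classes = []
    for t in terminals:
        cls = getattr(t, "curvature_class", None)
        if cls is None:
            cls = classify_curvature(float(t))
        classes.append(cls)
    if not classes:
        raise ValidationError("cannot compute proportions of an empty collection")
    n = len(classes)
    n_low = sum(1 for c in classes if c == "low")
    return n_low / n, (n - n_low) / n
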