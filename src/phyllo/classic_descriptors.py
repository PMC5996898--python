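"""Traditional leaf shape descriptors: circularity, aspect ratio, solidity.

All three are computed on the polygon defined by the ordered contour (not on
a raster), so they are resolution independent and invariant to translation,
rotation, and uniform scaling:

* circularity = 4*pi*A / P^2 with A the absolute shoelace area and P the
  polygon perimeter; 1 for a circle, lower for elongated or indented shapes;
* aspect ratio = major/minor axis of the moment-equivalent ellipse (the
  ellipse with the same second-order area moments as the filled polygon,
  the ImageJ convention);
* solidity = polygon area / convex hull area, sensitive to lobes, leaflets,
  and petioles.

Display transforms 1/aspect_ratio and solidity^8 spread the typically
skewed empirical distributions of these quantities for visualization.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .contour_io import Contour
from .errors import DegenerateShapeError

__all__ = [
    "ShapeDescriptors",
    "circularity",
    "aspect_ratio",
    "solidity",
    "transform_descriptors",
    "describe",
    "polygon_area",
    "polygon_moments",
]


@dataclasses.dataclass
class ShapeDescriptors:
    """Per-leaf classic descriptor values (see module docstring for definitions)."""

    circularity: float
    aspect_ratio: float
    solidity: float
    inv_aspect_ratio: float = float("nan")
    solidity8: float = float("nan")


def _closed(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=float)
    return pts, np.roll(pts, -1, axis=0)


def polygon_area(points: np.ndarray, signed: bool = False) -> float:
    """Shoelace area of a closed polygon given its vertices in order."""
    p, q = _closed(points)
    cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
    area = 0.5 * float(cross.sum())
    return area if signed else abs(area)


def polygon_moments(points: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Area, centroid, and central second-moment matrix of a filled polygon.

    Returns
    -------
    area : float
        Absolute polygon area.
    centroid : ndarray, shape (2,)
    cov : ndarray, shape (2, 2)
        Central second moments normalized by area, i.e. the covariance of
        the uniform distribution over the polygon interior.
    """
    p, q = _closed(points)
    cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
    a_signed = 0.5 * float(cross.sum())
    if a_signed == 0.0:
        raise DegenerateShapeError("polygon has zero area")
    cx = float(((p[:, 0] + q[:, 0]) * cross).sum()) / (6.0 * a_signed)
    cy = float(((p[:, 1] + q[:, 1]) * cross).sum()) / (6.0 * a_signed)
    exx = float(((p[:, 0] ** 2 + p[:, 0] * q[:, 0] + q[:, 0] ** 2) * cross).sum()) / (
        12.0 * a_signed
    )
    eyy = float(((p[:, 1] ** 2 + p[:, 1] * q[:, 1] + q[:, 1] ** 2) * cross).sum()) / (
        12.0 * a_signed
    )
    exy = float(
        (
            (
                p[:, 0] * q[:, 1]
                + 2.0 * p[:, 0] * p[:, 1]
                + 2.0 * q[:, 0] * q[:, 1]
                + q[:, 0] * p[:, 1]
            )
            * cross
        ).sum()
    ) / (24.0 * a_signed)
    cov = np.array(
        [[exx - cx * cx, exy - cx * cy], [exy - cx * cy, eyy - cy * cy]]
    )
    return abs(a_signed), np.array([cx, cy]), cov


def circularity(c: Contour) -> float:
    """4*pi*area/perimeter^2 of the outline polygon (holes excluded).

    Bounded above by 1 (isoperimetric inequality); self-intersecting
    outlines use the absolute shoelace area with a warning.
    """
    area = polygon_area(c.points, signed=True)
    if area < 0:
        area = -area
    perimeter = c.perimeter()
    if area == 0.0 or perimeter == 0.0:
        raise DegenerateShapeError(
            f"contour {c.id!r}: zero area or perimeter, circularity undefined"
        )
    return float(4.0 * np.pi * area / perimeter**2)


def aspect_ratio(c: Contour) -> float:
    """Major/minor axis ratio of the moment-equivalent fitted ellipse (>= 1).

    A degenerate minor axis (shape collapsed to a line within tolerance)
    returns ``inf`` with a warning rather than raising.
    """
    _, _, cov = polygon_moments(c.points)
    eigvals = np.linalg.eigvalsh(cov)
    lo, hi = float(eigvals[0]), float(eigvals[1])
    if lo <= max(hi, 1.0) * 1e-14:
        warnings.warn(
            f"contour {c.id!r}: degenerate minor axis, aspect ratio is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return float(np.sqrt(hi / lo))


def solidity(c: Contour) -> float:
    """Filled polygon area divided by its convex hull area, in (0, 1]."""
    area = polygon_area(c.points)
    if area == 0.0:
        raise DegenerateShapeError(f"contour {c.id!r}: zero area")
    try:
        hull_area = float(ConvexHull(c.points).volume)  # 2-D: volume == area
    except QhullError as exc:
        raise DegenerateShapeError(f"contour {c.id!r}: degenerate convex hull") from exc
    return float(min(area / hull_area, 1.0))


def transform_descriptors(d: ShapeDescriptors) -> ShapeDescriptors:
    """Fill the display transforms inv_aspect_ratio = 1/AR and solidity8 = S^8."""
    d.inv_aspect_ratio = 1.0 / d.aspect_ratio if d.aspect_ratio > 0 else 0.0
    d.solidity8 = d.solidity**8
    return d


def describe(c: Contour) -> ShapeDescriptors:
    """Compute all classic descriptors (including transforms) for one contour."""
    return transform_descriptors(
        ShapeDescriptors(
            circularity=circularity(c),
            aspect_ratio=aspect_ratio(c),
            solidity=solidity(c),
        )
    )
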