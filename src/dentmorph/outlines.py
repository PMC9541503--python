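"""Closed-outline morphometrics: radial pseudo-landmarks, centroid size, crown diameters.

A crown (or cervical) outline viewed occlusally is reduced to ``k`` pseudo-landmarks
placed where equiangularly spaced rays from the outline's area centroid intersect the
boundary.  The first ray points buccally (+y in the canonical left-molar frame) and
subsequent rays step clockwise (buccal -> mesial -> lingual -> distal).  Configurations
are scaled to unit centroid size before entering the shape space, so only shape is
analysed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Outline2D",
    "LandmarkConfiguration",
    "CrownDiameters",
    "area_centroid",
    "radial_pseudolandmarks",
    "normalize_configuration",
    "crown_diameters",
    "centroid_size",
]


class OutlineGeometryError(ValueError):
    """Raised for degenerate outlines (near-zero area, centroid outside polygon...)."""


@dataclass(frozen=True)
class Outline2D:
    """Simple closed planar polygon, counter-clockwise, coordinates in mm.

    The closing edge from the last vertex back to the first is implicit.
    """

    vertices: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("outline needs an (n>=3, 2) vertex array")
        object.__setattr__(self, "vertices", v)

    @property
    def signed_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def ensure_ccw(self) -> "Outline2D":
        return self if self.signed_area > 0 else Outline2D(self.vertices[::-1].copy())


@dataclass(frozen=True)
class LandmarkConfiguration:
    """Ordered pseudo-landmarks relative to the outline's area centroid.

    ``centroid_size`` is the geometric-morphometrics size measure
    ``CS = sqrt(sum_i ||x_i - xbar||^2)`` about the landmark mean.  For a
    normalized configuration the points were divided by the original CS
    (stored in ``original_centroid_size``) and CS == 1.
    """

    points: np.ndarray  # (k, 2)
    centroid_size: float
    normalized: bool = False
    original_centroid_size: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ValueError("points must be (k, 2)")
        object.__setattr__(self, "points", p)
        if self.normalized and abs(self.centroid_size - 1.0) > 1e-9:
            raise ValueError("normalized configuration must have unit centroid size")

    @property
    def k(self) -> int:
        return self.points.shape[0]

    def flatten(self) -> np.ndarray:
        """Row-major (x0, y0, x1, y1, ...) vector for shape-space analysis."""
        return self.points.reshape(-1)


@dataclass(frozen=True)
class CrownDiameters:
    """Mesiodistal and buccolingual bounding-box extents (mm), canonical frame."""

    MD: float
    BL: float

    def __post_init__(self) -> None:
        if self.MD <= 0 or self.BL <= 0:
            raise ValueError("diameters must be positive")


def area_centroid(outline: Outline2D) -> tuple[float, np.ndarray]:
    """Shoelace area (mm^2) and area-weighted centroid of a closed polygon.

    Raises
    ------
    OutlineGeometryError
        If the polygon area is below 1e-9 mm^2.
    """
    v = outline.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * float(np.sum(cross))
    if abs(area) < 1e-9:
        raise OutlineGeometryError("outline area below 1e-9 mm^2")
    cx = float(np.sum((x + xn) * cross)) / (6.0 * area)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * area)
    return abs(area), np.array([cx, cy])


def _point_in_polygon(point: np.ndarray, vertices: np.ndarray) -> bool:
    # even-odd ray crossing test
    x, y = point
    vx, vy = vertices[:, 0], vertices[:, 1]
    vxn, vyn = np.roll(vx, -1), np.roll(vy, -1)
    crosses = (vy > y) != (vyn > y)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = vx + (y - vy) / (vyn - vy) * (vxn - vx)
    hits = crosses & (x < np.where(crosses, xint, np.inf))
    return bool(np.sum(hits) % 2)


def _ray_polygon_intersections(origin: np.ndarray, direction: np.ndarray,
                               vertices: np.ndarray) -> np.ndarray:
    """Distances t > 0 where origin + t*direction crosses the polygon boundary."""
    a = vertices
    b = np.roll(vertices, -1, axis=0)
    e = b - a  # edge vectors
    d = direction
    # solve origin + t d = a + s e, 0 <= s <= 1, t > 0
    denom = d[0] * (-e[:, 1]) - d[1] * (-e[:, 0])
    rel = a - origin
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rel[:, 0] * (-e[:, 1]) - rel[:, 1] * (-e[:, 0])) / denom
        s = (d[0] * rel[:, 1] - d[1] * rel[:, 0]) / denom
    ok = np.isfinite(t) & np.isfinite(s) & (t > 1e-12) & (s >= -1e-12) & (s <= 1 + 1e-12)
    return np.sort(t[ok])


def radial_pseudolandmarks(outline: Outline2D, k: int = 16) -> LandmarkConfiguration:
    """Place ``k`` pseudo-landmarks on equiangular rays from the area centroid.

    Ray ``i`` points at angle ``90 deg - i * (360/k) deg`` from +x: the first
    landmark sits buccally on +y and the sequence steps clockwise in the occlusal
    view (buccal, mesial, lingual, distal for k=16 at indices 0, 4, 8, 12).  Where
    a ray crosses the boundary more than once the farthest crossing is kept — the
    silhouette of a crown is its outermost contour.  Coordinates are returned
    relative to the area centroid.
    """
    outline = outline.ensure_ccw()
    _, centroid = area_centroid(outline)
    if not _point_in_polygon(centroid, outline.vertices):
        raise OutlineGeometryError("area centroid lies outside the outline")
    pts = np.empty((k, 2))
    for i in range(k):
        theta = np.deg2rad(90.0 - i * 360.0 / k)
        d = np.array([np.cos(theta), np.sin(theta)])
        ts = _ray_polygon_intersections(centroid, d, outline.vertices)
        assert ts.size > 0, "ray from interior centroid must cross the boundary"
        pts[i] = ts[-1] * d  # farthest crossing, centroid-relative
    cs = centroid_size(pts)
    return LandmarkConfiguration(points=pts, centroid_size=cs, normalized=False,
                                 metadata={"k": k, "angular_order": "clockwise-from-buccal"})


def centroid_size(points: np.ndarray) -> float:
    """CS = sqrt(sum of squared distances of landmarks from their mean)."""
    p = np.asarray(points, dtype=float)
    return float(np.sqrt(np.sum((p - p.mean(axis=0)) ** 2)))


def normalize_configuration(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Scale a configuration to unit centroid size; the original CS is retained."""
    if config.normalized:
        raise ValueError("configuration already normalized")
    cs = config.centroid_size
    if cs <= 0:
        raise OutlineGeometryError("zero centroid size")
    return replace(config, points=config.points / cs, centroid_size=1.0,
                   normalized=True, original_centroid_size=cs)


def crown_diameters(outline: Outline2D) -> CrownDiameters:
    """Bounding-box MD (x extent) and BL (y extent) of a canonically oriented outline."""
    v = outline.vertices
    return CrownDiameters(MD=float(np.ptp(v[:, 0])), BL=float(np.ptp(v[:, 1])))
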