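"""Crown orientation: cervical plane fitting, canonical frame, silhouette projection.

A crown mesh is brought into a canonical occlusal frame before outline analysis:
the best-fit plane of the digitized cervical line becomes z = 0 with the occlusal
side at z > 0, the mesiodistal fissure runs along x and the buccal side faces +y.
Right-side specimens are mirrored into the left-side convention.  The crown's
occlusal silhouette is then the outer boundary of the mesh footprint on z = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from skimage import measure
from skimage.draw import polygon as draw_polygon

from .outlines import Outline2D

__all__ = [
    "Plane",
    "CanonicalFrame",
    "fit_cervical_plane",
    "orient_specimen",
    "project_silhouette",
    "load_mesh",
]


class PlaneFitError(ValueError):
    """Degenerate (collinear or insufficient) cervical points."""


class OrientationError(ValueError):
    """Direction hints parallel to the cervical normal or otherwise degenerate."""


class ProjectionError(ValueError):
    """Empty silhouette footprint."""


@dataclass(frozen=True)
class Plane:
    """Plane {x : normal . x = offset}; ``normal`` is unit length."""

    normal: np.ndarray
    offset: float
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.normal - self.offset


@dataclass(frozen=True)
class CanonicalFrame:
    """Rigid (plus optional mirror) map into the canonical crown frame.

    Applied as ``x' = rotation @ (M x) + translation`` where M reflects x -> -x
    when ``mirrored`` (right-side specimens re-expressed in the left-side
    convention).
    """

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # (3,)
    mirrored: bool = False

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        if self.mirrored:
            p = p * np.array([-1.0, 1.0, 1.0])
        return p @ self.rotation.T + self.translation

    @property
    def is_identity(self) -> bool:
        return (not self.mirrored and np.allclose(self.rotation, np.eye(3), atol=1e-9)
                and np.allclose(self.translation, 0.0, atol=1e-9))


def fit_cervical_plane(points: np.ndarray,
                       crown_reference: np.ndarray | None = None) -> Plane:
    """Total-least-squares plane through the cervical-line points.

    The plane minimizes the sum of squared orthogonal distances (smallest
    singular vector of the centered points).  The normal sign is chosen so the
    crown side is positive: the majority of ``crown_reference`` points (when
    given) or +z otherwise.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise PlaneFitError("need at least 3 points in 3D")
    center = pts.mean(axis=0)
    centered = pts - center
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise PlaneFitError("cervical points are collinear")
    normal = vt[2]
    if crown_reference is not None:
        side = np.median(np.asarray(crown_reference, dtype=float) @ normal - center @ normal)
        if side < 0:
            normal = -normal
    elif normal[2] < 0:
        normal = -normal
    offset = float(center @ normal)
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return Plane(normal=normal, offset=offset, rms_residual=rms)


def orient_specimen(mesh: trimesh.Trimesh, cervical_points: np.ndarray,
                    md_direction: np.ndarray, buccal_direction: np.ndarray,
                    side: str = "left") -> tuple[trimesh.Trimesh, CanonicalFrame]:
    """Orient a crown mesh into the canonical frame.

    The cervical best-fit plane becomes z = 0 (occlusal side positive, using
    the mesh vertices as the crown reference), the mesiodistal fissure hint is
    projected into the plane to define +x, and the buccal hint fixes the sign of
    +y.  Right-side crowns are mirrored across the y-z plane and re-wound so
    faces stay outward.  The returned frame reproduces the transform exactly.
    """
    if side not in ("left", "right"):
        raise OrientationError(f"side must be 'left' or 'right', got {side!r}")
    mirrored = side == "right"
    cerv = np.asarray(cervical_points, dtype=float)
    md = np.asarray(md_direction, dtype=float)
    buc = np.asarray(buccal_direction, dtype=float)
    if mirrored:
        flip = np.array([-1.0, 1.0, 1.0])
        cerv = cerv * flip
        md = md * flip
        buc = buc * flip
        mesh = mesh.copy()
        mesh.vertices = mesh.vertices * flip
        mesh.faces = mesh.faces[:, ::-1]  # restore outward winding

    plane = fit_cervical_plane(cerv, crown_reference=mesh.vertices)
    z_axis = plane.normal
    x_axis = md - (md @ z_axis) * z_axis
    nx = np.linalg.norm(x_axis)
    if nx < 1e-9 * np.linalg.norm(md):
        raise OrientationError("mesiodistal hint is parallel to the cervical normal")
    x_axis = x_axis / nx
    y_axis = np.cross(z_axis, x_axis)
    if y_axis @ buc < 0:  # buccal must face +y; rotate 180 deg about z
        x_axis, y_axis = -x_axis, -y_axis
    # rows of R are the canonical axes expressed in input coordinates
    R = np.vstack([x_axis, y_axis, z_axis])
    centroid = cerv.mean(axis=0)
    translation = -R @ centroid
    frame = CanonicalFrame(rotation=R, translation=translation, mirrored=mirrored)

    out = mesh.copy()
    out.vertices = (mesh.vertices @ R.T) + translation
    return out, frame


def project_silhouette(mesh: trimesh.Trimesh, raster_resolution: float = 0.02,
                       above_cervical_only: bool = True) -> Outline2D:
    """Outer boundary of the crown footprint on the cervical plane z = 0.

    Faces (optionally restricted to z >= 0 geometry) are projected to the xy
    plane and rasterized at ``raster_resolution`` mm; the largest boundary
    contour of the filled footprint is traced and returned counter-clockwise in
    mm.  Rasterization is robust to the non-watertight meshes typical of
    surface scans; the resolution knob trades accuracy for speed.
    """
    if raster_resolution <= 0:
        raise ValueError("raster_resolution must be positive")
    faces = mesh.faces
    verts = mesh.vertices
    if above_cervical_only:
        keep = (verts[:, 2] >= -1e-9)[faces].any(axis=1)
        faces = faces[keep]
    if len(faces) == 0:
        raise ProjectionError("no faces above the cervical plane")
    tri2d = verts[:, :2][faces]  # (m, 3, 2)
    lo = tri2d.reshape(-1, 2).min(axis=0) - 2 * raster_resolution
    hi = tri2d.reshape(-1, 2).max(axis=0) + 2 * raster_resolution
    nx = int(np.ceil((hi[0] - lo[0]) / raster_resolution)) + 1
    ny = int(np.ceil((hi[1] - lo[1]) / raster_resolution)) + 1
    grid = np.zeros((nx, ny), dtype=bool)
    cols = (tri2d - lo) / raster_resolution
    for tri in cols:
        rr, cc = draw_polygon(tri[:, 0], tri[:, 1], shape=grid.shape)
        grid[rr, cc] = True
    if not grid.any():
        raise ProjectionError("empty silhouette footprint")
    # pad so contours at the border close, then trace the longest one
    padded = np.pad(grid, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ProjectionError("no silhouette contour found")
    contour = max(contours, key=lambda c: _contour_area(c))
    xy = (contour - 1.0) * raster_resolution + lo
    outline = Outline2D(xy)
    return outline.ensure_ccw()


def _contour_area(contour: np.ndarray) -> float:
    x, y = contour[:, 0], contour[:, 1]
    return abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def load_mesh(path, unit_scale: float = 1.0) -> trimesh.Trimesh:
    """Load a PLY/STL/OBJ crown surface; drops degenerate faces, scales to mm."""
    mesh = trimesh.load_mesh(path, process=True)
    if unit_scale != 1.0:
        mesh.vertices = mesh.vertices * unit_scale
    if len(mesh.vertices) < 4:
        raise ValueError("mesh must have at least 4 vertices")
    return mesh
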