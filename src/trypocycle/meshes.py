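"""Anterior-caliber measurement on triangulated cell-surface meshes.

Replicates the volume-EM readout of anterior cell-end shape: walk a fixed
arclength (2 µm by convention) from the anterior tip along a user-supplied
on-surface contour, then measure the cross-cell caliber at that point by
sphere expansion — the radius at which a sphere centred on the contour point
first touches the cell surface on the opposite side.

For a surface point on a tube the expanding sphere permanently grazes the
wall it sits on; the measured event is the sphere reaching the far wall
straight across the lumen.  The implementation casts a ray from the center
along the inward surface normal and takes the first hit beyond an exclusion
radius that masks the local wall.  On a circular cylinder of radius R this
is exactly the diameter 2R, on a sphere 2R, and on a gently tapered tube
2 r(z) (1 + O(r'(z)^2)) — within a couple of percent of the local diameter
for realistic tapers.  All coordinates are in nanometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

__all__ = [
    "AnteriorPath",
    "point_at_arclength",
    "opposite_caliber",
    "anterior_caliber",
    "ANTERIOR_ARCLENGTH_NM",
]

#: Conventional arclength from the anterior tip at which caliber is read (2 µm).
ANTERIOR_ARCLENGTH_NM = 2000.0


@dataclass
class AnteriorPath:
    """Ordered on-surface polyline from the anterior tip, in nanometres."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("path must be an (n >= 2, 3) array of points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive path points must be distinct")
        self.points = pts
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def arclength(self) -> float:
        """Total polyline arclength (nm)."""
        return float(self._cum[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Point at cumulative arclength ``s`` by linear interpolation."""
        if s < 0 or s > self.arclength + 1e-9:
            raise ValueError(
                f"arclength {s} nm outside path length {self.arclength:.1f} nm"
            )
        s = min(s, self.arclength)
        i = int(np.searchsorted(self._cum, s, side="right")) - 1
        i = min(i, len(self._cum) - 2)
        t = (s - self._cum[i]) / (self._cum[i + 1] - self._cum[i])
        return (1 - t) * self.points[i] + t * self.points[i + 1]


def point_at_arclength(path: AnteriorPath, s: float) -> np.ndarray:
    """Point on ``path`` at cumulative arclength ``s`` (nm)."""
    return path.point_at(s)


def _surface_normal_at(mesh: trimesh.Trimesh, point: np.ndarray) -> np.ndarray:
    # Nearest-face lookup by exhaustive point-triangle distance (vectorised).
    # A point sitting on a mesh vertex gets the (averaged) vertex normal,
    # which tracks the smooth surface better than any single face normal.
    dv = np.linalg.norm(mesh.vertices - point, axis=1)
    iv = int(np.argmin(dv))
    cp = trimesh.triangles.closest_point(
        mesh.triangles, np.tile(point, (len(mesh.triangles), 1))
    )
    d2 = np.einsum("ij,ij->i", cp - point, cp - point)
    face = int(np.argmin(d2))
    if dv[iv] ** 2 <= d2[face] + 1e-12:
        return mesh.vertex_normals[iv]
    return mesh.face_normals[face]


def _ray_hits(
    mesh: trimesh.Trimesh, origin: np.ndarray, direction: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """All ray-mesh intersections (Moller-Trumbore, vectorised over faces).

    Returns (distances, face indices) for hits with positive distance.
    """
    tri = mesh.triangles
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origin - tri[:, 0]
    u = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", direction, qvec) * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    eps = 1e-9
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > eps)
    return t[hit], np.flatnonzero(hit)


def opposite_caliber(
    mesh: trimesh.Trimesh,
    center: np.ndarray,
    exclusion_radius: float = 300.0,
) -> float:
    """Sphere-expansion caliber at an on-surface point, in nanometres.

    Casts a ray from ``center`` along the inward surface normal and returns
    the distance to the first wall hit beyond ``exclusion_radius`` (ignoring
    the wall the center sits on).  The mesh must be watertight with outward
    normals.

    Raises
    ------
    ValueError
        If the mesh is not watertight, or no opposite wall is found.
    """
    if not mesh.is_watertight:
        raise ValueError("caliber measurement requires a watertight mesh")
    center = np.asarray(center, dtype=float)

    direction = -_surface_normal_at(mesh, center)
    dists, _ = _ray_hits(mesh, center, direction)
    keep = dists > exclusion_radius
    if not keep.any():
        raise ValueError(
            "no opposite wall found beyond the exclusion radius; the point may "
            "lie on a feature thinner than the exclusion radius"
        )
    return float(dists[keep].min())


def anterior_caliber(
    mesh: trimesh.Trimesh,
    path: AnteriorPath,
    arclength: float = ANTERIOR_ARCLENGTH_NM,
    exclusion_radius: float = 300.0,
) -> float:
    """Caliber at a fixed arclength from the anterior tip (nm).

    Composition of :func:`point_at_arclength` and :func:`opposite_caliber`;
    the path must be at least ``arclength`` long.
    """
    if path.arclength < arclength:
        raise ValueError(
            f"path arclength {path.arclength:.1f} nm is shorter than the "
            f"requested {arclength:.1f} nm"
        )
    center = path.point_at(arclength)
    return opposite_caliber(mesh, center, exclusion_radius=exclusion_radius)
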