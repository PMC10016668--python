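"""Indexed triangle meshes in millimetre coordinates.

The :class:`TriangleMesh` container is deliberately thin: two numpy arrays
plus derived quantities (face normals, areas, angle-weighted vertex normals)
computed on demand.  STL stores an unindexed triangle soup, so meshes read
from disk are welded (duplicate vertices merged within a tolerance) before
any connectivity-dependent query is meaningful; :func:`weld_vertices` does
this and is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

from .errors import ParameterError

#: default vertex welding tolerance in mm
WELD_TOLERANCE = 1e-6


@dataclass
class TriangleMesh:
    """Triangle surface mesh; coordinates in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Counter-clockwise winding defines the outward normal.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ParameterError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ParameterError("faces must be an (m, 3) array")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ParameterError("face indices out of range")
        if len(self.vertices) and not np.isfinite(self.vertices).all():
            raise ParameterError("vertex coordinates must be finite")

    # -- derived geometry -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self) -> np.ndarray:
        """Unit outward normals from vertex winding; zero rows for degenerate faces."""
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(norm > 0, n / norm, 0.0)
        return unit

    def face_areas(self) -> np.ndarray:
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length.

        Isolated vertices get a zero normal.
        """
        fn = self.face_normals() * (2.0 * self.face_areas())[:, None]
        idx = self.faces.ravel()
        vn = np.empty_like(self.vertices)
        for k in range(3):
            vn[:, k] = np.bincount(
                idx, weights=np.repeat(fn[:, k], 3), minlength=self.n_vertices
            )
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(norm > 0, vn / norm, 0.0)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    # -- interop ----------------------------------------------------------

    def to_trimesh(self) -> _trimesh.Trimesh:
        """Lossless view as a :class:`trimesh.Trimesh` (no processing applied)."""
        return _trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: _trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))


@dataclass
class MeshValidationReport:
    """Counts gathered while validating/welding a mesh."""

    vertex_count: int
    face_count: int
    duplicate_vertex_count: int
    degenerate_face_count: int
    duplicate_face_count: int
    watertight: bool

    def __post_init__(self) -> None:
        for name in (
            "vertex_count",
            "face_count",
            "duplicate_vertex_count",
            "degenerate_face_count",
            "duplicate_face_count",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


def weld_vertices(mesh: TriangleMesh, tolerance: float = WELD_TOLERANCE) -> TriangleMesh:
    """Merge vertices closer than ``tolerance`` and drop degenerate faces.

    Welding snaps coordinates to a grid of pitch ``tolerance`` for bucketing
    but keeps the first occurrence's exact coordinates, so welding an
    already-welded mesh is the identity.
    """
    if tolerance <= 0:
        raise ParameterError("tolerance must be positive")
    v = mesh.vertices
    key = np.round(v / tolerance).astype(np.int64)
    _, first, inverse = np.unique(
        key, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = v[first[order]]
    new_faces = rank[inverse][mesh.faces]
    # drop faces that collapsed to fewer than 3 distinct vertices
    ok = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    out = TriangleMesh(new_vertices, new_faces[ok])
    # also drop zero-area faces that survived index-level checks
    areas = out.face_areas()
    if (areas <= 0).any():
        out = TriangleMesh(out.vertices, out.faces[areas > 0])
    return out


def validate(
    mesh: TriangleMesh, tolerance: float = WELD_TOLERANCE
) -> tuple[TriangleMesh, MeshValidationReport]:
    """Weld, remove degenerate and duplicate faces, and report what was found."""
    welded = weld_vertices(mesh, tolerance)
    dup_vertices = mesh.n_vertices - welded.n_vertices
    degenerate = mesh.n_faces - welded.n_faces
    sorted_faces = np.sort(welded.faces, axis=1)
    _, first = np.unique(sorted_faces, axis=0, return_index=True)
    dup_faces = welded.n_faces - len(first)
    if dup_faces:
        keep = np.zeros(welded.n_faces, bool)
        keep[first] = True
        welded = TriangleMesh(welded.vertices, welded.faces[keep])
    watertight = bool(welded.to_trimesh().is_watertight) if welded.n_faces else False
    report = MeshValidationReport(
        vertex_count=welded.n_vertices,
        face_count=welded.n_faces,
        duplicate_vertex_count=dup_vertices,
        degenerate_face_count=degenerate,
        duplicate_face_count=dup_faces,
        watertight=watertight,
    )
    return welded, report
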