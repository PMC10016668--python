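"""Common-plane trimming and capped signed point-to-surface deviation.

After registration both meshes are cut identically by one plane in the
reference frame (removing base material irrelevant to the arch surfaces);
the surface comparison is then applied on the *test* object: every retained
test-mesh vertex is projected to its closest point on the reference
surface.  The sign convention is fixed and documented: positive means the
test point lies on the outward-normal side of its nearest reference facet,
i.e. the test surface sits *outside* the reference.  Points farther than
the maximum tolerance (default 2 mm) are discarded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from trimesh.intersections import slice_mesh_plane

from .errors import EmptyResultError, ParameterError
from .mesh import TriangleMesh
from .registration import RigidTransform, SpatialIndex

#: maximum point-to-surface tolerance in mm
DEFAULT_TOLERANCE_MM = 2.0


@dataclass(frozen=True)
class TrimPlane:
    """Oriented plane; the sub-mesh on the normal side is retained."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.point, float).reshape(3)
        n = np.asarray(self.normal, float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ParameterError("plane normal must be non-zero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    @classmethod
    def horizontal(cls, height: float) -> "TrimPlane":
        """Plane z = height keeping everything above."""
        return cls(np.array([0.0, 0.0, height]), np.array([0.0, 0.0, 1.0]))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.point) @ self.normal


@dataclass
class DeviationField:
    """Signed point-to-surface distances of one superimposition (mm)."""

    points: np.ndarray
    distances: np.ndarray
    reference_id: str = "reference"
    test_id: str = "test"
    tolerance_mm: float = DEFAULT_TOLERANCE_MM
    discarded_count: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        self.distances = np.asarray(self.distances, float).ravel()
        if len(self.points) != len(self.distances):
            raise ParameterError("points and distances must have equal length")
        if len(self.distances) and np.abs(self.distances).max() > self.tolerance_mm + 1e-12:
            raise ParameterError("retained distances exceed the tolerance")

    @property
    def sampled_count(self) -> int:
        """Total measurement points before tolerance capping."""
        return len(self.distances) + self.discarded_count

    def __len__(self) -> int:
        return len(self.distances)


def trim_by_plane(mesh: TriangleMesh, plane: TrimPlane) -> TriangleMesh:
    """Retain the sub-mesh on the normal side of the plane.

    Triangles crossing the plane are clipped exactly at the intersection
    (new vertices on the plane); triangles entirely behind it are dropped.
    Idempotent.
    """
    if mesh.n_faces == 0:
        raise EmptyResultError("cannot trim an empty mesh")
    side = plane.signed_distance(mesh.vertices) >= 0
    if side.all():
        return mesh.copy()
    sliced = slice_mesh_plane(
        mesh.to_trimesh(), plane_normal=plane.normal, plane_origin=plane.point
    )
    if sliced is None or len(sliced.faces) == 0:
        raise EmptyResultError("trim plane excludes the entire mesh")
    return TriangleMesh.from_trimesh(sliced)


def signed_distances_to_reference(
    points: np.ndarray, index: SpatialIndex
) -> np.ndarray:
    """Signed distance of each point to the indexed reference surface.

    Magnitude is the exact closest-point distance; the sign comes from the
    outward normal of the nearest facet (ties at shared edges resolve to the
    smaller face index inside the spatial query).
    """
    feet, faces, dist = index.query(points)
    outward = np.einsum(
        "ij,ij->i", np.asarray(points, float) - feet, index.face_normals[faces]
    )
    return np.where(outward >= 0, dist, -dist)


def measure_deviation(
    test: TriangleMesh,
    reference: TriangleMesh,
    transform: RigidTransform | None = None,
    plane: TrimPlane | None = None,
    tolerance_mm: float = DEFAULT_TOLERANCE_MM,
    reference_id: str = "reference",
    test_id: str = "test",
    reference_index: SpatialIndex | None = None,
) -> DeviationField:
    """Capped signed point-to-surface deviation of ``test`` against ``reference``.

    ``transform`` (the registration result) maps the test mesh into the
    reference frame; both meshes are then trimmed by ``plane`` (if given)
    and every retained test vertex is measured against the reference
    surface.  Measurement points are the trimmed test-mesh vertices, so the
    point count is a property of the test scan.  Points farther than
    ``tolerance_mm`` are discarded and counted.
    """
    if tolerance_mm <= 0:
        raise ParameterError("tolerance must be positive")
    if transform is not None:
        test = TriangleMesh(transform.apply(test.vertices), test.faces)
    if plane is not None:
        test = trim_by_plane(test, plane)
        reference = trim_by_plane(reference, plane)
        reference_index = None  # the index must match the trimmed reference
    if test.n_vertices == 0 or reference.n_faces == 0:
        raise EmptyResultError("nothing left to measure after trimming")
    if reference_index is None:
        reference_index = SpatialIndex(reference)
    signed = signed_distances_to_reference(test.vertices, reference_index)
    keep = np.abs(signed) <= tolerance_mm
    return DeviationField(
        points=test.vertices[keep],
        distances=signed[keep],
        reference_id=reference_id,
        test_id=test_id,
        tolerance_mm=tolerance_mm,
        discarded_count=int((~keep).sum()),
    )
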