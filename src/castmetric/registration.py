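"""Rigid best-fit (ICP) registration of a test scan onto a reference scan.

The registration follows the classic iterative-closest-point scheme used by
surface-inspection software for "global best-fit" alignment: measurement
points sampled on the test surface are projected onto the triangulated
reference surface, correspondences beyond a cutoff are discarded, and the
incremental least-squares rigid motion (Kabsch/SVD) is applied, iterating
until the RMS of correspondence distances stops improving.  The reference
object is never moved; the returned transform always maps the test frame
into the reference frame.

Closest-point queries are exact: a kd-tree over triangle centroids proposes
candidates, exact point-to-triangle distances rank them, and a ball query
with the per-mesh circumradius bound guarantees that no closer triangle was
missed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import AlignmentError, DegenerateGeometryError, ParameterError
from .mesh import TriangleMesh

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation then translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.ascontiguousarray(self.rotation, dtype=np.float64)
        t = np.ascontiguousarray(self.translation, dtype=np.float64).reshape(3)
        if R.shape != (3, 3):
            raise ParameterError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ParameterError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ParameterError("rotation is improper (determinant != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``x -> self(other(x))``."""
        R = _project_rotation(self.rotation @ other.rotation)
        t = self.rotation @ other.translation + self.translation
        return RigidTransform(R, t)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def to_matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix, row-major."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, float)
        if m.shape != (4, 4):
            raise ParameterError("expected a 4x4 homogeneous matrix")
        return cls(m[:3, :3], m[:3, 3])


def _project_rotation(R: np.ndarray) -> np.ndarray:
    """Nearest proper rotation (removes round-off drift from compositions)."""
    U, _, Vt = np.linalg.svd(R)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


# ---------------------------------------------------------------------------
# point-to-triangle distance

try:  # numba accelerates the per-pair kernel ~100x; numpy path is equivalent
    import numba as _numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _closest_point_on_triangles_numpy(
    points: np.ndarray, triangles: np.ndarray
) -> np.ndarray:
    """Closest point on each triangle to each query point (paired arrays).

    Vectorised barycentric-region algorithm; ``points`` is (n, 3) and
    ``triangles`` is (n, 3, 3); returns (n, 3) foot points.
    """
    p = np.asarray(points, float)
    tri = np.asarray(triangles, float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    # face interior
    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


if _HAVE_NUMBA:

    @_numba.njit(cache=True, fastmath=False)
    def _closest_point_on_triangles_numba(points, triangles):  # pragma: no cover
        n = points.shape[0]
        out = np.empty((n, 3))
        for i in range(n):
            px, py, pz = points[i, 0], points[i, 1], points[i, 2]
            ax, ay, az = triangles[i, 0, 0], triangles[i, 0, 1], triangles[i, 0, 2]
            bx, by, bz = triangles[i, 1, 0], triangles[i, 1, 1], triangles[i, 1, 2]
            cx, cy, cz = triangles[i, 2, 0], triangles[i, 2, 1], triangles[i, 2, 2]
            abx, aby, abz = bx - ax, by - ay, bz - az
            acx, acy, acz = cx - ax, cy - ay, cz - az
            apx, apy, apz = px - ax, py - ay, pz - az
            d1 = abx * apx + aby * apy + abz * apz
            d2 = acx * apx + acy * apy + acz * apz
            if d1 <= 0.0 and d2 <= 0.0:
                out[i, 0], out[i, 1], out[i, 2] = ax, ay, az
                continue
            bpx, bpy, bpz = px - bx, py - by, pz - bz
            d3 = abx * bpx + aby * bpy + abz * bpz
            d4 = acx * bpx + acy * bpy + acz * bpz
            if d3 >= 0.0 and d4 <= d3:
                out[i, 0], out[i, 1], out[i, 2] = bx, by, bz
                continue
            vc = d1 * d4 - d3 * d2
            if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                t = d1 / (d1 - d3) if d1 - d3 != 0.0 else 0.0
                out[i, 0] = ax + t * abx
                out[i, 1] = ay + t * aby
                out[i, 2] = az + t * abz
                continue
            cpx, cpy, cpz = px - cx, py - cy, pz - cz
            d5 = abx * cpx + aby * cpy + abz * cpz
            d6 = acx * cpx + acy * cpy + acz * cpz
            if d6 >= 0.0 and d5 <= d6:
                out[i, 0], out[i, 1], out[i, 2] = cx, cy, cz
                continue
            vb = d5 * d2 - d1 * d6
            if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                t = d2 / (d2 - d6) if d2 - d6 != 0.0 else 0.0
                out[i, 0] = ax + t * acx
                out[i, 1] = ay + t * acy
                out[i, 2] = az + t * acz
                continue
            va = d3 * d6 - d5 * d4
            if va <= 0.0 and d4 - d3 >= 0.0 and d5 - d6 >= 0.0:
                denom = (d4 - d3) + (d5 - d6)
                t = (d4 - d3) / denom if denom != 0.0 else 0.0
                out[i, 0] = bx + t * (cx - bx)
                out[i, 1] = by + t * (cy - by)
                out[i, 2] = bz + t * (cz - bz)
                continue
            denom = va + vb + vc
            if denom != 0.0:
                v = vb / denom
                w = vc / denom
            else:
                v = 1.0 / 3.0
                w = 1.0 / 3.0
            out[i, 0] = ax + v * abx + w * acx
            out[i, 1] = ay + v * aby + w * acy
            out[i, 2] = az + v * abz + w * acz
        return out


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on triangle i to point i (paired (n,3) / (n,3,3) arrays)."""
    points = np.ascontiguousarray(points, dtype=np.float64)
    triangles = np.ascontiguousarray(triangles, dtype=np.float64)
    if _HAVE_NUMBA:
        return _closest_point_on_triangles_numba(points, triangles)
    return _closest_point_on_triangles_numpy(points, triangles)


def _subdivide_long_triangles(
    triangles: np.ndarray, parent: np.ndarray, max_radius: float, max_rounds: int = 24
) -> tuple[np.ndarray, np.ndarray]:
    """Bisect triangles along their longest edge until every circumradius-like
    bound (max centroid-to-corner distance) is below ``max_radius``.

    Splitting changes only the index decomposition, never the surface, so
    distances computed against the pieces equal distances against the
    parents; ``parent`` maps each piece back to its original face id.
    """
    def _radii(tri: np.ndarray) -> np.ndarray:
        cent = tri.mean(axis=1)
        return np.linalg.norm(tri - cent[:, None, :], axis=2).max(axis=1)

    radii = _radii(triangles)
    big = radii > max_radius
    done_tris = [triangles[~big]]
    done_parents = [parent[~big]]
    queue_tris, queue_parents = triangles[big], parent[big]
    for _ in range(max_rounds):
        if not len(queue_tris):
            break
        tri = queue_tris
        edges = np.stack(
            [tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 1], tri[:, 0] - tri[:, 2]]
        )
        longest = np.argmax(np.linalg.norm(edges, axis=2), axis=0)
        rows = np.arange(len(tri))
        a = tri[rows, longest]
        b = tri[rows, (longest + 1) % 3]
        c = tri[rows, (longest + 2) % 3]
        mid = 0.5 * (a + b)
        pieces = np.concatenate(
            [np.stack([a, mid, c], axis=1), np.stack([mid, b, c], axis=1)]
        )
        parents = np.concatenate([queue_parents, queue_parents])
        big = _radii(pieces) > max_radius
        done_tris.append(pieces[~big])
        done_parents.append(parents[~big])
        queue_tris, queue_parents = pieces[big], parents[big]
    else:  # give up splitting pathological slivers; bound stays valid
        done_tris.append(queue_tris)
        done_parents.append(queue_parents)
    return np.concatenate(done_tris), np.concatenate(done_parents)


class SpatialIndex:
    """Exact nearest-point queries against a triangulated surface.

    Oversized triangles are bisected (index-internal only) so a kd-tree over
    piece centroids gives a tight circumradius bound.  ``k`` candidate
    pieces per query are ranked by exact point-to-triangle distance; any
    query for which a closer piece cannot be ruled out is re-resolved with a
    guaranteed ball search.  Meshes below ``brute_force_below`` pieces skip
    the tree and scan every triangle.  Ties within 1e-12 mm resolve to the
    smaller original face index.
    """

    def __init__(
        self,
        mesh: TriangleMesh,
        leafsize: int = 32,
        brute_force_below: int = 64,
    ):
        if mesh.n_faces == 0:
            raise ParameterError("cannot index an empty mesh")
        self.mesh = mesh
        tris = mesh.triangles
        cent = tris.mean(axis=1)
        radii = np.linalg.norm(tris - cent[:, None, :], axis=2).max(axis=1)
        # split outliers down toward the typical triangle size
        cap = max(2.0 * float(np.median(radii)), 1e-9)
        self.triangles, self.parent = _subdivide_long_triangles(
            tris, np.arange(mesh.n_faces, dtype=np.int64), cap
        )
        self.centroids = self.triangles.mean(axis=1)
        self.radii = np.linalg.norm(
            self.triangles - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.max_radius = float(self.radii.max())
        self.brute_force = len(self.triangles) <= brute_force_below
        self.tree = None if self.brute_force else cKDTree(self.centroids, leafsize=leafsize)
        self.face_normals = mesh.face_normals()

    def _rank(
        self, points: np.ndarray, cand: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Best foot point / original face / distance among candidate pieces."""
        n, k = cand.shape
        flat_pts = np.repeat(points, k, axis=0)
        flat_tris = self.triangles[cand.ravel()]
        feet = closest_point_on_triangles(flat_pts, flat_tris).reshape(n, k, 3)
        d = np.linalg.norm(feet - points[:, None, :], axis=2)
        best = d.min(axis=1)
        orig = self.parent[cand]
        tied = d <= best[:, None] + 1e-12
        face_ids = np.where(tied, orig, np.iinfo(np.int64).max).min(axis=1)
        # among tied candidates of the winning face, keep the closest piece
        d_pick = np.where(tied & (orig == face_ids[:, None]), d, np.inf)
        pick = np.argmin(d_pick, axis=1)
        rows = np.arange(n)
        return feet[rows, pick], face_ids, d[rows, pick]

    def query(
        self, points: np.ndarray, k: int = 16
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (foot points, face ids, unsigned distances) for each query point."""
        points = np.atleast_2d(np.asarray(points, float))
        n_pieces = len(self.triangles)
        if self.brute_force:
            cand = np.broadcast_to(np.arange(n_pieces), (len(points), n_pieces))
            return self._rank(points, np.ascontiguousarray(cand))
        k = min(k, n_pieces)
        dc, cand = self.tree.query(points, k=k)
        if k == 1:
            dc = dc[:, None]
            cand = cand[:, None]
        feet, faces, dist = self._rank(points, cand)
        # guarantee pass: a piece can beat `dist` only if its centroid lies
        # within dist + its circumradius of the query point.  Widen the
        # candidate set in batch, evaluate exactly only candidates whose
        # centroid lower bound allows an improvement; stragglers (radius
        # bound still inconclusive at k2 neighbours) take a ball search.
        unsure = np.nonzero(dist + self.max_radius > dc[:, -1])[0]
        if len(unsure) and k < n_pieces:
            k2 = min(max(8 * k, 64), n_pieces)
            dc2, cand2 = self.tree.query(points[unsure], k=k2)
            self._improve(points, feet, faces, dist, unsure, cand2, dc2)
            still = unsure[dist[unsure] + self.max_radius > dc2[:, -1]]
            k3 = min(8 * k2, n_pieces)
            if len(still) and k3 > k2:
                dc3, cand3 = self.tree.query(points[still], k=k3)
                self._improve(points, feet, faces, dist, still, cand3, dc3)
                still = still[dist[still] + self.max_radius > dc3[:, -1]]
            for i in still:
                ball = self.tree.query_ball_point(
                    points[i], dist[i] + self.max_radius + 1e-12
                )
                if len(ball) <= k3:
                    continue
                f1, fid1, d1 = self._rank(
                    points[i : i + 1], np.asarray(ball, np.int64)[None, :]
                )
                if d1[0] < dist[i]:
                    feet[i], faces[i], dist[i] = f1[0], fid1[0], d1[0]
        return feet, faces, dist

    def _improve(
        self,
        points: np.ndarray,
        feet: np.ndarray,
        faces: np.ndarray,
        dist: np.ndarray,
        rows: np.ndarray,
        cand: np.ndarray,
        dc: np.ndarray,
    ) -> None:
        """Refine current best answers for ``points[rows]`` using candidate
        pieces ``cand`` (centroid distances ``dc``), evaluating exactly only
        pieces whose centroid-minus-radius lower bound can beat the best."""
        viable = dc - self.radii[cand] < dist[rows, None]
        r_idx, c_idx = np.nonzero(viable)
        if not len(r_idx):
            return
        flat_rows = rows[r_idx]
        pieces = cand[r_idx, c_idx]
        f = closest_point_on_triangles(points[flat_rows], self.triangles[pieces])
        d = np.linalg.norm(f - points[flat_rows], axis=1)
        order = np.lexsort((self.parent[pieces], d, flat_rows))
        first = np.concatenate(
            [[True], flat_rows[order][1:] != flat_rows[order][:-1]]
        )
        win = order[first]
        better = d[win] < dist[flat_rows[win]]
        win = win[better]
        feet[flat_rows[win]] = f[win]
        faces[flat_rows[win]] = self.parent[pieces[win]]
        dist[flat_rows[win]] = d[win]


def closest_point_on_mesh(
    point: np.ndarray, index: SpatialIndex
) -> tuple[np.ndarray, int, float]:
    """Globally nearest surface point to ``point``: (foot, face id, distance)."""
    feet, faces, dist = index.query(np.asarray(point, float)[None, :])
    return feet[0], int(faces[0]), float(dist[0])


# ---------------------------------------------------------------------------
# rigid estimation and ICP


def estimate_rigid_transform(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid motion mapping ``source`` onto ``target``.

    Kabsch algorithm: SVD of the cross-covariance with reflection
    correction; translation from the centroids.  Requires at least three
    non-collinear pairs (matched by index).
    """
    src = np.asarray(source, float)
    tgt = np.asarray(target, float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ParameterError("source and target must be matching (n, 3) arrays")
    if len(src) < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    sc, tc = src.mean(axis=0), tgt.mean(axis=0)
    s0, t0 = src - sc, tgt - tc
    scale = np.linalg.norm(s0)
    if scale == 0 or np.linalg.matrix_rank(s0, tol=1e-9 * scale) < 2:
        raise DegenerateGeometryError("source points are collinear or coincident")
    H = s0.T @ t0
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, tc - R @ sc)


@dataclass
class IcpResult:
    """Outcome of one ICP registration."""

    transform: RigidTransform
    iterations: int
    rms: float
    converged: bool
    rms_trace: list[float] = field(default_factory=list)


def sample_surface_points(
    mesh: TriangleMesh, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform-area random sample of ``n`` points on the mesh surface."""
    areas = mesh.face_areas()
    total = areas.sum()
    if total <= 0:
        raise ParameterError("mesh has zero surface area")
    faces = rng.choice(mesh.n_faces, size=n, p=areas / total)
    r1, r2 = rng.random(n), rng.random(n)
    swap = r1 + r2 > 1
    r1[swap], r2[swap] = 1 - r1[swap], 1 - r2[swap]
    tri = mesh.triangles[faces]
    return tri[:, 0] + r1[:, None] * (tri[:, 1] - tri[:, 0]) + r2[:, None] * (
        tri[:, 2] - tri[:, 0]
    )


def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = points.mean(axis=0)
    cov = np.cov((points - c).T)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    v = v[:, order]
    if np.linalg.det(v) < 0:  # keep a right-handed basis
        v[:, 2] = -v[:, 2]
    return c, v


def _coarse_init(
    test_pts: np.ndarray, index: SpatialIndex, probe: np.ndarray
) -> RigidTransform:
    """Centroid + principal-axes prealignment with sign disambiguation.

    Principal axes are sign-ambiguous; all four proper-rotation sign
    combinations are scored by RMS of probe-point correspondences and the
    best one wins.  Arch asymmetry (anterior vs posterior mass) makes the
    score decisive.
    """
    ref_pts = index.mesh.vertices
    tc, tv = _principal_axes(test_pts)
    rc, rv = _principal_axes(ref_pts)
    best: RigidTransform | None = None
    best_rms = np.inf
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        S = np.diag([sx, sy, sx * sy])  # keeps determinant +1
        R = rv @ S @ tv.T
        if np.linalg.det(R) < 0:  # pragma: no cover - excluded by construction
            continue
        cand = RigidTransform(_project_rotation(R), rc - _project_rotation(R) @ tc)
        _, _, d = index.query(cand.apply(probe), k=1)
        rms = float(np.sqrt(np.mean(d**2)))
        if rms < best_rms:
            best_rms, best = rms, cand
    assert best is not None
    return best


def icp_align(
    test: TriangleMesh,
    reference: TriangleMesh,
    max_iterations: int = 100,
    tolerance: float = 1e-6,
    cutoff_mm: float = 2.0,
    sample_size: int = 25_000,
    seed: int = 0,
    coarse_init: bool = True,
    index: SpatialIndex | None = None,
) -> IcpResult:
    """Register ``test`` onto ``reference`` by trimmed point-to-surface ICP.

    Each iteration samples nothing new: a fixed uniform-area sample of the
    test surface (``sample_size`` points, ``seed``-deterministic) is
    projected onto the reference surface, correspondences farther than
    ``cutoff_mm`` are discarded, and the incremental Kabsch transform is
    accumulated.  Iteration stops when the relative RMS improvement drops
    below ``tolerance`` or after ``max_iterations``.

    Returns the cumulative transform mapping the test frame into the
    reference frame; the reference is never moved.
    """
    if test.n_faces == 0 or reference.n_faces == 0:
        raise ParameterError("both meshes must be non-empty")
    if max_iterations < 1 or tolerance <= 0 or cutoff_mm <= 0 or sample_size < 3:
        raise ParameterError("ICP parameters must be positive")
    if index is None:
        index = SpatialIndex(reference)
    rng = np.random.default_rng(seed)
    pts = sample_surface_points(test, sample_size, rng)

    if coarse_init:
        probe = pts[:: max(1, len(pts) // 1000)]
        T = _coarse_init(test.vertices, index, probe)
    else:
        T = RigidTransform.identity()

    trace: list[float] = []
    converged = False
    iterations = 0
    for _ in range(max_iterations):
        moved = T.apply(pts)
        feet, _, dist = index.query(moved)
        keep = dist <= cutoff_mm
        if keep.sum() < 3:
            raise AlignmentError(
                f"only {int(keep.sum())} correspondences within {cutoff_mm} mm cutoff"
            )
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        trace.append(rms)
        if len(trace) > 1:
            prev = trace[-2]
            if prev - rms <= tolerance * max(prev, 1e-12):
                converged = True
                break
        try:
            delta = estimate_rigid_transform(moved[keep], feet[keep])
        except DegenerateGeometryError as exc:
            raise AlignmentError(str(exc)) from exc
        T = delta.compose(T)
        iterations += 1
    return IcpResult(
        transform=T,
        iterations=iterations,
        rms=trace[-1],
        converged=converged,
        rms_trace=trace,
    )
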