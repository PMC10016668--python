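"""Synthetic full-arch casts with known, injected deformations.

The generator produces a watertight solid in the canonical arch frame: a
U-shaped (parabolic) dental arch whose occlusal relief carries one smooth
Gaussian bump per tooth, extruded down to a flat base.  The geometry is not
anatomical — smooth bumps suffice to give ICP rotational lock and to
distinguish the molar from the anterior region — but its scale is: arch
width and depth, tooth spacing and cusp height match a fully dentate
maxillary cast in millimetres.

Canonical frame conventions (all deformation fields rely on them):

* the arch midline is the plane ``x = 0``;
* the anterior midpoint of the arch is at maximal ``y``, the two posterior
  (molar) ends at minimal ``y``;
* the base plate lies in ``z = 0`` and the occlusal surface faces ``+z``.

Deformation modes mirror what the study observed on real scans: transverse
arch *widening* concentrated posteriorly (intraoral-scan-like stitching
distortion), global transverse *compression* (printing shrinkage),
zero-mean Gaussian *surface noise* along vertex normals (scanner noise),
and an arbitrary initial *rigid misalignment* that registration must
remove.  Every mode records exact ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .mesh import TriangleMesh
from .registration import RigidTransform, _project_rotation


@dataclass(frozen=True)
class SyntheticArchSpec:
    """Parameters of the synthetic reference arch and its scan emulation.

    Lengths in millimetres.  ``target_vertices`` controls the sampling
    density of the generated surface (total vertex count within 20%).
    """

    arch_width: float = 56.0
    arch_depth: float = 42.0
    tooth_count: int = 14
    tooth_height: float = 6.0
    tooth_radius: float = 2.2
    ridge_height: float = 7.0
    ridge_halfwidth: float = 6.0
    base_height: float = 8.0
    target_vertices: int = 600_000
    molar_widening: float = 0.02
    compression_factor: float = 1.0
    noise_sd: float = 0.01
    max_rotation_deg: float = 5.0
    max_translation: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tooth_count < 1:
            raise ParameterError("tooth_count must be >= 1")
        if self.target_vertices < 1000:
            raise ParameterError("target_vertices must be >= 1000")
        if not (0.9 < self.compression_factor < 1.1):
            raise ParameterError("compression_factor must lie in (0.9, 1.1)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# reference arch geometry


def _centerline(spec: SyntheticArchSpec, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parabolic arch centerline; u in [-1, 1], u=0 at the anterior midpoint.

    Returns (points (n, 2), in-plane unit normals (n, 2)); the normal points
    toward the outside of the U.
    """
    half = spec.arch_width / 2
    x = half * u
    y = spec.arch_depth * (1.0 - u**2)
    dx = np.full_like(u, half)
    dy = -2.0 * spec.arch_depth * u
    tang = np.stack([dx, dy], axis=-1)
    tang /= np.linalg.norm(tang, axis=-1, keepdims=True)
    normal = np.stack([tang[..., 1], -tang[..., 0]], axis=-1)
    return np.stack([x, y], axis=-1), normal


def _arc_fraction(spec: SyntheticArchSpec, u: np.ndarray) -> np.ndarray:
    """Normalised arc length from the anterior midpoint, in [0, 1] at u=±1."""
    uu = np.linspace(0, 1, 513)
    pts, _ = _centerline(spec, uu)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return np.interp(np.abs(u), uu, s / s[-1])


def _tooth_stations(spec: SyntheticArchSpec) -> np.ndarray:
    """Tooth centres as arc fractions, symmetric about the midline."""
    n = spec.tooth_count
    return (np.arange(n) + 0.5) / n * 2.0 - 1.0  # in signed arc fraction


def occlusal_height(spec: SyntheticArchSpec, s_signed: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Surface relief above the base at signed arc fraction ``s`` and lateral
    offset ``v`` (mm) from the centerline."""
    ridge = spec.ridge_height * np.exp(-((v / (0.55 * spec.ridge_halfwidth)) ** 2))
    arc_len = _total_arc_length(spec)
    bumps = np.zeros_like(ridge)
    sd_mm = spec.tooth_radius
    for st in _tooth_stations(spec):
        ds = (s_signed - st) * (arc_len / 2.0)  # signed fraction -> mm along arch
        bumps += spec.tooth_height * np.exp(-(ds**2 + v**2) / (2 * sd_mm**2))
    return spec.base_height + ridge + bumps


def _total_arc_length(spec: SyntheticArchSpec) -> float:
    uu = np.linspace(-1, 1, 1025)
    pts, _ = _centerline(spec, uu)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def generate_reference_arch(spec: SyntheticArchSpec) -> TriangleMesh:
    """Generate the watertight synthetic reference cast.

    A structured (u, v) grid defines the occlusal surface; a mirrored grid at
    ``z = 0`` forms the base plate, and a wall strip joins their shared
    boundary, yielding a closed solid.  Deterministic: the construction uses
    no randomness, so identical specs give bit-identical meshes.
    """
    spacing = 2.0 * _total_arc_length(spec) / (2 * spec.tooth_count)
    if spec.tooth_radius * 2.0 > spacing:
        raise ParameterError(
            f"tooth_radius {spec.tooth_radius} mm exceeds half the station "
            f"spacing ({spacing / 2:.2f} mm); bumps would merge"
        )
    n_grid = spec.target_vertices // 2
    aspect = _total_arc_length(spec) / (2.0 * spec.ridge_halfwidth)
    n_u = max(16, int(round(np.sqrt(n_grid * aspect))))
    n_v = max(8, int(round(n_grid / n_u)))

    u = np.linspace(-1, 1, n_u)
    v = np.linspace(-spec.ridge_halfwidth, spec.ridge_halfwidth, n_v)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    pts2d, nrm2d = _centerline(spec, uu.ravel())
    xy = pts2d + vv.ravel()[:, None] * nrm2d
    s_signed = np.sign(uu.ravel()) * _arc_fraction(spec, uu.ravel())
    z = occlusal_height(spec, s_signed, vv.ravel())

    top = np.column_stack([xy, z])
    bottom = np.column_stack([xy, np.zeros(len(xy))])
    vertices = np.vstack([top, bottom])

    def vid(i: np.ndarray, j: np.ndarray, layer: int) -> np.ndarray:
        return layer * (n_u * n_v) + i * n_v + j

    i, j = np.meshgrid(np.arange(n_u - 1), np.arange(n_v - 1), indexing="ij")
    i, j = i.ravel(), j.ravel()
    # the (u, v) -> (x, y) map is orientation-reversing (v runs along the
    # clockwise-rotated tangent), so top faces wind (0, 2, 1) in grid order
    # to give outward (upward) normals
    q = [vid(i, j, 0), vid(i + 1, j, 0), vid(i + 1, j + 1, 0), vid(i, j + 1, 0)]
    top_faces = np.concatenate(
        [np.stack([q[0], q[2], q[1]], 1), np.stack([q[0], q[3], q[2]], 1)]
    )
    # bottom faces wind the other way (outward normals down)
    qb = [vid(i, j, 1), vid(i + 1, j, 1), vid(i + 1, j + 1, 1), vid(i, j + 1, 1)]
    bottom_faces = np.concatenate(
        [np.stack([qb[0], qb[1], qb[2]], 1), np.stack([qb[0], qb[2], qb[3]], 1)]
    )

    # wall: the grid boundary loop, top ring to bottom ring
    loop_i = np.concatenate(
        [
            np.zeros(n_v - 1, int),  # u = -1 edge, j ascending
            np.arange(n_u - 1),  # v = +half edge, i ascending
            np.full(n_v - 1, n_u - 1),  # u = +1 edge, j descending
            np.arange(n_u - 1, 0, -1),  # v = -half edge, i descending
        ]
    )
    loop_j = np.concatenate(
        [
            np.arange(n_v - 1),
            np.full(n_u - 1, n_v - 1),
            np.arange(n_v - 1, 0, -1),
            np.zeros(n_u - 1, int),
        ]
    )
    a = vid(loop_i, loop_j, 0)
    b = vid(np.roll(loop_i, -1), np.roll(loop_j, -1), 0)
    a2 = vid(loop_i, loop_j, 1)
    b2 = vid(np.roll(loop_i, -1), np.roll(loop_j, -1), 1)
    wall_faces = np.concatenate(
        [np.stack([a, a2, b2], 1), np.stack([a, b2, b], 1)]
    )

    faces = np.vstack([top_faces, bottom_faces, wall_faces])
    return TriangleMesh(vertices, faces)


def centerline_height_profile(
    spec: SyntheticArchSpec, mesh: TriangleMesh, n_samples: int = 400
) -> np.ndarray:
    """Sample the mesh's occlusal height along the arch centerline.

    For each centerline sample the nearest top-surface vertex (in xy)
    supplies the height; used to verify one local height maximum per tooth.
    """
    u = np.linspace(-1, 1, n_samples)
    pts2d, _ = _centerline(spec, u)
    top = mesh.vertices[mesh.vertices[:, 2] > spec.base_height / 2]
    from scipy.spatial import cKDTree

    tree = cKDTree(top[:, :2])
    _, idx = tree.query(pts2d)
    return top[idx, 2]


def count_strict_local_maxima(values: np.ndarray) -> int:
    """Strict interior local maxima after collapsing consecutive duplicates
    (nearest-vertex sampling of a discrete profile produces plateaus)."""
    v = np.asarray(values, float)
    v = v[np.concatenate([[True], np.diff(v) != 0])]
    if len(v) < 3:
        return 0
    return int(np.sum((v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])))


# ---------------------------------------------------------------------------
# deformation fields


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def apply_molar_widening(mesh: TriangleMesh, magnitude: float) -> TriangleMesh:
    """Transverse widening rising from zero anteriorly to ``magnitude`` at the
    posterior ends, applied outward on each side of the midline.

    The ramp is a smoothstep in normalised anterior-to-posterior position
    (``y``), which increases monotonically with arc length on the parabolic
    arch.  Negative ``magnitude`` narrows.  Exactly invertible by
    ``-magnitude`` because the displacement is purely transverse.
    """
    if magnitude == 0.0:
        return mesh.copy()
    v = mesh.vertices.copy()
    y = v[:, 1]
    y_min, y_max = y.min(), y.max()
    span = max(y_max - y_min, 1e-12)
    ramp = _smoothstep((y_max - y) / span)
    v[:, 0] += magnitude * ramp * np.sign(v[:, 0])
    return TriangleMesh(v, mesh.faces.copy())


def apply_compression(mesh: TriangleMesh, factor: float) -> TriangleMesh:
    """Scale transverse coordinates by ``factor`` about the midline plane
    ``x = 0`` (models print shrinkage narrowing the arch)."""
    if not (0.9 < factor < 1.1):
        raise ParameterError("compression factor must lie in (0.9, 1.1)")
    v = mesh.vertices.copy()
    v[:, 0] *= factor
    return TriangleMesh(v, mesh.faces.copy())


def apply_scan_noise(
    mesh: TriangleMesh, sd: float, seed: int, return_displacements: bool = False
) -> TriangleMesh | tuple[TriangleMesh, np.ndarray]:
    """Displace every vertex along its normal by independent N(0, sd) noise.

    Line-of-sight error model: optical scanners err chiefly along the view
    direction, which for a surface patch is approximately its normal.
    """
    if sd < 0:
        raise ParameterError("noise sd must be >= 0")
    if sd == 0:
        out = mesh.copy()
        disp = np.zeros(mesh.n_vertices)
    else:
        rng = np.random.default_rng(seed)
        disp = rng.normal(0.0, sd, mesh.n_vertices)
        out = TriangleMesh(
            mesh.vertices + disp[:, None] * mesh.vertex_normals(), mesh.faces.copy()
        )
    if return_displacements:
        return out, disp
    return out


def apply_rigid_perturbation(mesh: TriangleMesh, transform: RigidTransform) -> TriangleMesh:
    """Map every vertex by a proper rigid motion (initial misalignment)."""
    return TriangleMesh(transform.apply(mesh.vertices), mesh.faces.copy())


def random_rigid_transform(
    rng: np.random.Generator, max_rotation_deg: float, max_translation: float
) -> RigidTransform:
    """Uniform random rotation axis, rotation angle and translation within bounds."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-max_translation, max_translation, size=3)
    return RigidTransform(_project_rotation(R), t)


# ---------------------------------------------------------------------------
# study sets


@dataclass(frozen=True)
class DeformationRecipe:
    """One group's scan-emulation recipe, applied in canonical-frame order:
    widening, then compression, then surface noise, then rigid perturbation."""

    molar_widening: float = 0.0
    compression_factor: float = 1.0
    noise_sd: float = 0.0


@dataclass
class GroundTruth:
    """Exact provenance of one synthetic test mesh."""

    group: str
    replicate: int
    recipe: DeformationRecipe
    noise_seed: int
    perturbation: RigidTransform
    canonical_vertices: np.ndarray  # deformed vertices before rigid perturbation


@dataclass
class StudySet:
    """One reference mesh plus named groups of deformed test meshes."""

    reference: TriangleMesh
    groups: dict[str, list[TriangleMesh]]
    ground_truth: dict[str, list[GroundTruth]]

    def __post_init__(self) -> None:
        for name, meshes in self.groups.items():
            if not meshes:
                raise ParameterError(f"group {name!r} is empty")
            if len(self.ground_truth.get(name, [])) != len(meshes):
                raise ParameterError(f"group {name!r} lacks ground-truth records")


def derive_subseed(master_seed: int, group: str, replicate: int, salt: str = "") -> int:
    """Stable sub-seed from (master seed, group name, replicate index).

    SHA-256 based, so adding a group never changes other groups' meshes.
    """
    digest = hashlib.sha256(
        f"{master_seed}:{group}:{replicate}:{salt}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def make_test_mesh(
    reference: TriangleMesh,
    recipe: DeformationRecipe,
    noise_seed: int,
    perturbation: RigidTransform,
) -> tuple[TriangleMesh, np.ndarray]:
    """Apply a recipe to the reference; returns (mesh, canonical vertices)."""
    m = reference
    if recipe.molar_widening:
        m = apply_molar_widening(m, recipe.molar_widening)
    if recipe.compression_factor != 1.0:
        m = apply_compression(m, recipe.compression_factor)
    m = apply_scan_noise(m, recipe.noise_sd, noise_seed)
    canonical = m.vertices.copy()
    return apply_rigid_perturbation(m, perturbation), canonical


def generate_study_set(
    spec: SyntheticArchSpec,
    group_plan: dict[str, DeformationRecipe],
    n_per_group: int,
    seed: int,
) -> StudySet:
    """Build the full synthetic study: one reference and n test scans per group.

    Per-mesh sub-seeds derive deterministically from ``seed`` so the whole
    StudySet is bit-reproducible and adding a group leaves others unchanged.
    """
    if not group_plan:
        raise ParameterError("group plan is empty")
    if n_per_group < 2:
        raise ParameterError("n_per_group must be >= 2")
    reference = generate_reference_arch(spec)
    groups: dict[str, list[TriangleMesh]] = {}
    truth: dict[str, list[GroundTruth]] = {}
    for name, recipe in group_plan.items():
        groups[name] = []
        truth[name] = []
        for i in range(n_per_group):
            noise_seed = derive_subseed(seed, name, i, "noise")
            rng = np.random.default_rng(derive_subseed(seed, name, i, "pose"))
            perturbation = random_rigid_transform(
                rng, spec.max_rotation_deg, spec.max_translation
            )
            mesh, canonical = make_test_mesh(reference, recipe, noise_seed, perturbation)
            groups[name].append(mesh)
            truth[name].append(
                GroundTruth(
                    group=name,
                    replicate=i,
                    recipe=recipe,
                    noise_seed=noise_seed,
                    perturbation=perturbation,
                    canonical_vertices=canonical,
                )
            )
    return StudySet(reference=reference, groups=groups, ground_truth=truth)


#: Default group plan emulating the study's three scan workflows: an
#: intraoral-scan-like group (posterior widening, low noise), a print-like
#: group (the same widening carried through, then compression overshooting
#: it, moderate noise) and a gypsum-like group (no systematic deformation,
#: high noise).  Magnitudes are chosen so group summaries land in the tens
#: of micrometres, the scale reported for real casts.
DEFAULT_GROUP_PLAN: dict[str, DeformationRecipe] = {
    "IOS": DeformationRecipe(molar_widening=0.02, noise_sd=0.010),
    "DLP": DeformationRecipe(
        molar_widening=0.02, compression_factor=0.9985, noise_sd=0.020
    ),
    "GYPSUM": DeformationRecipe(noise_sd=0.050),
}
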