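"""Shared fixtures: small synthetic meshes sized for fast, exact checks."""

from __future__ import annotations

import numpy as np
import pytest

from castmetric.mesh import TriangleMesh
from castmetric.synthetic_data import SyntheticArchSpec, generate_reference_arch


@pytest.fixture(scope="session")
def small_spec() -> SyntheticArchSpec:
    """Coarse arch: enough resolution for sub-µm geometry checks, fast ICP."""
    return SyntheticArchSpec(target_vertices=6000, seed=11)


@pytest.fixture(scope="session")
def small_arch(small_spec) -> TriangleMesh:
    return generate_reference_arch(small_spec)


@pytest.fixture(scope="session")
def medium_spec() -> SyntheticArchSpec:
    """Finer arch for checks sensitive to faceting error."""
    return SyntheticArchSpec(target_vertices=20_000, seed=11)


@pytest.fixture(scope="session")
def medium_arch(medium_spec) -> TriangleMesh:
    return generate_reference_arch(medium_spec)


@pytest.fixture()
def tetrahedron() -> TriangleMesh:
    """Unit tetrahedron, outward-wound: the smallest closed mesh."""
    vertices = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriangleMesh(vertices, faces)


@pytest.fixture()
def flat_patch() -> TriangleMesh:
    """10x10 mm planar grid in z = 0 with +z normals."""
    n = 12
    g = np.linspace(0.0, 10.0, n)
    xx, yy = np.meshgrid(g, g, indexing="ij")
    vertices = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(n * n)])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a, b = i * n + j, (i + 1) * n + j
            c, d = (i + 1) * n + j + 1, i * n + j + 1
            faces.append([a, b, c])
            faces.append([a, c, d])
    return TriangleMesh(vertices, np.array(faces))


def random_triangle_soup(rng: np.random.Generator, n_faces: int) -> TriangleMesh:
    """Unstructured triangles in a 10 mm cube (valid but unconnected mesh)."""
    anchors = rng.uniform(0, 10, (n_faces, 3))
    tris = anchors[:, None, :] + rng.normal(0, 1.2, (n_faces, 3, 3))
    vertices = tris.reshape(-1, 3)
    faces = np.arange(3 * n_faces).reshape(-1, 3)
    return TriangleMesh(vertices, faces)
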