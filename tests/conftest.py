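"""Shared fixtures: canonical meshes and small phantom cases."""

import numpy as np
import pytest
import trimesh

from organmatch.mesh_io import TriMesh, validate_mesh


@pytest.fixture(scope="session")
def cube10():
    """Closed unit-style cube spanning [0, 10]^3 (8 vertices, 12 faces)."""
    box = trimesh.creation.box(extents=(10.0, 10.0, 10.0))
    box.apply_translation((5.0, 5.0, 5.0))
    return validate_mesh(TriMesh(box.vertices, box.faces, "cube"))


@pytest.fixture(scope="session")
def icosphere10():
    """Icosphere of radius 10 mm, subdivision 3 (642 vertices)."""
    ico = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    return validate_mesh(TriMesh(ico.vertices, ico.faces, "sphere"))


@pytest.fixture(scope="session")
def icosphere_coarse():
    """Icosphere of radius 10 mm, subdivision 2 (162 vertices)."""
    ico = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
    return validate_mesh(TriMesh(ico.vertices, ico.faces, "sphere"))


def brute_force_ray_parity(points, mesh, seed=123):
    """Independent containment oracle: crossing parity of one jittered ray
    per point, Möller-Trumbore over every triangle."""
    rng = np.random.default_rng(seed)
    tri = mesh.triangles
    v0 = tri[:, 0]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    out = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(np.atleast_2d(points)):
        while True:
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            h = np.cross(d, e2)
            det = np.einsum("ij,ij->i", e1, h)
            if np.any(np.abs(det) < 1e-12):
                continue
            inv = 1.0 / det
            s = p - v0
            u = np.einsum("ij,ij->i", s, h) * inv
            q = np.cross(s, e1)
            v = q @ d * inv
            t = np.einsum("ij,ij->i", e2, q) * inv
            hit = (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 0)
            near_edge = hit & ((u < 1e-9) | (v < 1e-9) | (1 - u - v < 1e-9))
            if near_edge.any():
                continue
            out[i] = bool(hit.sum() % 2)
            break
    return out
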