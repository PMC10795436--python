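"""Reading, writing and validation of triangular organ-surface meshes.

All coordinates are millimetres in the LPS patient frame
(+x left, +y posterior, +z superior).  File formats carry no unit
metadata; values are taken as mm verbatim.

Validation guarantees the invariants every downstream computation relies
on: vertices deduplicated (tolerance 1e-6 mm), the surface closed (every
edge shared by exactly two faces) and consistently wound with outward
normals (signed volume > 0).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy.spatial import cKDTree

__all__ = [
    "TriMesh",
    "MeshFormatError",
    "MeshValidationError",
    "read_mesh",
    "write_mesh",
    "validate_mesh",
]

#: vertices closer than this (mm) are merged during validation
DEDUP_TOL = 1e-6

_FORMATS = {".stl": "stl", ".ply": "ply", ".obj": "obj"}


class MeshFormatError(ValueError):
    """The file could not be parsed as a supported mesh format."""


class MeshValidationError(ValueError):
    """The mesh violates a structural invariant that cannot be repaired."""


@dataclass(frozen=True)
class TriMesh:
    """A closed triangulated organ surface in patient coordinates (mm).

    Instances produced by :func:`read_mesh` / :func:`validate_mesh` are
    deduplicated, closed and consistently wound with outward normals.
    """

    vertices: np.ndarray  # (n, 3) float64, mm
    faces: np.ndarray  # (m, 3) int64 vertex indices
    label: str = field(default="")

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshValidationError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshValidationError(f"faces must be (m, 3), got {f.shape}")
        if len(v) == 0 or len(f) == 0:
            raise MeshValidationError("mesh has no vertices or no faces")
        if f.min() < 0 or f.max() >= len(v):
            raise MeshValidationError("face index out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape (m, 3, 3)."""
        return self.vertices[self.faces]

    @property
    def is_closed(self) -> bool:
        """True iff every undirected edge is shared by exactly two faces
        (computed once and memoized; topology is immutable)."""
        cached = getattr(self, "_is_closed", None)
        if cached is None:
            e = np.sort(
                self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
            )
            _, counts = np.unique(e, axis=0, return_counts=True)
            cached = bool((counts == 2).all())
            object.__setattr__(self, "_is_closed", cached)
        return cached

    def volume(self) -> float:
        """Enclosed volume (mm³) by the divergence theorem; positive for
        outward-wound closed surfaces."""
        a, b, c = (self.triangles[:, i, :] for i in range(3))
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def with_label(self, label: str) -> "TriMesh":
        return replace(self, label=label)


# ---------------------------------------------------------------------------
# validation


def _dedup_vertices(vertices: np.ndarray, faces: np.ndarray, tol: float):
    """Merge vertices closer than ``tol`` (union-find over close pairs)."""
    n = len(vertices)
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(vertices)
    for i, j in tree.query_pairs(tol):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    root = np.array([find(i) for i in range(n)])
    uniq, inverse = np.unique(root, return_inverse=True)
    new_vertices = vertices[uniq]
    new_faces = inverse[faces]
    # drop degenerate faces created by merging
    ok = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    return new_vertices, new_faces[ok]


def _edge_map(faces: np.ndarray) -> dict:
    """Undirected edge -> list of (face index, directed orientation)."""
    edges: dict = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (min(u, v), max(u, v))
            edges.setdefault(key, []).append((fi, u < v))
    return edges


def _check_closed(faces: np.ndarray) -> None:
    for (u, v), uses in _edge_map(faces).items():
        if len(uses) != 2:
            raise MeshValidationError(
                f"surface is not closed: edge ({u}, {v}) is shared by "
                f"{len(uses)} face(s), expected exactly 2"
            )


def _fix_winding(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Make winding consistent by BFS propagation across shared edges,
    then orient outward (signed volume > 0)."""
    faces = faces.copy()
    edge_faces: dict = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            edge_faces.setdefault((min(u, v), max(u, v)), []).append(fi)

    def directed_edges(f):
        a, b, c = f
        return ((a, b), (b, c), (c, a))

    visited = np.zeros(len(faces), dtype=bool)
    for seed in range(len(faces)):
        if visited[seed]:
            continue
        stack = [seed]
        visited[seed] = True
        while stack:
            fi = stack.pop()
            for u, v in directed_edges(faces[fi]):
                key = (min(u, v), max(u, v))
                for fj in edge_faces[key]:
                    if fj == fi or visited[fj]:
                        continue
                    # consistent winding: the shared edge must appear with
                    # opposite direction in the neighbour
                    if (u, v) in directed_edges(faces[fj]):
                        faces[fj] = faces[fj][::-1]
                    visited[fj] = True
                    stack.append(fj)

    signed = np.einsum(
        "ij,ij->i",
        vertices[faces[:, 0]],
        np.cross(vertices[faces[:, 1]], vertices[faces[:, 2]]),
    ).sum()
    if signed < 0:
        faces = faces[:, ::-1]
    return faces


def validate_mesh(mesh: TriMesh) -> TriMesh:
    """Return a validated copy: deduplicated, closed, outward-wound.

    Raises :class:`MeshValidationError` (naming the defect) if the surface
    is open or otherwise unrepairable.  Idempotent: validating a validated
    mesh returns an identical mesh.
    """
    v, f = _dedup_vertices(mesh.vertices, mesh.faces, DEDUP_TOL)
    if len(f) == 0:
        raise MeshValidationError("no non-degenerate faces after deduplication")
    _check_closed(f)
    f = _fix_winding(v, f)
    out = TriMesh(v, f, mesh.label)
    if out.volume() <= 0:
        raise MeshValidationError("mesh has non-positive enclosed volume")
    return out


# ---------------------------------------------------------------------------
# file I/O (format parsing delegated to trimesh)


def read_mesh(path, label: str = "", max_vertices: int | None = None) -> TriMesh:
    """Read an STL (binary or ASCII), PLY or OBJ file into a validated TriMesh.

    Parameters
    ----------
    path : str or Path
        Mesh file; format inferred from the extension.
    label : str
        Organ name attached to the mesh (e.g. ``"cervix"``).
    max_vertices : int, optional
        If given, emit a ``UserWarning`` when the validated mesh exceeds
        this vertex count (dense meshes slow the optimizer down).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    ext = path.suffix.lower()
    if ext not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {ext!r} (use .stl/.ply/.obj)")
    try:
        tm = _trimesh.load(str(path), file_type=_FORMATS[ext], force="mesh", process=False)
    except Exception as exc:  # parsing failure in any backend
        raise MeshFormatError(f"could not parse {path}: {exc}") from exc
    if not isinstance(tm, _trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangulated surface")
    mesh = validate_mesh(TriMesh(tm.vertices, tm.faces, label))
    if max_vertices is not None and mesh.n_vertices > max_vertices:
        import warnings

        warnings.warn(
            f"{path} has {mesh.n_vertices} vertices (> {max_vertices}); "
            "matching time grows linearly with vertex count",
            stacklevel=2,
        )
    return mesh


def write_mesh(mesh: TriMesh, path, file_format: str | None = None) -> None:
    """Write a TriMesh to STL (binary), PLY (ASCII) or OBJ.

    Round-trip contract: reading the written file reproduces the vertices
    within 1e-5 mm and identical face topology.
    """
    path = Path(path)
    fmt = file_format or _FORMATS.get(path.suffix.lower())
    if fmt not in {"stl", "ply", "obj"}:
        raise MeshFormatError(f"unsupported output format {fmt!r}")
    tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    kwargs = {"encoding": "ascii"} if fmt == "ply" else {}
    data = tm.export(file_type=fmt, **kwargs)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
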