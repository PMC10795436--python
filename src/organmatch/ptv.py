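"""Planning target volume construction and vertex-based coverage.

The PTV is the reference (planning) organ surface expanded by safety
margins.  Two margin policies are built in:

* ``ptv_iso_5mm`` — a uniform 5 mm margin on both organs,
* ``ptv_aniso_default`` — direction-dependent margins, (R, L, A, P, S, I)
  = (5, 5, 15, 15, 10, 10) mm for the cervix and (10, 10, 20, 20, 15, 15)
  mm for the uterus (cervix margins 5 mm smaller than uterine in every
  direction), reflecting the anisotropy of cervix/uterus motion.

Expansion displaces each vertex outward along its area-weighted normal n
by ``m(n) = ||(m_x n_x, m_y n_y, m_z n_z)||`` where each ``m_*`` is the
margin of the anatomical direction the normal component points to (LPS:
n_x < 0 is rightward, n_y < 0 anterior, n_z < 0 inferior).  For an
isotropic margin this is a uniform normal offset.  This octant-wise
directional offset approximates a Minkowski sum with an octant-wise
ellipsoid; exact Minkowski expansion is out of scope.

Coverage is the fraction of daily organ-mesh vertices contained in the
PTV, where the PTV containment predicate is "inside either expanded
organ surface".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .cost import WeightSet
from .geometry import winding_number, point_surface_distance, ON_SURFACE_TOL
from .matcher import MatchResult, auto_match
from .mesh_io import TriMesh, validate_mesh

__all__ = [
    "OrganMargins",
    "MarginSpec",
    "CoverageResult",
    "PTV",
    "margin_preset",
    "expand_mesh",
    "build_ptv",
    "coverage",
    "evaluate_fraction",
]

_DIRECTIONS = ("R", "L", "A", "P", "S", "I")


@dataclass(frozen=True)
class OrganMargins:
    """Six directional margins in mm: right, left, anterior, posterior,
    superior, inferior."""

    R: float
    L: float
    A: float
    P: float
    S: float
    I: float

    def __post_init__(self) -> None:
        if any(getattr(self, d) < 0 for d in _DIRECTIONS):
            raise ValueError("margins must be non-negative")

    @classmethod
    def isotropic(cls, margin: float) -> "OrganMargins":
        return cls(*([float(margin)] * 6))

    @property
    def is_isotropic(self) -> bool:
        vals = self.as_tuple()
        return all(v == vals[0] for v in vals)

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, d) for d in _DIRECTIONS)


@dataclass(frozen=True)
class MarginSpec:
    """Per-organ margin sets plus a label for reports."""

    cervix: OrganMargins
    uterus: OrganMargins
    name: str = ""

    @classmethod
    def from_config(cls, path) -> "MarginSpec":
        """YAML/JSON: either ``{"preset": "ptv_iso_5mm"}`` or explicit
        ``{"cervix": [R, L, A, P, S, I], "uterus": [...]}`` lists in mm."""
        path = Path(path)
        with open(path) as fh:
            data = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        if "preset" in data:
            return margin_preset(data["preset"])
        return cls(
            cervix=OrganMargins(*[float(v) for v in data["cervix"]]),
            uterus=OrganMargins(*[float(v) for v in data["uterus"]]),
            name=str(data.get("name", "")),
        )


_PRESETS = {
    "ptv_iso_5mm": MarginSpec(
        cervix=OrganMargins.isotropic(5.0), uterus=OrganMargins.isotropic(5.0),
        name="ptv_iso_5mm",
    ),
    "ptv_aniso_default": MarginSpec(
        cervix=OrganMargins(5.0, 5.0, 15.0, 15.0, 10.0, 10.0),
        uterus=OrganMargins(10.0, 10.0, 20.0, 20.0, 15.0, 15.0),
        name="ptv_aniso_default",
    ),
}


def margin_preset(name: str) -> MarginSpec:
    if name not in _PRESETS:
        raise ValueError(f"unknown margin preset {name!r}; valid: {sorted(_PRESETS)}")
    return _PRESETS[name]


def _vertex_normals(mesh: TriMesh) -> np.ndarray:
    tri = mesh.triangles
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # area-weighted
    vn = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], fn)
    return vn / np.linalg.norm(vn, axis=1, keepdims=True)


def directional_magnitude(normals: np.ndarray, margins: OrganMargins) -> np.ndarray:
    """Offset distance for each unit normal under the six-direction margin
    set: the Euclidean norm of the componentwise margin-scaled normal."""
    n = np.atleast_2d(normals)
    mx = np.where(n[:, 0] < 0, margins.R, margins.L)
    my = np.where(n[:, 1] < 0, margins.A, margins.P)
    mz = np.where(n[:, 2] < 0, margins.I, margins.S)
    return np.sqrt((mx * n[:, 0]) ** 2 + (my * n[:, 1]) ** 2 + (mz * n[:, 2]) ** 2)


def expand_mesh(reference: TriMesh, margins: OrganMargins) -> TriMesh:
    """Displace every vertex outward along its area-weighted normal by the
    directional margin magnitude.  Zero margins return the mesh unchanged;
    the result is re-validated (closed, outward-wound)."""
    if all(v == 0 for v in margins.as_tuple()):
        return reference
    normals = _vertex_normals(reference)
    mag = directional_magnitude(normals, margins)
    expanded = TriMesh(reference.vertices + mag[:, None] * normals, reference.faces, reference.label)
    return validate_mesh(expanded)


class PTV:
    """Containment predicate over the union of two expanded organ surfaces.

    ``contains`` is the authoritative semantics (inside either surface);
    :meth:`export_mesh` returns the two expanded shells concatenated into
    one mesh object for visualization — it is not a boolean union.
    """

    def __init__(self, cervix_expanded: TriMesh, uterus_expanded: TriMesh, name: str = ""):
        self.cervix_expanded = cervix_expanded
        self.uterus_expanded = uterus_expanded
        self.name = name

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        out = np.zeros(len(points), dtype=bool)
        for surf in (self.cervix_expanded, self.uterus_expanded):
            todo = ~out
            if not todo.any():
                break
            pts = points[todo]
            inside = winding_number(pts, surf) > 0.5
            near = point_surface_distance(pts, surf) < ON_SURFACE_TOL
            out[todo] |= inside | near
        return out

    def export_mesh(self) -> TriMesh:
        c, u = self.cervix_expanded, self.uterus_expanded
        return TriMesh(
            np.vstack([c.vertices, u.vertices]),
            np.vstack([c.faces, u.faces + c.n_vertices]),
            f"ptv_{self.name}" if self.name else "ptv",
        )


def build_ptv(ref_cervix: TriMesh, ref_uterus: TriMesh, spec: MarginSpec) -> PTV:
    """Expand both reference organs by their margin sets."""
    return PTV(
        expand_mesh(ref_cervix, spec.cervix),
        expand_mesh(ref_uterus, spec.uterus),
        name=spec.name,
    )


@dataclass(frozen=True)
class CoverageResult:
    """Fractions of daily-mesh vertices inside the PTV (0..1)."""

    fraction_cervix: float
    fraction_uterus: float
    n_cervix: int
    n_uterus: int

    @property
    def fraction_combined(self) -> float:
        total = self.n_cervix + self.n_uterus
        inside = self.fraction_cervix * self.n_cervix + self.fraction_uterus * self.n_uterus
        return inside / total

    def to_dict(self) -> dict:
        return {
            "fraction_cervix": self.fraction_cervix,
            "fraction_uterus": self.fraction_uterus,
            "fraction_combined": self.fraction_combined,
            "n_cervix": self.n_cervix,
            "n_uterus": self.n_uterus,
        }


def coverage(daily_cervix: TriMesh, daily_uterus: TriMesh, ptv: PTV) -> CoverageResult:
    """Per-organ and combined fractions of daily vertices inside the PTV."""
    in_c = ptv.contains(daily_cervix.vertices)
    in_u = ptv.contains(daily_uterus.vertices)
    return CoverageResult(
        fraction_cervix=float(in_c.mean()),
        fraction_uterus=float(in_u.mean()),
        n_cervix=daily_cervix.n_vertices,
        n_uterus=daily_uterus.n_vertices,
    )


def evaluate_fraction(
    daily_cervix: TriMesh,
    daily_uterus: TriMesh,
    ref_cervix: TriMesh,
    ref_uterus: TriMesh,
    weights: WeightSet,
    spec: MarginSpec,
    mode: str = "trans_and_rot",
    clamp_deg: float | None = 3.0,
) -> tuple[CoverageResult, MatchResult]:
    """Position the daily organs (translation alone or translation plus
    clamped rotation), then score them against the reference-built PTV."""
    match = auto_match(
        daily_cervix, daily_uterus, ref_cervix, ref_uterus, weights,
        clamp_deg=clamp_deg, mode=mode,
    )
    ptv = build_ptv(ref_cervix, ref_uterus, spec)
    cov = coverage(match.matched_cervix, match.matched_uterus, ptv)
    return cov, match
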