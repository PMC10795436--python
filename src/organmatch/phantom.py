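"""Synthetic pelvic phantoms: cervix/uterus surface pairs with known motion.

Real inputs to the matcher are meshes contoured on daily and planning MR
images, co-registered on the pelvic bones.  No such data ships with the
package, so this module fabricates geometrically comparable stand-ins:

* the cervix is a superellipsoid (semi-axes 15 x 15 x 20 mm, exponent
  2.5, i.e. squareness 0.8 — slightly boxy so rotations are observable
  in the cost; a sphere would make rotation about its centre a no-op),
* the uterus is a larger superellipsoid (25 x 20 x 40 mm) stacked
  superior-anterior to the cervix with its long axis anteverted 30°
  (tilted anteriorly from the S-I axis), which makes pitch the most
  identifiable rotation — matching the motion structure seen clinically,
* the daily pair is the reference pair moved by a known rigid transform
  about the pooled centroid, optionally followed by a smooth band-limited
  radial deformation.

Default inter-fraction motion sampling is anisotropic: A-P and S-I
translation half-widths (12 mm) are twice the R-L half-width (6 mm), and
rotation is pitch-dominant (true pitch uniform over [-6°, 14°], yaw/roll
over [-1°, 1°]).  Under these defaults roughly a sixth of fractions need
more than 10 mm of posterior/superior correction and essentially none
need it left-right — the regime reported for cervix/uterus motion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh as _trimesh

from .geometry import RigidTransform, apply_transform, centroid
from .mesh_io import TriMesh

__all__ = ["PhantomSpec", "PhantomCase", "superellipsoid_mesh", "make_phantom", "make_cohort"]

#: superellipsoid exponent: 2.0 is an ellipsoid, larger is boxier
_EXPONENT = 2.5


def superellipsoid_mesh(
    semi_axes, subdivisions: int = 2, exponent: float = _EXPONENT, label: str = ""
) -> TriMesh:
    """Closed superellipsoid |x/a|^p + |y/b|^p + |z/c|^p = 1, built by
    radially mapping an icosphere (so the triangulation is uniform and
    watertight by construction)."""
    ico = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = ico.vertices / np.linalg.norm(ico.vertices, axis=1, keepdims=True)
    a = np.asarray(semi_axes, dtype=float)
    r = (np.abs(u / a) ** exponent).sum(axis=1) ** (-1.0 / exponent)
    return TriMesh(u * r[:, None], ico.faces, label)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, true motion and noise of one synthetic fraction.

    ``translation`` / ``rotation`` are either fixed truths (3-vectors) or
    ``None``, in which case they are sampled uniformly from
    ``center ± half-width`` per axis using ``seed``.
    """

    seed: int = 0
    cervix_semi_axes: tuple = (15.0, 15.0, 20.0)
    uterus_semi_axes: tuple = (25.0, 20.0, 40.0)
    uterus_tilt_deg: float = 30.0  # anteversion: long axis tilted anterior
    uterus_offset: tuple = (0.0, -15.0, 45.0)  # uterus centre relative to cervix
    subdivisions: int = 2
    translation: tuple | None = None  # fixed (x, y, z) mm, or None to sample
    rotation: tuple | None = None  # fixed (pitch, yaw, roll) deg, or None
    translation_half_widths: tuple = (6.0, 12.0, 12.0)  # R-L, A-P, S-I mm
    translation_centers: tuple = (0.0, 0.0, 0.0)
    rotation_half_widths: tuple = (10.0, 1.0, 1.0)  # pitch, yaw, roll deg
    # true pitch displacement biased positive so the *corrective* pitch the
    # matcher reports has a negative median, as seen clinically
    rotation_centers: tuple = (4.0, 0.0, 0.0)
    deformation_amplitude: float = 0.0  # mm, 0 = exactly rigid


@dataclass(frozen=True)
class PhantomCase:
    ref_cervix: TriMesh
    ref_uterus: TriMesh
    daily_cervix: TriMesh
    daily_uterus: TriMesh
    truth: RigidTransform
    spec: PhantomSpec

    def truth_dict(self) -> dict:
        return {
            "translation_mm": [float(v) for v in self.truth.translation],
            "rotation_deg": {"pitch": self.truth.pitch, "yaw": self.truth.yaw, "roll": self.truth.roll},
            "center_mm": [float(v) for v in self.truth.center],
            "deformation_amplitude_mm": self.spec.deformation_amplitude,
            "seed": self.spec.seed,
        }

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth_dict(), fh, indent=2)


def _reference_pair(spec: PhantomSpec) -> tuple:
    cervix = superellipsoid_mesh(spec.cervix_semi_axes, spec.subdivisions, label="cervix")
    uterus = superellipsoid_mesh(spec.uterus_semi_axes, spec.subdivisions, label="uterus")
    tilt = RigidTransform(pitch=spec.uterus_tilt_deg, center=np.zeros(3))
    uterus = apply_transform(uterus, tilt)
    uterus = TriMesh(uterus.vertices + np.asarray(spec.uterus_offset, float), uterus.faces, "uterus")
    return cervix, uterus


def _smooth_radial_field(mesh: TriMesh, amplitude: float, rng: np.random.Generator) -> TriMesh:
    """Band-limited outward displacement: amplitude x a sum of three
    long-wavelength sinusoids of the vertex coordinates, applied along
    area-weighted vertex normals.  Wavelengths are on the organ scale, so
    the perturbation is smooth and keeps the surface closed for
    amplitudes up to ~20% of the smallest semi-axis."""
    v, f = mesh.vertices, mesh.faces
    extent = float(np.ptp(v, axis=0).max())
    g = np.zeros(len(v))
    for _ in range(3):
        w = rng.normal(size=3)
        w *= (2.0 * np.pi / extent) / np.linalg.norm(w)
        phase = rng.uniform(0, 2 * np.pi)
        g += rng.normal() * np.sin(v @ w + phase)
    g /= max(np.abs(g).max(), 1e-12)
    normals = _vertex_normals(v, f)
    return TriMesh(v + amplitude * g[:, None] * normals, f, mesh.label)


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = vertices[faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # area-weighted
    vn = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    return vn / np.linalg.norm(vn, axis=1, keepdims=True)


def make_phantom(spec: PhantomSpec) -> PhantomCase:
    """Build one fraction: reference pair, moved (and optionally deformed)
    daily pair, and the ground-truth transform.  Bit-reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    ref_cervix, ref_uterus = _reference_pair(spec)

    if spec.translation is not None:
        t = np.asarray(spec.translation, dtype=float)
    else:
        c = np.asarray(spec.translation_centers, float)
        w = np.asarray(spec.translation_half_widths, float)
        t = rng.uniform(c - w, c + w)
    if spec.rotation is not None:
        ang = np.asarray(spec.rotation, dtype=float)
    else:
        c = np.asarray(spec.rotation_centers, float)
        w = np.asarray(spec.rotation_half_widths, float)
        ang = rng.uniform(c - w, c + w)

    center = centroid(ref_cervix, ref_uterus)
    truth = RigidTransform(
        translation=t, pitch=float(ang[0]), yaw=float(ang[1]), roll=float(ang[2]), center=center
    )
    daily_cervix = apply_transform(ref_cervix, truth)
    daily_uterus = apply_transform(ref_uterus, truth)

    if spec.deformation_amplitude > 0:
        r_min = min(min(spec.cervix_semi_axes), min(spec.uterus_semi_axes))
        if spec.deformation_amplitude > 0.2 * r_min:
            raise ValueError(
                f"deformation amplitude {spec.deformation_amplitude} mm exceeds 20% of the "
                f"smallest semi-axis ({r_min} mm); the surface may self-intersect"
            )
        daily_cervix = _smooth_radial_field(daily_cervix, spec.deformation_amplitude, rng)
        daily_uterus = _smooth_radial_field(daily_uterus, spec.deformation_amplitude, rng)
        for m in (daily_cervix, daily_uterus):
            if m.volume() <= 0:
                raise ValueError("deformation inverted the surface")

    return PhantomCase(ref_cervix, ref_uterus, daily_cervix, daily_uterus, truth, spec)


def make_cohort(n_fractions: int, template: PhantomSpec | None = None, seed: int = 0) -> list:
    """n independent fractions; per-case seeds derived deterministically
    from the master seed (all seeds stay below 2**31)."""
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    template = template or PhantomSpec()
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n_fractions):
        case_seed = int(rng.integers(0, 2**31 - 1))
        cases.append(make_phantom(replace(template, seed=case_seed)))
    return cases
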