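"""PTV margin expansion and vertex coverage."""

import numpy as np
import pytest

from organmatch.geometry import RigidTransform, apply_transform
from organmatch.mesh_io import TriMesh
from organmatch.phantom import PhantomSpec, make_phantom
from organmatch.ptv import (
    CoverageResult,
    MarginSpec,
    OrganMargins,
    PTV,
    build_ptv,
    coverage,
    evaluate_fraction,
    expand_mesh,
    margin_preset,
)


def test_margin_presets_exact_values():
    iso = margin_preset("ptv_iso_5mm")
    assert iso.cervix.as_tuple() == (5,) * 6
    assert iso.uterus.as_tuple() == (5,) * 6
    assert iso.cervix.is_isotropic
    aniso = margin_preset("ptv_aniso_default")
    assert aniso.cervix.as_tuple() == (5, 5, 15, 15, 10, 10)
    assert aniso.uterus.as_tuple() == (10, 10, 20, 20, 15, 15)
    with pytest.raises(ValueError):
        margin_preset("ptv_huge")


def test_negative_margin_rejected():
    with pytest.raises(ValueError):
        OrganMargins(-1, 0, 0, 0, 0, 0)


@pytest.mark.parametrize("fmt", ["yaml", "json"])
def test_margin_config_round_trip(tmp_path, fmt):
    import json

    data = {"cervix": [5, 5, 15, 15, 10, 10], "uterus": [10, 10, 20, 20, 15, 15], "name": "aniso"}
    path = tmp_path / f"m.{fmt}"
    path.write_text(json.dumps(data))  # JSON is valid YAML too
    spec = MarginSpec.from_config(path)
    assert spec.cervix.as_tuple() == (5, 5, 15, 15, 10, 10)
    assert spec.uterus.as_tuple() == (10, 10, 20, 20, 15, 15)


def test_margin_config_preset(tmp_path):
    path = tmp_path / "m.yaml"
    path.write_text("preset: ptv_iso_5mm\n")
    assert MarginSpec.from_config(path).name == "ptv_iso_5mm"


def test_isotropic_expansion_of_sphere(icosphere10):
    """5 mm isotropic expansion of a 10 mm icosphere is a 15 mm sphere
    within 2% radial error at subdivision 3."""
    out = expand_mesh(icosphere10, OrganMargins.isotropic(5.0))
    r = np.linalg.norm(out.vertices, axis=1)
    assert np.abs(r - 15.0).max() < 0.02 * 15.0


def test_zero_margins_are_identity(icosphere10):
    out = expand_mesh(icosphere10, OrganMargins.isotropic(0.0))
    np.testing.assert_array_equal(out.vertices, icosphere10.vertices)


def test_directional_expansion_at_axis_aligned_normals(icosphere10):
    """Vertices whose normals align with -x, +y, +z move by the R (5), P
    (15) and S (10) margins respectively."""
    m = OrganMargins(5, 5, 15, 15, 10, 10)
    out = expand_mesh(icosphere10, m)
    for target, expected in [((-10, 0, 0), 5.0), ((0, 10, 0), 15.0), ((0, 0, 10), 10.0)]:
        i = int(np.argmin(np.linalg.norm(icosphere10.vertices - np.array(target), axis=1)))
        disp = np.linalg.norm(out.vertices[i] - icosphere10.vertices[i])
        assert disp == pytest.approx(expected, rel=1e-6)


def test_union_containment_of_disjoint_and_overlapping_spheres(icosphere10):
    far = TriMesh(icosphere10.vertices + np.array([50.0, 0, 0]), icosphere10.faces, "b")
    ptv = PTV(icosphere10, far)
    assert ptv.contains([[0, 0, 0], [50, 0, 0], [25, 0, 0]]).tolist() == [True, True, False]

    # spheres of radius 15 whose centers are 20 mm apart: the midpoint is
    # 10 mm from each center, inside both
    a = expand_mesh(icosphere10, OrganMargins.isotropic(5.0))
    b = TriMesh(a.vertices + np.array([20.0, 0, 0]), a.faces, "b")
    assert PTV(a, b).contains([[10.0, 0, 0]])[0]


def test_nested_union_equals_outer(icosphere10):
    inner = TriMesh(icosphere10.vertices * 0.3, icosphere10.faces, "inner")
    outer = expand_mesh(icosphere10, OrganMargins.isotropic(5.0))
    ptv = PTV(inner, outer)
    pts = np.random.default_rng(0).uniform(-20, 20, size=(50, 3))
    from organmatch.geometry import winding_number

    np.testing.assert_array_equal(ptv.contains(pts), winding_number(pts, outer) > 0.5)


def test_reference_organs_fully_covered_by_any_positive_margin():
    case = make_phantom(PhantomSpec(seed=20))
    spec = MarginSpec(OrganMargins.isotropic(1.0), OrganMargins.isotropic(1.0), "tight")
    ptv = build_ptv(case.ref_cervix, case.ref_uterus, spec)
    cov = coverage(case.ref_cervix, case.ref_uterus, ptv)
    assert cov.fraction_cervix == 1.0
    assert cov.fraction_uterus == 1.0
    assert cov.fraction_combined == 1.0


def test_coverage_counts_match_brute_force(icosphere10, icosphere_coarse):
    """Shifted 10 mm sphere against a 15 mm spherical PTV: the covered
    fraction equals the exhaustive count of vertices within 15 mm of the
    PTV center."""
    ptv_surf = expand_mesh(icosphere10, OrganMargins.isotropic(5.0))
    shifted = TriMesh(icosphere_coarse.vertices + np.array([7.0, 0, 0]), icosphere_coarse.faces, "d")
    ptv = PTV(ptv_surf, TriMesh(ptv_surf.vertices + 1000.0, ptv_surf.faces, "far"))
    cov = coverage(shifted, shifted, ptv)
    expected = float((np.linalg.norm(shifted.vertices, axis=1) < 15.0).mean())
    assert cov.fraction_cervix == pytest.approx(expected, abs=0.02)


def test_fully_exterior_daily_has_zero_coverage(icosphere_coarse, icosphere10):
    daily = TriMesh(icosphere_coarse.vertices + np.array([200.0, 0, 0]), icosphere_coarse.faces, "d")
    ptv = PTV(icosphere10, icosphere10)
    cov = coverage(daily, daily, ptv)
    assert cov.fraction_combined == 0.0


def test_coverage_monotone_in_margins():
    case = make_phantom(PhantomSpec(seed=21, translation=(6, 9, -7), rotation=(0, 0, 0)))
    fractions = []
    for m in (1.0, 5.0, 10.0, 20.0):
        spec = MarginSpec(OrganMargins.isotropic(m), OrganMargins.isotropic(m), f"iso{m}")
        ptv = build_ptv(case.ref_cervix, case.ref_uterus, spec)
        fractions.append(coverage(case.daily_cervix, case.daily_uterus, ptv).fraction_combined)
    assert all(a <= b + 1e-12 for a, b in zip(fractions, fractions[1:]))


def test_coverage_invariant_under_common_rigid_motion():
    case = make_phantom(PhantomSpec(seed=22, translation=(4, -6, 3), rotation=(0, 0, 0)))
    spec = margin_preset("ptv_iso_5mm")
    ptv = build_ptv(case.ref_cervix, case.ref_uterus, spec)
    before = coverage(case.daily_cervix, case.daily_uterus, ptv)
    tf = RigidTransform(translation=(9, -2, 5), pitch=15.0, yaw=7.0, roll=-4.0, center=(0, 0, 20))
    ptv_moved = PTV(apply_transform(ptv.cervix_expanded, tf), apply_transform(ptv.uterus_expanded, tf))
    after = coverage(
        apply_transform(case.daily_cervix, tf), apply_transform(case.daily_uterus, tf), ptv_moved
    )
    assert before.fraction_cervix == after.fraction_cervix
    assert before.fraction_uterus == after.fraction_uterus


def test_evaluate_fraction_identity_and_translation():
    case = make_phantom(PhantomSpec(seed=23, translation=(0, 0, 0), rotation=(0, 0, 0)))
    from organmatch.cost import scenario

    cov, match = evaluate_fraction(
        case.daily_cervix, case.daily_uterus, case.ref_cervix, case.ref_uterus,
        scenario("A"), margin_preset("ptv_iso_5mm"), mode="trans_only",
    )
    assert cov.fraction_combined == 1.0
    np.testing.assert_array_equal(match.translation, np.zeros(3))

    moved = make_phantom(PhantomSpec(seed=24, translation=(8, -11, 6), rotation=(0, 0, 0)))
    cov2, match2 = evaluate_fraction(
        moved.daily_cervix, moved.daily_uterus, moved.ref_cervix, moved.ref_uterus,
        scenario("A"), margin_preset("ptv_iso_5mm"), mode="trans_and_rot", clamp_deg=3.0,
    )
    assert cov2.fraction_combined == 1.0  # residual under the floor << 5 mm margin


def test_ptv_export_mesh_concatenates_shells(icosphere10):
    ptv = PTV(icosphere10, TriMesh(icosphere10.vertices + 40.0, icosphere10.faces, "b"), "iso")
    merged = ptv.export_mesh()
    assert merged.n_vertices == 2 * icosphere10.n_vertices
    assert merged.n_faces == 2 * icosphere10.n_faces
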