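"""The step-halving positioning search: recovery, monotonicity, clamping."""

import numpy as np
import pytest

from organmatch.cost import organ_cost, scenario
from organmatch.matcher import (
    ROTATION_FLOOR_DEG,
    TRANSLATION_FLOOR_MM,
    auto_match,
    rotational_positioning,
    translational_positioning,
)
from organmatch.mesh_io import TriMesh
from organmatch.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="module")
def matched_case():
    return make_phantom(PhantomSpec(seed=1, translation=(0, 0, 0), rotation=(0, 0, 0)))


def test_already_matched_pair_stays_put(matched_case):
    c = matched_case
    w = scenario("A")
    res = auto_match(c.daily_cervix, c.daily_uterus, c.ref_cervix, c.ref_uterus, w)
    np.testing.assert_array_equal(res.translation, np.zeros(3))
    assert res.pitch == res.yaw == res.roll == 0.0
    assert res.final_cost.total == 0.0
    assert not any(e.accepted for e in res.trace.entries)


def test_known_translation_recovered_within_floor():
    c = make_phantom(PhantomSpec(seed=2, translation=(6, -8, 4), rotation=(0, 0, 0)))
    res = auto_match(c.daily_cervix, c.daily_uterus, c.ref_cervix, c.ref_uterus, scenario("A"))
    np.testing.assert_array_less(np.abs(res.translation - np.array([-6.0, 8.0, -4.0])),
                                 TRANSLATION_FLOOR_MM + 1e-12)


def test_subfloor_displacement_residual_bounded():
    """A 0.4 mm displacement is below the 1 mm step floor: either a 1 mm
    overshoot or no move, so the residual never exceeds 0.6 mm."""
    c = make_phantom(PhantomSpec(seed=3, translation=(0.4, 0, 0), rotation=(0, 0, 0)))
    res = translational_positioning(
        c.daily_cervix, c.daily_uterus, c.ref_cervix, c.ref_uterus, scenario("A")
    )
    residual = res.translation[0] + 0.4
    assert abs(residual) <= 0.6 + 1e-12


def test_pure_pitch_recovered_within_floor():
    c = make_phantom(PhantomSpec(seed=4, translation=(0, 0, 0), rotation=(10, 0, 0)))
    res = rotational_positioning(
        c.daily_cervix, c.daily_uterus, c.ref_cervix, c.ref_uterus, scenario("A")
    )
    assert abs(res.pitch + 10.0) <= ROTATION_FLOOR_DEG
    assert abs(res.yaw) <= ROTATION_FLOOR_DEG
    assert abs(res.roll) <= ROTATION_FLOOR_DEG


def test_roll_recovery_is_weaker_than_pitch():
    """Roll of the anteverted uterus is first-order degenerate with yaw
    (both tip the long axis the same way), so the greedy axis-aligned
    search can stall short of the 0.5° floor on roll.  The net orientation
    still matches: the final cost is far below the original, and the roll
    residual stays within a degree."""
    c = make_phantom(PhantomSpec(seed=5, translation=(0, 0, 0), rotation=(0, 0, -12.0)))
    res = rotational_positioning(
        c.daily_cervix, c.daily_uterus, c.ref_cervix, c.ref_uterus, scenario("A")
    )
    assert abs(res.roll - 12.0) <= 1.0
    assert res.final_cost.total < 0.05 * res.trace.original_cost


def test_trace_invariants_on_mixed_motion():
    c = make_phantom(PhantomSpec(seed=6, translation=(5, -9, 7), rotation=(8, 0, 0),
                                 deformation_amplitude=1.0))
    res = auto_match(c.daily_cervix, c.daily_uterus, c.ref_cervix, c.ref_uterus, scenario("B"))
    assert res.final_cost.total <= res.trace.original_cost
    floors = {"translation": TRANSLATION_FLOOR_MM, "rotation": ROTATION_FLOOR_DEG}
    last_step: dict = {}
    prev_iter: dict = {}
    for e in res.trace.entries:
        if e.accepted:
            assert e.cost_after < e.cost_before
        if not e.skipped:
            assert e.step >= floors[e.phase] - 1e-12
        # commanded magnitudes never increase within a phase
        key = (e.phase, e.axis)
        if key in last_step and e.iteration > prev_iter[key]:
            assert e.step <= last_step[key] + 1e-12
        last_step[key], prev_iter[key] = e.step, e.iteration
    accepted = res.trace.accepted_costs()
    assert np.all(np.diff(accepted) < 0) if len(accepted) > 1 else True


def test_trace_ends_with_rejected_floor_sweep():
    c = make_phantom(PhantomSpec(seed=7, translation=(4, 2, -3), rotation=(0, 0, 0)))
    res = translational_positioning(
        c.daily_cervix, c.daily_uterus, c.ref_cervix, c.ref_uterus, scenario("A")
    )
    tail = res.trace.entries[-6:]
    assert all(not e.accepted for e in tail)
    assert all(e.step == pytest.approx(TRANSLATION_FLOOR_MM) for e in tail)


def test_determinism_bitwise():
    c = make_phantom(PhantomSpec(seed=8))
    w = scenario("C")
    r1 = auto_match(c.daily_cervix, c.daily_uterus, c.ref_cervix, c.ref_uterus, w, clamp_deg=3.0)
    r2 = auto_match(c.daily_cervix, c.daily_uterus, c.ref_cervix, c.ref_uterus, w, clamp_deg=3.0)
    assert r1.trace.to_frame().equals(r2.trace.to_frame())
    np.testing.assert_array_equal(r1.matched_cervix.vertices, r2.matched_cervix.vertices)
    assert (r1.pitch, r1.yaw, r1.roll) == (r2.pitch, r2.yaw, r2.roll)


def test_clamp_limits_every_axis():
    c = make_phantom(PhantomSpec(seed=9, translation=(2, -4, 3), rotation=(10, 0, 0)))
    res = auto_match(c.daily_cervix, c.daily_uterus, c.ref_cervix, c.ref_uterus,
                     scenario("A"), clamp_deg=3.0)
    assert abs(res.pitch) <= 3.0 + 1e-9
    assert abs(res.yaw) <= 3.0 + 1e-9
    assert abs(res.roll) <= 3.0 + 1e-9


def test_zero_clamp_equals_translation_only():
    c = make_phantom(PhantomSpec(seed=10, translation=(3, 5, -2), rotation=(6, 0, 0)))
    w = scenario("A")
    r0 = auto_match(c.daily_cervix, c.daily_uterus, c.ref_cervix, c.ref_uterus, w, clamp_deg=0.0)
    rt = auto_match(c.daily_cervix, c.daily_uterus, c.ref_cervix, c.ref_uterus, w, mode="trans_only")
    np.testing.assert_array_equal(r0.matched_cervix.vertices, rt.matched_cervix.vertices)
    np.testing.assert_array_equal(r0.matched_uterus.vertices, rt.matched_uterus.vertices)
    assert r0.pitch == r0.yaw == r0.roll == 0.0


def test_scenario_c_prioritizes_cervix():
    """When the organs disagree (cervix displaced posteriorly, uterus
    anteriorly), the cervix-focused weights must leave the cervix at
    least as well aligned as the unweighted scenario."""
    base = make_phantom(PhantomSpec(seed=11, translation=(0, 0, 0), rotation=(0, 0, 0)))
    dc = TriMesh(base.daily_cervix.vertices + np.array([0, 8.0, 0]), base.daily_cervix.faces, "cervix")
    du = TriMesh(base.daily_uterus.vertices + np.array([0, -8.0, 0]), base.daily_uterus.faces, "uterus")
    final = {}
    for name in ("A", "C"):
        r = auto_match(dc, du, base.ref_cervix, base.ref_uterus, scenario(name))
        final[name] = organ_cost(r.matched_cervix, base.ref_cervix, 1.0, 1.0).cost
    assert final["C"] <= final["A"] + 1e-12


def test_unknown_mode_rejected(matched_case):
    c = matched_case
    with pytest.raises(ValueError):
        auto_match(c.daily_cervix, c.daily_uterus, c.ref_cervix, c.ref_uterus,
                   scenario("A"), mode="rot_only")


def test_eval_cap_flags_trace():
    c = make_phantom(PhantomSpec(seed=12, translation=(25, -28, 22), rotation=(0, 0, 0)))
    res = auto_match(c.daily_cervix, c.daily_uterus, c.ref_cervix, c.ref_uterus,
                     scenario("A"), eval_cap=5)
    assert res.trace.cap_exceeded
    assert res.final_cost.total <= res.trace.original_cost


def test_match_result_export(tmp_path):
    c = make_phantom(PhantomSpec(seed=13, translation=(6, 2, -4), rotation=(0, 0, 0)))
    res = auto_match(c.daily_cervix, c.daily_uterus, c.ref_cervix, c.ref_uterus, scenario("A"))
    res.to_json(tmp_path / "m.json")
    res.trace.to_csv(tmp_path / "t.csv")
    import json

    d = json.loads((tmp_path / "m.json").read_text())
    assert set(d["translation_directions_mm"]) == {"R", "L", "A", "P", "S", "I"}
    # signed translation maps onto one-sided anatomical magnitudes
    x = d["translation_mm"][0]
    assert d["translation_directions_mm"]["L" if x > 0 else "R"] == pytest.approx(abs(x))
    import pandas as pd

    df = pd.read_csv(tmp_path / "t.csv")
    assert {"phase", "iteration", "step", "axis", "sign", "accepted"} <= set(df.columns)
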