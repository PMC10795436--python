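"""Step-halving rigid positioning of the daily organ pair.

The daily cervix and uterus move together as one rigid body.  Starting
from the bone-matched position, a translational phase runs first, then a
rotational phase — each a "dichotomy" search:

* translation: the first move is the full pooled-centroid difference
  between reference and daily meshes; subsequent per-axis step
  magnitudes halve each iteration, floored at 1 mm (couch translation
  accuracy).  At each magnitude, signed axis moves (x+, x-, y+, y-, z+,
  z-) are tried in fixed order and accepted greedily on strict cost
  decrease; the sweep repeats until it accepts nothing, then the steps
  halve.  A rejected full sweep at the 1 mm floor ends the phase.
* rotation: same scheme with an initial 45° magnitude, halving to a
  0.5° floor (couch rotation accuracy), candidates ±pitch, ±yaw, ±roll
  about the pooled daily centroid fixed at the start of the phase.  An
  optional clamp (±3° by default in coverage evaluation, the couch
  rotation tolerance) skips any candidate that would push a cumulative
  axis angle past the limit.

Every attempted move is recorded in a trace; accepted moves strictly
decrease the cost, so the final cost never exceeds the original
(bone-matched) cost and termination is guaranteed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .cost import CostBreakdown, WeightSet, total_cost
from .geometry import centroid
from .mesh_io import TriMesh

__all__ = [
    "TraceEntry",
    "OptimizationTrace",
    "MatchResult",
    "translational_positioning",
    "rotational_positioning",
    "auto_match",
    "TRANSLATION_FLOOR_MM",
    "ROTATION_FLOOR_DEG",
    "INITIAL_ROTATION_DEG",
]

#: minimum translational couch correction (mm)
TRANSLATION_FLOOR_MM = 1.0
#: minimum rotational couch correction (degrees)
ROTATION_FLOOR_DEG = 0.5
#: first exploratory rotation magnitude (degrees)
INITIAL_ROTATION_DEG = 45.0

#: relative tolerance for "the cost decreased": exact ties revert
_DECREASE_RTOL = 1e-9

_AXES = np.eye(3)
_ROT_AXIS_NAMES = ("pitch", "yaw", "roll")
#: rotation axis unit vectors in LPS: pitch about x, yaw about z, roll about y
_ROT_AXES = {"pitch": np.array([1.0, 0, 0]), "yaw": np.array([0, 0, 1.0]), "roll": np.array([0, 1.0, 0])}


@dataclass(frozen=True)
class TraceEntry:
    phase: str  # "translation" | "rotation"
    iteration: int  # magnitude index M (1 = initial full move / 45 degrees)
    step: float  # commanded magnitude (mm or degrees)
    axis: str  # "x"|"y"|"z"|"centroid"|"pitch"|"yaw"|"roll"
    sign: int
    cost_before: float
    cost_after: float  # NaN for clamp-skipped candidates (never evaluated)
    accepted: bool
    skipped: bool = False  # True when the rotation clamp vetoed the candidate


@dataclass
class OptimizationTrace:
    original_cost: float
    entries: list = field(default_factory=list)
    cap_exceeded: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "original_cost": self.original_cost,
                    "cap_exceeded": self.cap_exceeded,
                    "entries": [e.__dict__ for e in self.entries],
                },
                fh,
                indent=2,
            )

    def accepted_costs(self) -> np.ndarray:
        return np.array([e.cost_after for e in self.entries if e.accepted])


@dataclass(frozen=True)
class MatchResult:
    """Outcome of positioning: accumulated couch correction and diagnostics."""

    translation: np.ndarray  # accumulated (x, y, z) mm, LPS signed
    pitch: float  # accumulated degrees about x
    yaw: float  # accumulated degrees about z
    roll: float  # accumulated degrees about y
    rotation_center: np.ndarray | None
    original_cost: CostBreakdown
    final_cost: CostBreakdown
    trace: OptimizationTrace
    clamp_deg: float | None
    matched_cervix: TriMesh
    matched_uterus: TriMesh

    def anatomical_translation(self) -> dict:
        """Per-direction magnitudes under the LPS sign map."""
        x, y, z = self.translation
        return {
            "L": max(x, 0.0), "R": max(-x, 0.0),
            "P": max(y, 0.0), "A": max(-y, 0.0),
            "S": max(z, 0.0), "I": max(-z, 0.0),
        }

    def to_dict(self) -> dict:
        return {
            "translation_mm": [float(v) for v in self.translation],
            "translation_directions_mm": self.anatomical_translation(),
            "rotation_deg": {"pitch": self.pitch, "yaw": self.yaw, "roll": self.roll},
            "rotation_center_mm": None
            if self.rotation_center is None
            else [float(v) for v in self.rotation_center],
            "clamp_deg": self.clamp_deg,
            "original_cost": self.original_cost.to_dict(),
            "final_cost": self.final_cost.to_dict(),
            "cap_exceeded": self.trace.cap_exceeded,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class _CapExceeded(Exception):
    pass


class _State:
    """Current daily vertex positions plus a capped cost evaluator."""

    def __init__(self, cervix, uterus, ref_cervix, ref_uterus, weights, eval_cap):
        self.vc = cervix.vertices.copy()
        self.vu = uterus.vertices.copy()
        self.fc, self.fu = cervix.faces, uterus.faces
        self.lc, self.lu = cervix.label, uterus.label
        self.ref_cervix, self.ref_uterus = ref_cervix, ref_uterus
        self.weights = weights
        self.eval_cap = eval_cap
        self.evals = 0

    def meshes(self):
        return TriMesh(self.vc, self.fc, self.lc), TriMesh(self.vu, self.fu, self.lu)

    def cost_at(self, vc, vu) -> CostBreakdown:
        if self.evals >= self.eval_cap:
            raise _CapExceeded
        self.evals += 1
        return total_cost(
            TriMesh(vc, self.fc, self.lc),
            TriMesh(vu, self.fu, self.lu),
            self.ref_cervix,
            self.ref_uterus,
            self.weights,
        )


def _decreased(before: float, after: float) -> bool:
    return (before - after) > _DECREASE_RTOL * max(abs(before), 1e-30)


def _make_result(state, trans, angles, center, original, current, trace, clamp):
    mc, mu = state.meshes()
    return MatchResult(
        translation=np.asarray(trans, dtype=float),
        pitch=float(angles[0]),
        yaw=float(angles[1]),
        roll=float(angles[2]),
        rotation_center=None if center is None else np.asarray(center, dtype=float),
        original_cost=original,
        final_cost=current,
        trace=trace,
        clamp_deg=clamp,
        matched_cervix=mc,
        matched_uterus=mu,
    )


def translational_positioning(
    daily_cervix: TriMesh,
    daily_uterus: TriMesh,
    ref_cervix: TriMesh,
    ref_uterus: TriMesh,
    weights: WeightSet,
    eval_cap: int = 500,
    _state: "_State | None" = None,
    _trace: "OptimizationTrace | None" = None,
) -> MatchResult:
    """Translational phase: centroid shift, then halving axis sweeps."""
    state = _state or _State(daily_cervix, daily_uterus, ref_cervix, ref_uterus, weights, eval_cap)
    current = state.cost_at(state.vc, state.vu)
    original = getattr(state, "_original_breakdown", current)
    trace = _trace or OptimizationTrace(original_cost=current.total)
    total_trans = np.zeros(3)

    try:
        # M = 1: the full centroid-difference move, accept/revert like any other
        v0 = centroid(ref_cervix, ref_uterus) - centroid(*state.meshes())
        cand = state.cost_at(state.vc + v0, state.vu + v0)
        ok = _decreased(current.total, cand.total)
        trace.entries.append(
            TraceEntry("translation", 1, float(np.linalg.norm(v0)), "centroid", 1,
                       current.total, cand.total, ok)
        )
        if ok:
            state.vc += v0
            state.vu += v0
            total_trans += v0
            current = cand

        # M >= 2: per-axis magnitudes halved from the centroid move, floored
        step = np.maximum(np.abs(v0) / 2.0, TRANSLATION_FLOOR_MM)
        m_index = 2
        while True:
            swept_accept = True
            while swept_accept:
                swept_accept = False
                for axis in range(3):
                    for sign in (1, -1):
                        dv = sign * step[axis] * _AXES[axis]
                        cand = state.cost_at(state.vc + dv, state.vu + dv)
                        ok = _decreased(current.total, cand.total)
                        trace.entries.append(
                            TraceEntry("translation", m_index, float(step[axis]), "xyz"[axis],
                                       sign, current.total, cand.total, ok)
                        )
                        if ok:
                            state.vc += dv
                            state.vu += dv
                            total_trans += dv
                            current = cand
                            swept_accept = True
            if np.all(step <= TRANSLATION_FLOOR_MM + 1e-12):
                break
            step = np.maximum(step / 2.0, TRANSLATION_FLOOR_MM)
            m_index += 1
    except _CapExceeded:
        trace.cap_exceeded = True

    return _make_result(state, total_trans, (0.0, 0.0, 0.0), None,
                        original, current, trace, None)


def rotational_positioning(
    daily_cervix: TriMesh,
    daily_uterus: TriMesh,
    ref_cervix: TriMesh,
    ref_uterus: TriMesh,
    weights: WeightSet,
    clamp_deg: float | None = None,
    eval_cap: int = 500,
    _state: "_State | None" = None,
    _trace: "OptimizationTrace | None" = None,
) -> MatchResult:
    """Rotational phase: 45° start, halving to the 0.5° floor, about the
    pooled daily centroid fixed at phase start."""
    state = _state or _State(daily_cervix, daily_uterus, ref_cervix, ref_uterus, weights, eval_cap)
    current = state.cost_at(state.vc, state.vu)
    original = getattr(state, "_original_breakdown", current)
    trace = _trace or OptimizationTrace(original_cost=current.total)
    center = centroid(*state.meshes())
    # finite rotations do not commute, so the couch-relevant total is the
    # NET orientation, tracked as a matrix and reported (and clamped) via
    # its pitch/roll/yaw decomposition in the package convention
    net = np.eye(3)

    def rotated(vertices, R):
        return (vertices - center) @ R.T + center

    try:
        mag = INITIAL_ROTATION_DEG
        m_index = 1
        while True:
            swept_accept = True
            while swept_accept:
                swept_accept = False
                for axis_name in _ROT_AXIS_NAMES:
                    for sign in (1, -1):
                        R_inc = Rotation.from_rotvec(
                            np.deg2rad(sign * mag) * _ROT_AXES[axis_name]
                        ).as_matrix()
                        cand_net = R_inc @ net
                        if clamp_deg is not None and np.any(
                            np.abs(_euler_pyr(cand_net)) > clamp_deg + 1e-9
                        ):
                            trace.entries.append(
                                TraceEntry("rotation", m_index, mag, axis_name, sign,
                                           current.total, float("nan"), False, skipped=True)
                            )
                            continue
                        vc = rotated(state.vc, R_inc)
                        vu = rotated(state.vu, R_inc)
                        cand = state.cost_at(vc, vu)
                        ok = _decreased(current.total, cand.total)
                        trace.entries.append(
                            TraceEntry("rotation", m_index, mag, axis_name, sign,
                                       current.total, cand.total, ok)
                        )
                        if ok:
                            state.vc, state.vu = vc, vu
                            net = cand_net
                            current = cand
                            swept_accept = True
            if mag <= ROTATION_FLOOR_DEG + 1e-12:
                break
            mag = max(mag / 2.0, ROTATION_FLOOR_DEG)
            m_index += 1
    except _CapExceeded:
        trace.cap_exceeded = True

    pitch, yaw, roll = _euler_pyr(net)
    return _make_result(state, np.zeros(3), (pitch, yaw, roll),
                        center, original, current, trace, clamp_deg)


def _euler_pyr(R: np.ndarray) -> np.ndarray:
    """Net rotation matrix -> (pitch, yaw, roll) degrees, extrinsic
    pitch(x)-roll(y)-yaw(z) convention."""
    x, y, z = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
    return np.array([x, z, y])


def auto_match(
    daily_cervix: TriMesh,
    daily_uterus: TriMesh,
    ref_cervix: TriMesh,
    ref_uterus: TriMesh,
    weights: WeightSet,
    clamp_deg: float | None = None,
    mode: str = "trans_and_rot",
    eval_cap: int = 500,
) -> MatchResult:
    """Full positioning: translational phase, then (optionally) rotational.

    ``mode`` is ``"trans_only"`` or ``"trans_and_rot"``.  Each phase has
    its own cost-evaluation cap.
    """
    if mode not in ("trans_only", "trans_and_rot"):
        raise ValueError(f"unknown mode {mode!r}")
    state = _State(daily_cervix, daily_uterus, ref_cervix, ref_uterus, weights, eval_cap)
    original = state.cost_at(state.vc, state.vu)
    state._original_breakdown = original
    state.evals = 0

    t_res = translational_positioning(
        daily_cervix, daily_uterus, ref_cervix, ref_uterus, weights,
        eval_cap=eval_cap, _state=state, _trace=None,
    )
    if mode == "trans_only":
        return t_res

    state.evals = 0  # per-phase cap
    r_res = rotational_positioning(
        t_res.matched_cervix, t_res.matched_uterus, ref_cervix, ref_uterus, weights,
        clamp_deg=clamp_deg, eval_cap=eval_cap, _state=state,
        _trace=OptimizationTrace(original_cost=t_res.trace.original_cost,
                                 entries=t_res.trace.entries,
                                 cap_exceeded=t_res.trace.cap_exceeded),
    )
    return replace(r_res, translation=t_res.translation)
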