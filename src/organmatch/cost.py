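"""The weighted two-organ vertex-to-surface cost.

For one organ, daily-mesh vertices are split into those outside the
closed reference surface (distances d, count i) and those inside
(distances D, count t), and

    Cost_organ = W_out * Σ d² / i  +  W_in * Σ D² / t

i.e. a weighted mean squared surface distance per group, in mm² scaled
by the dimensionless weights.  An empty group contributes 0.  The total
cost is the sum of the cervix and uterus costs, each organ scored
against its own reference.  W_out pulls stray vertices back toward the
surface; W_in penalizes vertices buried away from it, so only a daily
mesh lying exactly on the reference surface achieves zero cost.

Three preset weight scenarios are provided:

* ``A`` = (1, 1, 1, 1) — unweighted baseline,
* ``B`` = (10, 5, 10, 5) — outside vertices emphasized for both organs,
* ``C`` = (10, 5, 2, 0.5) — cervix alignment prioritized over the uterus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .geometry import classify_vertices
from .mesh_io import TriMesh

__all__ = ["WeightSet", "OrganCost", "CostBreakdown", "scenario", "organ_cost", "total_cost"]

_SCENARIOS = {
    "A": (1.0, 1.0, 1.0, 1.0),
    "B": (10.0, 5.0, 10.0, 5.0),
    "C": (10.0, 5.0, 2.0, 0.5),
}


@dataclass(frozen=True)
class WeightSet:
    """The four cost weights (order: W_out_cervix, W_in_cervix,
    W_out_uterus, W_in_uterus)."""

    w_out_cervix: float
    w_in_cervix: float
    w_out_uterus: float
    w_in_uterus: float
    name: str = ""

    def __post_init__(self) -> None:
        w = self.as_tuple()
        if any(x < 0 for x in w):
            raise ValueError("weights must be non-negative")
        if not any(x > 0 for x in w):
            raise ValueError("at least one weight must be positive")

    def as_tuple(self) -> tuple:
        return (self.w_out_cervix, self.w_in_cervix, self.w_out_uterus, self.w_in_uterus)

    @classmethod
    def from_config(cls, path) -> "WeightSet":
        """Load from a YAML/JSON mapping with the four weight keys and an
        optional ``name``, or a mapping ``{"scenario": "A"|"B"|"C"}``."""
        path = Path(path)
        with open(path) as fh:
            data = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        if "scenario" in data:
            return scenario(data["scenario"])
        return cls(
            w_out_cervix=float(data["w_out_cervix"]),
            w_in_cervix=float(data["w_in_cervix"]),
            w_out_uterus=float(data["w_out_uterus"]),
            w_in_uterus=float(data["w_in_uterus"]),
            name=str(data.get("name", "")),
        )


def scenario(name: str) -> WeightSet:
    """Return one of the preset weight scenarios ``A``, ``B`` or ``C``."""
    key = str(name).strip().upper()
    if key not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid scenarios: A, B, C")
    return WeightSet(*_SCENARIOS[key], name=key)


@dataclass(frozen=True)
class OrganCost:
    """Cost components for one organ.

    The unweighted mean squared distances are retained so a different
    WeightSet can be applied without re-classifying vertices.
    """

    outside_term: float  # w_out * mean d²
    inside_term: float  # w_in * mean D²
    mean_sq_outside: float  # Σ d² / i (0 if i == 0)
    mean_sq_inside: float  # Σ D² / t (0 if t == 0)
    n_outside: int
    n_inside: int

    @property
    def cost(self) -> float:
        return self.outside_term + self.inside_term

    def reweighted(self, w_out: float, w_in: float) -> "OrganCost":
        return OrganCost(
            outside_term=w_out * self.mean_sq_outside,
            inside_term=w_in * self.mean_sq_inside,
            mean_sq_outside=self.mean_sq_outside,
            mean_sq_inside=self.mean_sq_inside,
            n_outside=self.n_outside,
            n_inside=self.n_inside,
        )


@dataclass(frozen=True)
class CostBreakdown:
    cervix: OrganCost
    uterus: OrganCost

    @property
    def cost_cervix(self) -> float:
        return self.cervix.cost

    @property
    def cost_uterus(self) -> float:
        return self.uterus.cost

    @property
    def total(self) -> float:
        return self.cervix.cost + self.uterus.cost

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "cervix": {
                "cost": self.cervix.cost,
                "outside_term": self.cervix.outside_term,
                "inside_term": self.cervix.inside_term,
                "n_outside": self.cervix.n_outside,
                "n_inside": self.cervix.n_inside,
            },
            "uterus": {
                "cost": self.uterus.cost,
                "outside_term": self.uterus.outside_term,
                "inside_term": self.uterus.inside_term,
                "n_outside": self.uterus.n_outside,
                "n_inside": self.uterus.n_inside,
            },
        }


def organ_cost(daily: TriMesh, reference: TriMesh, w_out: float, w_in: float) -> OrganCost:
    """Score one daily organ against its own reference surface."""
    if daily.n_vertices == 0:
        raise ValueError("daily mesh has no vertices")
    cls = classify_vertices(daily.vertices, reference)
    i, t = cls.n_outside, cls.n_inside
    msq_out = float(np.square(cls.outside_distances).sum() / i) if i else 0.0
    msq_in = float(np.square(cls.inside_distances).sum() / t) if t else 0.0
    return OrganCost(
        outside_term=w_out * msq_out,
        inside_term=w_in * msq_in,
        mean_sq_outside=msq_out,
        mean_sq_inside=msq_in,
        n_outside=i,
        n_inside=t,
    )


def total_cost(
    daily_cervix: TriMesh,
    daily_uterus: TriMesh,
    ref_cervix: TriMesh,
    ref_uterus: TriMesh,
    weights: WeightSet,
) -> CostBreakdown:
    """Sum of per-organ costs, cervix vs its reference and uterus vs its
    reference."""
    return CostBreakdown(
        cervix=organ_cost(daily_cervix, ref_cervix, weights.w_out_cervix, weights.w_in_cervix),
        uterus=organ_cost(daily_uterus, ref_uterus, weights.w_out_uterus, weights.w_in_uterus),
    )
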