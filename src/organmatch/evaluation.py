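"""Cohort-level summaries and scenario comparisons.

A cohort table holds one row per (fraction, weight scenario) with the
computed couch corrections and PTV coverages.  Conventions:

* translations are signed LPS mm from the translational phase;
* reported rotations come from an unclamped rotational phase (the
  correction the anatomy actually calls for), while coverage under
  ``trans_and_rot`` uses the clamped (±3° default) rotation actually
  deliverable by the couch;
* exceedance is directional: a +12 mm y translation counts toward the
  posterior direction only.

Scenario comparisons use paired t-tests per direction/axis with
Bonferroni correction, significance level 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cost import WeightSet, scenario as weight_scenario
from .matcher import auto_match, rotational_positioning
from .ptv import MarginSpec, build_ptv, coverage, margin_preset

__all__ = [
    "run_fraction",
    "run_cohort",
    "summarize",
    "compare_scenarios",
    "plot_cohort",
    "DIRECTION_SIGNS",
]

#: anatomical direction -> (axis index, sign of the signed LPS translation)
DIRECTION_SIGNS = {"R": (0, -1), "L": (0, +1), "A": (1, -1), "P": (1, +1), "I": (2, -1), "S": (2, +1)}

_ROT_COLS = ("pitch", "yaw", "roll")


def run_fraction(case, weights: WeightSet, margin_specs, clamp_deg: float = 3.0) -> dict:
    """All quantities for one fraction under one weight set.

    Runs the translational phase, an unclamped rotational phase (reported
    rotation) and a clamped rotational phase (used for coverage), then
    scores both positioning modes against each margin spec's PTV.
    """
    t_res = auto_match(
        case.daily_cervix, case.daily_uterus, case.ref_cervix, case.ref_uterus,
        weights, mode="trans_only",
    )
    r_free = rotational_positioning(
        t_res.matched_cervix, t_res.matched_uterus, case.ref_cervix, case.ref_uterus, weights,
    )
    r_clamped = rotational_positioning(
        t_res.matched_cervix, t_res.matched_uterus, case.ref_cervix, case.ref_uterus, weights,
        clamp_deg=clamp_deg,
    )
    row = {
        "scenario": weights.name or "custom",
        "tx": float(t_res.translation[0]),
        "ty": float(t_res.translation[1]),
        "tz": float(t_res.translation[2]),
        "pitch": r_free.pitch,
        "yaw": r_free.yaw,
        "roll": r_free.roll,
        "original_cost": t_res.trace.original_cost,
        "final_cost_trans": t_res.final_cost.total,
        "final_cost_rot": r_clamped.final_cost.total,
    }
    for spec in margin_specs:
        ptv = build_ptv(case.ref_cervix, case.ref_uterus, spec)
        for mode, (mc, mu) in {
            "trans_only": (t_res.matched_cervix, t_res.matched_uterus),
            "trans_and_rot": (r_clamped.matched_cervix, r_clamped.matched_uterus),
        }.items():
            cov = coverage(mc, mu, ptv)
            row[f"cov_{spec.name}_{mode}"] = cov.fraction_combined
            row[f"cov_cervix_{spec.name}_{mode}"] = cov.fraction_cervix
            row[f"cov_uterus_{spec.name}_{mode}"] = cov.fraction_uterus
    return row


def run_cohort(
    cases,
    scenarios=("A", "B", "C"),
    margin_specs=None,
    clamp_deg: float = 3.0,
) -> pd.DataFrame:
    """One row per (fraction, scenario); complete for every combination."""
    if margin_specs is None:
        margin_specs = (margin_preset("ptv_iso_5mm"), margin_preset("ptv_aniso_default"))
    rows = []
    for case_id, case in enumerate(cases):
        for sc in scenarios:
            w = sc if isinstance(sc, WeightSet) else weight_scenario(sc)
            row = run_fraction(case, w, margin_specs, clamp_deg=clamp_deg)
            row["case_id"] = case_id
            row["seed"] = case.spec.seed
            rows.append(row)
    cols = ["case_id", "seed", "scenario"]
    df = pd.DataFrame(rows)
    return df[cols + [c for c in df.columns if c not in cols]]


def _directional(df: pd.DataFrame, direction: str) -> pd.Series:
    axis, sign = DIRECTION_SIGNS[direction]
    v = df[["tx", "ty", "tz"][axis]] * sign
    return v.clip(lower=0.0)  # magnitude in this direction, 0 if the shift is the other way


def summarize(table: pd.DataFrame, exceed_mm: float = 10.0) -> dict:
    """Cohort summary statistics.

    Returns a dict with per-scenario translation stats (median/IQR of the
    signed axes, directional exceedance percentages), rotation stats, and
    coverage threshold percentages (fractions with coverage >= 80% and
    >= 95% per PTV and positioning mode).
    """
    if len(table) == 0:
        raise ValueError("empty cohort table")
    out: dict = {"n_fractions": int(table["case_id"].nunique()), "scenarios": {}}
    cov_cols = [c for c in table.columns if c.startswith("cov_") and not c.startswith(("cov_cervix", "cov_uterus"))]
    for sc, g in table.groupby("scenario", sort=True):
        s: dict = {"n": int(len(g))}
        s["translation_mm"] = {
            ax: {
                "median": float(g[ax].median()),
                "iqr": [float(g[ax].quantile(0.25)), float(g[ax].quantile(0.75))],
            }
            for ax in ("tx", "ty", "tz")
        }
        s["exceedance_pct"] = {
            d: float(100.0 * (_directional(g, d) > exceed_mm).mean()) for d in DIRECTION_SIGNS
        }
        s["rotation_deg"] = {
            ax: {
                "median": float(g[ax].median()),
                "iqr": [float(g[ax].quantile(0.25)), float(g[ax].quantile(0.75))],
            }
            for ax in _ROT_COLS
        }
        s["coverage_pct_of_fractions"] = {
            col.removeprefix("cov_"): {
                "ge_80": float(100.0 * (g[col] >= 0.80).mean()),
                "ge_95": float(100.0 * (g[col] >= 0.95).mean()),
                "median": float(100.0 * g[col].median()),
            }
            for col in cov_cols
        }
        out["scenarios"][sc] = s
    return out


def compare_scenarios(
    table: pd.DataFrame,
    pairs=(("A", "B"), ("A", "C"), ("B", "C")),
    quantities=("R", "L", "A", "P", "S", "I", "pitch", "yaw", "roll"),
    alpha: float = 0.05,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Paired t-tests between weight scenarios.

    Fractions are paired by ``case_id``.  ``family_size`` defaults to the
    number of scenario pairs, applied per quantity (each direction/axis is
    its own comparison family); the Bonferroni-adjusted p is
    ``min(1, p * family_size)``.
    """
    fam = family_size if family_size is not None else len(pairs)
    records = []
    for q in quantities:
        for a, b in pairs:
            ga = table[table["scenario"] == a].set_index("case_id").sort_index()
            gb = table[table["scenario"] == b].set_index("case_id").sort_index()
            if len(ga) == 0 or len(gb) == 0 or not ga.index.equals(gb.index):
                raise ValueError(f"scenarios {a!r}/{b!r} are not paired on the same fractions")
            va = _directional(ga, q) if q in DIRECTION_SIGNS else ga[q]
            vb = _directional(gb, q) if q in DIRECTION_SIGNS else gb[q]
            diff = va.to_numpy() - vb.to_numpy()
            if np.allclose(diff, diff[0]) and np.isclose(diff[0], 0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(va, vb)
                t, p = float(t), float(p)
            p_adj = min(1.0, p * fam)
            records.append(
                {
                    "quantity": q,
                    "pair": f"{a}-{b}",
                    "t": t,
                    "p": p,
                    "p_bonferroni": p_adj,
                    "family_size": fam,
                    "significant": bool(p_adj < alpha),
                }
            )
    return pd.DataFrame(records)


def plot_cohort(table: pd.DataFrame, path) -> None:
    """Box plots of per-direction translations, rotations and coverages by
    scenario (one figure, three panels)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scenarios = sorted(table["scenario"].unique())
    fig, axes = plt.subplots(1, 3, figsize=(15, 4.5))

    width = 0.8 / len(scenarios)
    dirs = list(DIRECTION_SIGNS)
    for k, sc in enumerate(scenarios):
        g = table[table["scenario"] == sc]
        data = [_directional(g, d) for d in dirs]
        pos = np.arange(len(dirs)) + (k - (len(scenarios) - 1) / 2) * width
        axes[0].boxplot(data, positions=pos, widths=width * 0.9)
    axes[0].axhline(10.0, color="red", linestyle="--", linewidth=1)
    axes[0].set_xticks(np.arange(len(dirs)), dirs)
    axes[0].set_ylabel("translation (mm)")
    axes[0].set_title("directional translations")

    for k, sc in enumerate(scenarios):
        g = table[table["scenario"] == sc]
        pos = np.arange(3) + (k - (len(scenarios) - 1) / 2) * width
        axes[1].boxplot([g[c] for c in _ROT_COLS], positions=pos, widths=width * 0.9)
    axes[1].axhline(3.0, color="red", linestyle="--", linewidth=1)
    axes[1].axhline(-3.0, color="red", linestyle="--", linewidth=1)
    axes[1].set_xticks(np.arange(3), _ROT_COLS)
    axes[1].set_ylabel("rotation (deg)")
    axes[1].set_title("rotations (unclamped)")

    cov_cols = [c for c in table.columns if c.startswith("cov_") and not c.startswith(("cov_cervix", "cov_uterus"))]
    for k, sc in enumerate(scenarios):
        g = table[table["scenario"] == sc]
        pos = np.arange(len(cov_cols)) + (k - (len(scenarios) - 1) / 2) * width
        axes[2].boxplot([100 * g[c] for c in cov_cols], positions=pos, widths=width * 0.9)
    axes[2].set_xticks(np.arange(len(cov_cols)), [c.removeprefix("cov_") for c in cov_cols], rotation=30, ha="right", fontsize=7)
    axes[2].set_ylabel("coverage (%)")
    axes[2].set_title("PTV coverage")

    fig.suptitle(f"scenarios: {', '.join(scenarios)}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
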