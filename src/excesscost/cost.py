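"""DRG variable/fixed cost decomposition and excess length-of-stay costing.

Each DRG's average cost is reported by treatment-expense subcategory.
Subcategories that scale with days in hospital are classed *variable*
(ward nursing, ward medical, non-clinical salaries, pathology, imaging,
allied health, pharmacy, supplies, on-costs, hotel, depreciation); one-off
subcategories are *fixed* (critical care, operating rooms, emergency
departments, special procedure suites, prosthesis).

An episode that stayed strictly longer than the all-ages overnight average
for its DRG is "above average"; its extra days (LOS minus the average, as a
real number) are costed at the DRG's daily variable cost.  Episodes at or
below the average have zero extra days and never enter the cost regression.
"""

from __future__ import annotations

import pandas as pd

VARIABLE_SUBCATEGORIES = (
    "ward nursing",
    "ward medical",
    "non-clinical salaries",
    "pathology",
    "imaging",
    "allied health",
    "pharmacy",
    "supplies",
    "on-costs",
    "hotel",
    "depreciation",
)
FIXED_SUBCATEGORIES = (
    "critical care",
    "operating rooms",
    "emergency departments",
    "special procedure suites",
    "prosthesis",
)
ALL_SUBCATEGORIES = VARIABLE_SUBCATEGORIES + FIXED_SUBCATEGORIES


class CostClassificationError(ValueError):
    """A subcategory is not classified as variable or fixed."""


class UnknownDRGError(KeyError):
    """An episode's DRG code is absent from the reference table."""


def split_costs(subcategory_costs) -> tuple[float, float]:
    """Split one DRG's subcategory amounts into (variable_total, fixed_total).

    ``subcategory_costs`` is a mapping (or pandas Series/row) from
    subcategory name to amount.  Every supplied subcategory must be one of
    the sixteen classified names.
    """
    items = dict(subcategory_costs)
    unknown = [k for k in items if k not in ALL_SUBCATEGORIES]
    if unknown:
        raise CostClassificationError(f"unclassified subcategories: {unknown}")
    variable_total = float(sum(items.get(k, 0.0) for k in VARIABLE_SUBCATEGORIES))
    fixed_total = float(sum(items.get(k, 0.0) for k in FIXED_SUBCATEGORIES))
    return variable_total, fixed_total


def add_cost_totals(ref: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`split_costs` over a DRG reference table.

    Returns a copy with ``variable_total``, ``fixed_total`` and
    ``daily_variable_cost`` columns.
    """
    missing = [c for c in ALL_SUBCATEGORIES if c not in ref.columns]
    if missing:
        raise CostClassificationError(f"reference table missing subcategory columns: {missing}")
    out = ref.copy()
    out["variable_total"] = out[list(VARIABLE_SUBCATEGORIES)].sum(axis=1)
    out["fixed_total"] = out[list(FIXED_SUBCATEGORIES)].sum(axis=1)
    if (out["avg_overnight_los"] <= 0).any():
        bad = out.loc[out["avg_overnight_los"] <= 0, "drg"].tolist()
        raise ValueError(f"non-positive average overnight LOS for DRGs: {bad}")
    out["daily_variable_cost"] = out["variable_total"] / out["avg_overnight_los"]
    return out


def daily_variable_cost(ref) -> float:
    """Variable total divided by the DRG's average overnight LOS.

    ``ref`` is one reference row (mapping/Series) with the sixteen
    subcategory amounts and ``avg_overnight_los``.
    """
    avg_los = float(ref["avg_overnight_los"])
    if avg_los <= 0:
        raise ValueError(f"average overnight LOS must be positive, got {avg_los}")
    variable_total, _ = split_costs({k: ref[k] for k in ALL_SUBCATEGORIES if k in ref})
    return variable_total / avg_los


def excess_cost(episodes: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    """Per-episode excess-LOS cost records.

    ``extra_days = max(0, los_days - avg_overnight_los)`` as a real number
    (state averages are generally fractional); ``above_average`` is strict
    (equal-to-average is not "longer than average");
    ``extra_cost = extra_days * daily_variable_cost``.
    """
    ref_tot = ref if "daily_variable_cost" in ref.columns else add_cost_totals(ref)
    cols = ["drg", "avg_overnight_los", "daily_variable_cost"]
    if "cost_weight" in ref_tot.columns:
        cols.append("cost_weight")
    merged = episodes.merge(ref_tot[cols], on="drg", how="left", validate="many_to_one")
    if merged["avg_overnight_los"].isna().any():
        missing = sorted(merged.loc[merged["avg_overnight_los"].isna(), "drg"].unique())
        raise UnknownDRGError(f"DRG codes absent from reference table: {missing}")
    out = merged[["episode_id", "drg"] + (["cost_weight"] if "cost_weight" in cols else [])].copy()
    out["extra_days"] = (merged["los_days"] - merged["avg_overnight_los"]).clip(lower=0.0)
    out["above_average"] = out["extra_days"] > 0
    out["daily_variable_cost"] = merged["daily_variable_cost"]
    out["extra_cost"] = out["extra_days"] * out["daily_variable_cost"]
    return out


def select_above_average(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only strictly-above-average episodes (the regression sample)."""
    return records.loc[records["above_average"]].reset_index(drop=True)
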