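"""Outcome and exposure phenotypes.

Twelve-month weight-loss success categories, dietary adherence (the share of
reported energy intake *not* coming from the diet's restricted macronutrient)
and dietary change (how much restricted-component intake dropped from
baseline).  The restricted component is fixed by the arm: carbohydrates on the
low-carb diet, fat on the low-fat diet.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io_formats import recall_column

__all__ = [
    "SUCCESS_CATEGORIES",
    "classify_success",
    "dietary_adherence",
    "dietary_change",
    "restricted_component",
    "phenotype_table",
]

SUCCESS_CATEGORIES = ("US", "MS", "VS")

ON_DIET_TIMEPOINTS = ("3mo", "6mo", "12mo")


def classify_success(weight_loss_pct) -> str | float:
    """Map 12-month % weight loss to US (<3%), MS (3-10%) or VS (>10%).

    Boundaries 3% and 10% fall in MS (the category is the closed interval);
    negative values (weight gain) are US.  Missing input stays missing.
    """
    if weight_loss_pct is None or (
        isinstance(weight_loss_pct, float) and math.isnan(weight_loss_pct)
    ):
        return float("nan")
    w = float(weight_loss_pct)
    if w < 3.0:
        return "US"
    if w <= 10.0:
        return "MS"
    return "VS"


def _mean_available(values) -> float:
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return float("nan")
    return float(arr.mean())


def dietary_adherence(on_diet_restricted_pct) -> float:
    """100 minus the mean on-diet restricted-component %kcal.

    *on_diet_restricted_pct* holds the restricted macronutrient's share of
    total kcal at the 3-, 6- and 12-month recalls; missing recalls are
    dropped from the mean.  A subject holding restricted intake at 10%
    throughout scores an adherence of 90%.
    """
    mean = _mean_available(on_diet_restricted_pct)
    return float("nan") if math.isnan(mean) else 100.0 - mean


def dietary_change(baseline_restricted_pct, on_diet_restricted_pct) -> float:
    """Baseline minus mean on-diet restricted %kcal (percentage points).

    Positive values mean the subject cut back on the restricted component;
    the value may be negative if intake increased.  Missing baseline yields
    missing.
    """
    if baseline_restricted_pct is None or (
        isinstance(baseline_restricted_pct, float) and math.isnan(baseline_restricted_pct)
    ):
        return float("nan")
    mean = _mean_available(on_diet_restricted_pct)
    if math.isnan(mean):
        return float("nan")
    return float(baseline_restricted_pct) - mean


def restricted_component(diet: str) -> str:
    """The macronutrient restricted on a given arm: carbs or fat."""
    if diet == "low-carb":
        return "carb"
    if diet == "low-fat":
        return "fat"
    raise ValueError(f"unknown diet {diet!r}")


def phenotype_table(subjects: pd.DataFrame) -> pd.DataFrame:
    """Per-subject phenotypes derived from the subject metadata table.

    Columns: ``success`` (US/MS/VS), ``adherence_pct``, ``change_pct`` and
    ``restricted_component``.
    """
    rows = {}
    for subject_id, rec in subjects.iterrows():
        comp = restricted_component(rec["diet"])
        on_diet = [rec.get(recall_column(comp, tp), float("nan")) for tp in ON_DIET_TIMEPOINTS]
        baseline = rec.get(recall_column(comp, "baseline"), float("nan"))
        rows[subject_id] = {
            "success": classify_success(rec.get("weight_loss_pct_12mo", float("nan"))),
            "adherence_pct": dietary_adherence(on_diet),
            "change_pct": dietary_change(baseline, on_diet),
            "restricted_component": comp,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject_id"
    return out
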