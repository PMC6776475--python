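"""Per-child nutrient and sugar intakes from weighed dietary records.

A weighed dietary record lists, per child and survey day, every food consumed
and the grams actually eaten (net of leftovers).  Intakes follow the standard
composition-table arithmetic — grams/100 × content per 100 g — summed within a
day and averaged over the (three) recorded days.  Free-sugar intake is also
broken down by the ten food groups, the percentage of energy supplied by each
energy-providing nutrient is computed from configurable Atwater-style factors,
and children whose free sugar supplies at least 10 % of energy are flagged as
excessive consumers (the WHO threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .composition import FOOD_GROUPS, FoodItem, SugarAssignment
from .stats import two_sample_t

#: nutrients carried through the pipeline, g/d (energy kcal/d)
NUTRIENTS = (
    "energy", "protein", "fat", "saturated_fat", "carbohydrate",
    "total_sugar", "added_sugar", "free_sugar",
)

#: energy-providing nutrients and their default kcal/g factors
DEFAULT_ENERGY_FACTORS: Mapping[str, float] = {
    "protein": 4.0,
    "fat": 9.0,
    "saturated_fat": 9.0,
    "carbohydrate": 4.0,
    "total_sugar": 4.0,
    "added_sugar": 4.0,
    "free_sugar": 4.0,
}

EXCESSIVE_THRESHOLD_PCT = 10.0


class UnresolvedFoodCodeError(KeyError):
    """A dietary record refers to food codes absent from the composition database."""


@dataclass
class IntakeConfig:
    """Tunables of the intake pipeline.

    ``day_weights``: optional per-day weights for the mean over recorded days
    (default: unweighted mean).  ``energy_factors``: kcal per gram by nutrient.
    """

    day_weights: Optional[Mapping[int, float]] = None
    energy_factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENERGY_FACTORS)
    )
    excessive_threshold_pct: float = EXCESSIVE_THRESHOLD_PCT


def nutrient_frame(
    items: Mapping[str, FoodItem] | Sequence[FoodItem],
    assignments: Mapping[str, SugarAssignment],
) -> pd.DataFrame:
    """Per-100 g nutrient contents indexed by food code, sugar columns from the
    assignment database, plus the food group for the breakdown."""
    if not isinstance(items, Mapping):
        items = {it.food_code: it for it in items}
    rows = []
    for code, item in items.items():
        a = assignments[code]
        rows.append(
            {
                "food_code": code,
                "group": item.group,
                "energy": item.energy,
                "protein": item.protein,
                "fat": item.fat,
                "saturated_fat": item.saturated_fat,
                "carbohydrate": item.carbohydrate,
                "total_sugar": a.total_sugar,
                "added_sugar": a.added_sugar,
                "free_sugar": a.free_sugar,
            }
        )
    return pd.DataFrame(rows).set_index("food_code")


def _group_cols() -> list[str]:
    return [f"free_sugar_{g}" for g in FOOD_GROUPS]


def daily_intake(entries: pd.DataFrame, nutrients: pd.DataFrame) -> pd.Series:
    """Nutrient totals for one child-day: sum of amount/100 x per-100 g content.

    ``entries`` needs columns ``food_code`` and ``amount``; an empty frame
    yields all-zero intakes.
    """
    index = list(NUTRIENTS) + _group_cols()
    if len(entries) == 0:
        return pd.Series(0.0, index=index)
    missing = set(entries["food_code"]) - set(nutrients.index)
    if missing:
        raise UnresolvedFoodCodeError(
            f"food codes not in database: {sorted(missing)}"
        )
    merged = entries.merge(nutrients, left_on="food_code", right_index=True)
    scale = merged["amount"].to_numpy() / 100.0
    out = pd.Series(0.0, index=index)
    for n in NUTRIENTS:
        out[n] = float(np.dot(scale, merged[n].to_numpy()))
    fs = scale * merged["free_sugar"].to_numpy()
    for g, value in zip(merged["group"], fs):
        out[f"free_sugar_{g}"] += float(value)
    return out


def mean_daily_intake(
    day_totals: pd.DataFrame, config: Optional[IntakeConfig] = None
) -> pd.Series:
    """Mean over recorded days (rows); unweighted unless day weights are set."""
    config = config or IntakeConfig()
    if len(day_totals) == 0:
        raise ValueError("no recorded days")
    if config.day_weights is None:
        return day_totals.mean(axis=0)
    w = np.array([config.day_weights[d] for d in day_totals.index], dtype=float)
    w = w / w.sum()
    return pd.Series(day_totals.to_numpy().T @ w, index=day_totals.columns)


def percent_energy(grams_per_day: float, energy_kcal: float, kcal_per_gram: float) -> float:
    """% of daily energy supplied by ``grams_per_day`` of a nutrient."""
    if energy_kcal <= 0:
        raise ValueError(f"non-positive energy intake {energy_kcal}")
    return grams_per_day * kcal_per_gram / energy_kcal * 100.0


def classify_excessive(free_sugar_pct_energy: float, threshold: float = EXCESSIVE_THRESHOLD_PCT) -> bool:
    """True iff free sugar supplies at least ``threshold`` % of energy (WHO: 10 %)."""
    return free_sugar_pct_energy >= threshold


def intake_summaries(
    records: pd.DataFrame,
    nutrients: pd.DataFrame,
    config: Optional[IntakeConfig] = None,
) -> pd.DataFrame:
    """One row per child: mean daily intakes, % energy, group breakdown, excessive flag.

    ``records`` columns: child_id, day_index, food_code, amount (day_type is
    carried in the input but does not enter the unweighted mean).
    """
    config = config or IntakeConfig()
    rows = []
    for child_id, child_records in records.groupby("child_id", sort=True):
        day_totals = pd.DataFrame(
            {
                day: daily_intake(day_entries, nutrients)
                for day, day_entries in child_records.groupby("day_index")
            }
        ).T
        mean = mean_daily_intake(day_totals, config)
        row: dict = {"child_id": child_id}
        row.update({n: mean[n] for n in NUTRIENTS})
        row.update({c: mean[c] for c in _group_cols()})
        for n, factor in config.energy_factors.items():
            row[f"pct_energy_{n}"] = percent_energy(mean[n], mean["energy"], factor)
        row["excessive"] = classify_excessive(
            row["pct_energy_free_sugar"], config.excessive_threshold_pct
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("child_id")


def prevalence_excessive(summaries: pd.DataFrame) -> float:
    """Prevalence of excessive free-sugar intake, %, to 1 decimal."""
    if len(summaries) == 0:
        raise ValueError("empty cohort")
    return round(100.0 * summaries["excessive"].sum() / len(summaries), 1)


def cohort_intake_table(summaries: pd.DataFrame, equal_variance: bool = True) -> pd.DataFrame:
    """Cohort intake summary: mean and SD overall and by excessive status, with
    two-sample t-test p-values for the group difference.

    Rows: free sugar total and by food group (g/d), energy (kcal/d), and % of
    energy for each energy-providing nutrient.  Degenerate strata (n < 2 or
    zero variance in both groups with equal means) get a missing p-value.
    """
    quantities = (
        [("free_sugar", "Total free sugar, g/d")]
        + [(f"free_sugar_{g}", f"Free sugar: {g}, g/d") for g in FOOD_GROUPS]
        + [("energy", "Energy, kcal/d")]
        + [
            (f"pct_energy_{n}", f"{n.replace('_', ' ').capitalize()}, % of energy")
            for n in ("protein", "fat", "saturated_fat", "carbohydrate",
                      "total_sugar", "added_sugar", "free_sugar")
        ]
    )
    exc = summaries[summaries["excessive"]]
    non = summaries[~summaries["excessive"]]
    rows = []
    for col, label in quantities:
        row = {
            "quantity": label,
            "mean": summaries[col].mean(),
            "sd": summaries[col].std(ddof=1),
            "mean_excessive": exc[col].mean() if len(exc) else np.nan,
            "sd_excessive": exc[col].std(ddof=1) if len(exc) > 1 else np.nan,
            "mean_non_excessive": non[col].mean() if len(non) else np.nan,
            "sd_non_excessive": non[col].std(ddof=1) if len(non) > 1 else np.nan,
        }
        if len(exc) >= 2 and len(non) >= 2:
            t, p = two_sample_t(
                exc[col].to_numpy(), non[col].to_numpy(), equal_variance=equal_variance
            )
            row["p_value"] = p
        else:
            row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("quantity")


def group_contribution_pct(summaries: pd.DataFrame) -> pd.Series:
    """Mean per-child percentage contribution of each food group to free sugar.

    The mean of per-child percentages, not the ratio of cohort means: children
    with little free sugar weigh as much as heavy consumers, which is the
    convention matching published group-contribution figures.
    """
    contrib = {}
    total = summaries["free_sugar"]
    for g in FOOD_GROUPS:
        share = summaries[f"free_sugar_{g}"].where(total > 0, 0.0) / total.where(total > 0, 1.0)
        contrib[g] = 100.0 * share.mean()
    return pd.Series(contrib).sort_values(ascending=False)
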