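"""CSV schemas for the three inputs and the assignment output.

All files are plain UTF-8 CSV.  Missing values are empty cells — never 0,
because absence of a saccharide measurement and a measured 0 g content mean
different things to the assignment cascades.  Booleans are written 1/0.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import pandas as pd

from .composition import (
    SACCHARIDES,
    FoodItem,
    ForeignTableRef,
    SaccharideProfile,
    SugarAssignment,
)

_BOOL_COLS = (
    "carbohydrate_is_all_sugar",
    "no_added_sugar",
    "all_sugar_added",
    "is_fruit_juice_or_honey_or_syrup",
    "assume_half_added",
)
_OPT_FLOAT_COLS = (
    "literature_total_sugar",
    "natural_sugar",
    "added_sugar_label",
    "free_sugar_label",
)
_REF_COLS = ("raw_form_ref", "similar_ref", "unsweetened_ref")

FOOD_TABLE_COLUMNS = (
    ("food_code", "name", "group", "energy", "protein", "fat", "saturated_fat",
     "carbohydrate", "dietary_fiber", "water")
    + SACCHARIDES
    + _BOOL_COLS
    + _OPT_FLOAT_COLS
    + _REF_COLS
    + ("foreign_country",)
    + tuple(f"foreign_{s}" for s in SACCHARIDES)
    + ("foreign_disaccharide_mono_equiv", "foreign_added_sugar", "foreign_free_sugar",
       "recipe")
)


def _opt(value) -> Optional[float]:
    if value is None or value == "" or pd.isna(value):
        return None
    return float(value)


def _parse_recipe(text) -> Optional[list[tuple[str, float]]]:
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return None
    parts = []
    for chunk in str(text).split(";"):
        code, prop = chunk.split(":")
        parts.append((code.strip(), float(prop)))
    return parts


def _format_recipe(recipe: Optional[list[tuple[str, float]]]) -> str:
    if not recipe:
        return ""
    return ";".join(f"{code}:{prop:g}" for code, prop in recipe)


def food_item_to_row(item: FoodItem) -> dict:
    row: dict = {
        "food_code": item.food_code,
        "name": item.name,
        "group": item.group,
        "energy": item.energy,
        "protein": item.protein,
        "fat": item.fat,
        "saturated_fat": item.saturated_fat,
        "carbohydrate": item.carbohydrate,
        "dietary_fiber": item.dietary_fiber,
        "water": item.water,
        "recipe": _format_recipe(item.recipe),
    }
    for s in SACCHARIDES:
        row[s] = getattr(item.saccharides, s)
    for c in _BOOL_COLS:
        row[c] = int(getattr(item, c))
    for c in _OPT_FLOAT_COLS:
        row[c] = getattr(item, c)
    for c in _REF_COLS:
        row[c] = getattr(item, c) or ""
    if item.foreign is not None:
        row["foreign_country"] = item.foreign.source_country
        for s in SACCHARIDES:
            row[f"foreign_{s}"] = getattr(item.foreign.saccharides, s)
        row["foreign_disaccharide_mono_equiv"] = int(
            item.foreign.disaccharide_as_monosaccharide_equivalent
        )
        row["foreign_added_sugar"] = item.foreign.added_sugar
        row["foreign_free_sugar"] = item.foreign.free_sugar
    else:
        row["foreign_country"] = ""
        for s in SACCHARIDES:
            row[f"foreign_{s}"] = None
        row["foreign_disaccharide_mono_equiv"] = ""
        row["foreign_added_sugar"] = None
        row["foreign_free_sugar"] = None
    return row


def row_to_food_item(row: Mapping) -> FoodItem:
    prof = SaccharideProfile(**{s: _opt(row.get(s)) for s in SACCHARIDES})
    foreign = None
    country = row.get("foreign_country")
    if country is not None and not pd.isna(country) and str(country) != "":
        foreign = ForeignTableRef(
            source_country=str(country),
            saccharides=SaccharideProfile(
                **{s: _opt(row.get(f"foreign_{s}")) for s in SACCHARIDES}
            ),
            disaccharide_as_monosaccharide_equivalent=bool(
                int(float(row.get("foreign_disaccharide_mono_equiv") or 0))
            ),
            added_sugar=_opt(row.get("foreign_added_sugar")),
            free_sugar=_opt(row.get("foreign_free_sugar")),
        )

    def ref(col: str) -> Optional[str]:
        v = row.get(col)
        if v is None or (isinstance(v, float) and pd.isna(v)) or str(v) == "":
            return None
        return str(v)

    return FoodItem(
        food_code=str(row["food_code"]),
        name=str(row["name"]),
        group=str(row["group"]),
        energy=float(row["energy"]),
        protein=float(row.get("protein") or 0.0),
        fat=float(row.get("fat") or 0.0),
        saturated_fat=float(row.get("saturated_fat") or 0.0),
        carbohydrate=float(row["carbohydrate"]),
        dietary_fiber=float(row.get("dietary_fiber") or 0.0),
        water=float(row.get("water") or 0.0),
        saccharides=prof,
        **{c: bool(int(float(row.get(c) or 0))) for c in _BOOL_COLS},
        **{c: _opt(row.get(c)) for c in _OPT_FLOAT_COLS},
        raw_form_ref=ref("raw_form_ref"),
        similar_ref=ref("similar_ref"),
        unsweetened_ref=ref("unsweetened_ref"),
        foreign=foreign,
        recipe=_parse_recipe(row.get("recipe")),
    )


def write_food_table(items: Iterable[FoodItem], path) -> None:
    df = pd.DataFrame([food_item_to_row(it) for it in items], columns=list(FOOD_TABLE_COLUMNS))
    df.to_csv(path, index=False)


def read_food_table(path) -> list[FoodItem]:
    df = pd.read_csv(path, dtype={"food_code": str})
    return [row_to_food_item(row) for _, row in df.iterrows()]


def assignments_to_frame(assignments: Mapping[str, SugarAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "food_code": a.food_code,
                "total_sugar": a.total_sugar,
                "added_sugar": a.added_sugar,
                "free_sugar": a.free_sugar,
                "total_step": a.total_step,
                "free_step": a.free_step,
            }
            for a in assignments.values()
        ]
    )


def write_assignments(assignments: Mapping[str, SugarAssignment], path) -> None:
    assignments_to_frame(assignments).to_csv(path, index=False)


def read_assignments(path) -> dict[str, SugarAssignment]:
    df = pd.read_csv(path, dtype={"food_code": str})
    return {
        r.food_code: SugarAssignment(
            food_code=r.food_code,
            total_sugar=float(r.total_sugar),
            total_step=int(r.total_step),
            added_sugar=float(r.added_sugar),
            free_sugar=float(r.free_sugar),
            free_step=int(r.free_step),
        )
        for r in df.itertuples()
    }


def read_records(path) -> pd.DataFrame:
    """Dietary records: child_id, day_index, day_type, food_code, amount (g)."""
    return pd.read_csv(path, dtype={"food_code": str, "child_id": str})


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"child_id": str})
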