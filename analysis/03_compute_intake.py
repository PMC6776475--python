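#!/usr/bin/env python
"""Estimate intakes and summarise the cohort's diet.

Converts the dietary records plus the sugar database into per-child mean daily
intakes, writes the cohort intake table (means/SDs overall and by excessive
status with group-difference t-tests) and the food-group contributions to
free-sugar intake.
"""

from pathlib import Path

import pandas as pd

from sugarintake.dataio import read_assignments, read_food_table, read_records
from sugarintake.intake import (
    cohort_intake_table,
    group_contribution_pct,
    intake_summaries,
    nutrient_frame,
    prevalence_excessive,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    items = read_food_table(OUT / "food_table.csv")
    assignments = read_assignments(OUT / "sugar_db.csv")
    nutrients = nutrient_frame(items, assignments)
    summaries = intake_summaries(read_records(OUT / "records.csv"), nutrients)
    summaries.to_csv(OUT / "intake.csv")

    table = cohort_intake_table(summaries)
    table.to_csv(OUT / "intake_table.csv")
    contrib = group_contribution_pct(summaries)
    contrib.to_csv(OUT / "group_contributions_pct.csv", header=["mean_pct"])

    fs = summaries["free_sugar"]
    pct = summaries["pct_energy_free_sugar"]
    print(f"n = {len(summaries)} children")
    print(f"free sugar: {fs.mean():.1f} (SD {fs.std():.1f}) g/d; "
          f"{pct.mean():.1f} (SD {pct.std():.1f}) % of energy")
    print(f"energy: {summaries['energy'].mean():.0f} "
          f"(SD {summaries['energy'].std():.0f}) kcal/d")
    print(f"prevalence of excessive intake (≥10 %E): {prevalence_excessive(summaries)}%")
    print("\ntop food-group contributions to free sugar (mean per-child %):")
    print(contrib.head(5).round(1).to_string())


if __name__ == "__main__":
    main()
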