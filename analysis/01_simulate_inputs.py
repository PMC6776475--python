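#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes the three inputs every later stage consumes — a food composition table,
a cohort covariate table and 3-day weighed dietary records — plus the hidden
ground truth used only for verification, to results/.
"""

from pathlib import Path

from sugarintake.dataio import write_food_table
from sugarintake.simulate import simulate_study

SEED = 20240901 % 2**31
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    study = simulate_study(seed=SEED)
    write_food_table(study.food_items, OUT / "food_table.csv")
    study.cohort_raw.to_csv(OUT / "cohort.csv")
    study.records.to_csv(OUT / "records.csv", index=False)
    study.food_truth.to_csv(OUT / "ground_truth_foods.csv")
    study.cohort_truth.to_csv(OUT / "ground_truth_cohort.csv")
    n = study.cohort_raw.shape[0]
    boys = (study.cohort_raw["sex"] == "Boys").sum()
    print(f"seed {SEED}: {len(study.food_items)} foods, "
          f"{n} children ({boys} boys), {len(study.records)} record rows")
    print(f"wrote inputs and ground truth to {OUT}")


if __name__ == "__main__":
    main()
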