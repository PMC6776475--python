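#!/usr/bin/env python
"""Associations between characteristics/lifestyles and excessive intake.

Derives the categorical covariates from the raw cohort table, then computes
crude odds ratios (2x2 cross-products with Wald 95 % CIs) and multivariable-
adjusted odds ratios (all covariates entered simultaneously into one logistic
model).  Categories with an empty outcome cell are reported "—".
"""

from pathlib import Path

import pandas as pd

from sugarintake.covariates import COVARIATE_SCHEME, derive_covariates
from sugarintake.stats import association_frame, association_table, render_association_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    raw = pd.read_csv(OUT / "cohort.csv", dtype={"child_id": str}).set_index("child_id")
    summaries = pd.read_csv(OUT / "intake.csv", dtype={"child_id": str}).set_index("child_id")
    covariates = derive_covariates(raw.loc[summaries.index])

    rows, fit = association_table(
        covariates, summaries["excessive"].astype(bool), COVARIATE_SCHEME
    )
    association_frame(rows).to_csv(OUT / "associations.csv", index=False)
    print(render_association_table(rows))
    print(f"\njoint logistic fit on {fit.n_obs} children; converged: {fit.converged}")
    n_undef = sum(r.adjusted.undefined for r in rows if not r.is_reference)
    print(f"categories undefined by separation: {n_undef}")


if __name__ == "__main__":
    main()
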