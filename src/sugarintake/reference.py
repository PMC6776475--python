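"""Published cohort category counts and reported estimates, used as inputs.

The source study prints, for every covariate category, the number of children
and the number with excessive free-sugar intake.  Those printed counts fully
determine the crude 2x2 odds ratios, so they serve both as a desk check of the
estimators and as the default covariate marginals of the simulator.  Reported
headline figures (mean free-sugar intake, prevalence of excessive intake) are
kept alongside for calibration checks.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

#: variable -> (reference category, [(category, n_total, n_excessive,
#: printed crude OR or None for the reference / separated rows,
#: printed CI low, CI high)])
CRUDE_TABLE: Mapping[str, tuple[str, Sequence[tuple]]] = {
    "sex": ("Boys", [
        ("Boys", 166, 37, None, None, None),
        ("Girls", 166, 35, 0.93, 0.55, 1.57),
    ]),
    "age": ("3", [
        ("3", 87, 23, None, None, None),
        ("4", 86, 17, 0.69, 0.34, 1.40),
        ("5", 85, 18, 0.75, 0.37, 1.51),
        ("6", 74, 14, 0.65, 0.31, 1.38),
    ]),
    "weight_status": ("Normal", [
        ("Underweight", 35, 8, 1.06, 0.46, 2.44),
        ("Normal", 269, 59, None, None, None),
        ("Overweight and obese", 28, 5, 0.78, 0.28, 2.12),
    ]),
    "sleep": ("<10", [
        ("<10", 52, 15, None, None, None),
        ("≥10", 280, 57, 0.63, 0.32, 1.23),
    ]),
    "outdoor": ("<1", [
        ("<1", 85, 21, None, None, None),
        ("≥1 to <2", 158, 36, 0.90, 0.49, 1.67),
        ("≥2", 89, 15, 0.62, 0.29, 1.30),
    ]),
    "screen": ("<0.5", [
        ("<0.5", 44, 3, None, None, None),
        ("≥0.5 to <1", 173, 39, 3.98, 1.17, 13.54),
        ("≥1", 115, 30, 4.82, 1.39, 16.73),
    ]),
    "maternal_age": ("20 to 29", [
        ("20 to 29", 20, 4, None, None, None),
        ("30 to 39", 224, 42, 0.92, 0.29, 2.90),
        ("≥40", 88, 26, 1.68, 0.51, 5.50),
    ]),
    "maternal_weight_status": ("Normal", [
        ("Underweight", 47, 9, 0.82, 0.37, 1.79),
        ("Normal", 258, 58, None, None, None),
        ("Overweight and obese", 27, 5, 0.78, 0.28, 2.16),
    ]),
    "maternal_education": ("≤12", [
        ("≤12", 63, 15, None, None, None),
        ("13 to 14", 153, 37, 1.02, 0.51, 2.03),
        ("≥15", 116, 20, 0.67, 0.31, 1.42),
    ]),
    "maternal_occupation": ("Professional and manager", [
        ("Professional and manager", 162, 28, None, None, None),
        ("Office work, service, and sales", 129, 34, 1.71, 0.97, 3.01),
        ("Manual", 28, 6, 1.31, 0.49, 3.51),
        ("Unemployed", 13, 4, 2.13, 0.61, 7.40),
    ]),
    "maternal_smoking": ("No", [
        ("No", 308, 65, None, None, None),
        ("Yes", 24, 7, 1.54, 0.61, 3.87),
    ]),
    "paternal_age": ("20 to 29", [
        ("20 to 29", 12, 3, None, None, None),
        ("30 to 39", 198, 38, 0.71, 0.18, 2.76),
        ("≥40", 122, 31, 1.02, 0.26, 4.02),
    ]),
    "paternal_weight_status": ("Normal", [
        ("Underweight", 12, 3, 1.23, 0.32, 4.73),
        ("Normal", 235, 50, None, None, None),
        ("Overweight and obese", 85, 19, 1.07, 0.59, 1.94),
    ]),
    "paternal_education": ("≤12", [
        ("≤12", 113, 23, None, None, None),
        ("13 to 14", 76, 20, 1.40, 0.70, 2.78),
        ("≥15", 143, 29, 1.00, 0.54, 1.84),
    ]),
    "paternal_occupation": ("Professional and manager", [
        ("Professional and manager", 148, 34, None, None, None),
        ("Office work, service, and sales", 90, 17, 0.78, 0.41, 1.50),
        ("Manual", 92, 21, 0.99, 0.53, 1.84),
        ("Unemployed", 2, 0, None, None, None),  # separation: reported "—"
    ]),
    "paternal_smoking": ("No", [
        ("No", 186, 43, None, None, None),
        ("Yes", 146, 29, 0.82, 0.49, 1.40),
    ]),
    "grandparents": ("No", [
        ("No", 272, 56, None, None, None),
        ("Yes", 60, 16, 1.40, 0.74, 2.67),
    ]),
    "siblings": ("0", [
        ("0", 54, 14, None, None, None),
        ("1", 182, 39, 0.78, 0.39, 1.58),
        ("≥2", 96, 19, 0.71, 0.32, 1.55),
    ]),
    "income": ("Low", [
        ("Low", 91, 25, None, None, None),
        ("Middle", 144, 28, 0.64, 0.34, 1.18),
        ("High", 97, 19, 0.64, 0.33, 1.27),
    ]),
}

#: headline cohort figures
N_CHILDREN = 332
N_EXCESSIVE = 72
MEAN_FREE_SUGAR_G = 26.8
SD_FREE_SUGAR_G = 12.3
MEAN_FREE_SUGAR_PCT = 7.8
SD_FREE_SUGAR_PCT = 3.2
PREVALENCE_EXCESSIVE_PCT = 21.7


def crude_cells(variable: str):
    """(reference cell, comparison cells with printed values) for one variable."""
    from .stats import ContingencyCell

    ref_cat, rows = CRUDE_TABLE[variable]
    ref = next(
        ContingencyCell(cat, nt, ne) for cat, nt, ne, *_ in rows if cat == ref_cat
    )
    comparisons = [
        (ContingencyCell(cat, nt, ne), por, plo, phi)
        for cat, nt, ne, por, plo, phi in rows
        if cat != ref_cat
    ]
    return ref, comparisons
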