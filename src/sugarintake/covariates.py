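"""Categorical covariates of the cohort, derived from raw questionnaire fields.

Every cutpoint follows the convention that a printed ">= x" boundary is
inclusive upward: the categorizers use left-closed intervals, so a value equal
to a cutpoint lands in the higher category.

Weekday/weekend durations (outdoor play, screen time) are combined into a
weekly-weighted daily mean with weights 5/7 and 2/7.  Child weight status uses
age- and sex-specific BMI cutoffs mapped to the adult thresholds of 18.5 and
25 kg/m2 (an IOTF-style table supplied as a replaceable fixture; the copy that
ships with the package holds synthetic stand-in values).  Household income is
equivalized by an equivalence scale (default: square root of household size)
before bucketing into the study's tertile cutpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping, Optional, Sequence

import pandas as pd

# ---------------------------------------------------------------- categorizer


def categorize(value: float, cutpoints: Sequence[float], labels: Sequence[str]) -> str:
    """Bucket ``value`` into left-closed intervals: value >= cutpoint goes up.

    ``len(labels)`` must be ``len(cutpoints) + 1``; cutpoints strictly increasing.
    """
    if len(labels) != len(cutpoints) + 1:
        raise ValueError("need one more label than cutpoints")
    if list(cutpoints) != sorted(set(cutpoints)):
        raise ValueError("cutpoints must be strictly increasing")
    if value != value:  # NaN
        raise ValueError("cannot categorize NaN")
    idx = sum(value >= c for c in cutpoints)
    return labels[idx]


def weekly_weighted_hours(weekday_h: float, weekend_h: float) -> float:
    """Daily mean over a week: weekday hours x 5/7 + weekend hours x 2/7."""
    if weekday_h < 0 or weekend_h < 0:
        raise ValueError("durations must be non-negative")
    return weekday_h * 5.0 / 7.0 + weekend_h * 2.0 / 7.0


def total_sleep(nap_h: float, night_h: float) -> float:
    """Daily sleep: daytime nap plus night-time sleep, h/d."""
    if nap_h < 0 or night_h < 0:
        raise ValueError("sleep durations must be non-negative")
    return nap_h + night_h


def bmi(weight_kg: float, height_cm: float) -> float:
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


ADULT_BMI_CUTS = (18.5, 25.0)
WEIGHT_STATUS_LABELS = ("Underweight", "Normal", "Overweight and obese")


def adult_weight_status(bmi_value: float) -> str:
    """Adult BMI categories: <18.5 underweight, 18.5-<25 normal, >=25 overweight/obese."""
    if bmi_value <= 0:
        raise ValueError("BMI must be positive")
    return categorize(bmi_value, ADULT_BMI_CUTS, WEIGHT_STATUS_LABELS)


def load_child_bmi_cutoffs(path=None) -> pd.DataFrame:
    """Age- and sex-specific child BMI cutoff table, indexed by (age_years, sex).

    Columns ``lower``/``upper`` correspond to adult BMI 18.5 and 25.  Without a
    ``path`` the packaged synthetic stand-in table is loaded.
    """
    if path is None:
        path = resources.files("sugarintake.data") / "iotf_cutoffs_synthetic.csv"
    df = pd.read_csv(path)
    return df.set_index(["age_years", "sex"])


def child_weight_status(
    bmi_value: float, age_years: int, sex: str, cutoffs: pd.DataFrame
) -> str:
    """Child weight status via age/sex BMI thresholds mapped to adult 18.5/25."""
    try:
        row = cutoffs.loc[(age_years, sex)]
    except KeyError:
        raise KeyError(f"no BMI cutoffs for age {age_years}, sex {sex!r}") from None
    return categorize(
        bmi_value, (float(row["lower"]), float(row["upper"])), WEIGHT_STATUS_LABELS
    )


INCOME_CUTS = (2_380_000.0, 3_340_000.0)
INCOME_LABELS = ("Low", "Middle", "High")


def equivalized_income_tertile(
    income_yen: float,
    household_size: int,
    scale: Optional[Callable[[int], float]] = None,
) -> str:
    """Equivalized income bucket: income / scale(household size), tertile cutpoints
    at 2,380,000 and 3,340,000 yen/year (boundaries inclusive upward)."""
    if household_size < 1:
        raise ValueError("household size must be >= 1")
    if income_yen < 0:
        raise ValueError("income must be non-negative")
    scale = scale or (lambda n: n ** 0.5)
    return categorize(income_yen / scale(household_size), INCOME_CUTS, INCOME_LABELS)


# ------------------------------------------------------------ covariate scheme

SLEEP_LABELS = ("<10", "≥10")
OUTDOOR_LABELS = ("<1", "≥1 to <2", "≥2")
SCREEN_LABELS = ("<0.5", "≥0.5 to <1", "≥1")
PARENT_AGE_LABELS = ("20 to 29", "30 to 39", "≥40")
EDUCATION_LABELS = ("≤12", "13 to 14", "≥15")
OCCUPATION_LABELS = (
    "Professional and manager",
    "Office work, service, and sales",
    "Manual",
    "Unemployed",
)
SIBLING_LABELS = ("0", "1", "≥2")

#: ordered covariate scheme of the association table: variable -> (categories, reference)
COVARIATE_SCHEME: Mapping[str, tuple[tuple[str, ...], str]] = {
    "sex": (("Boys", "Girls"), "Boys"),
    "age": (("3", "4", "5", "6"), "3"),
    "weight_status": (WEIGHT_STATUS_LABELS, "Normal"),
    "sleep": (SLEEP_LABELS, "<10"),
    "outdoor": (OUTDOOR_LABELS, "<1"),
    "screen": (SCREEN_LABELS, "<0.5"),
    "maternal_age": (PARENT_AGE_LABELS, "20 to 29"),
    "maternal_weight_status": (WEIGHT_STATUS_LABELS, "Normal"),
    "maternal_education": (EDUCATION_LABELS, "≤12"),
    "maternal_occupation": (OCCUPATION_LABELS, "Professional and manager"),
    "maternal_smoking": (("No", "Yes"), "No"),
    "paternal_age": (PARENT_AGE_LABELS, "20 to 29"),
    "paternal_weight_status": (WEIGHT_STATUS_LABELS, "Normal"),
    "paternal_education": (EDUCATION_LABELS, "≤12"),
    "paternal_occupation": (OCCUPATION_LABELS, "Professional and manager"),
    "paternal_smoking": (("No", "Yes"), "No"),
    "grandparents": (("No", "Yes"), "No"),
    "siblings": (SIBLING_LABELS, "0"),
    "income": (INCOME_LABELS, "Low"),
}


@dataclass
class CovariateConfig:
    """Cutpoints and scales of the categorizers (defaults as in the scheme above)."""

    sleep_cuts: tuple[float, ...] = (10.0,)
    outdoor_cuts: tuple[float, ...] = (1.0, 2.0)
    screen_cuts: tuple[float, ...] = (0.5, 1.0)
    income_scale: Callable[[int], float] = staticmethod(lambda n: n ** 0.5)


def derive_covariates(
    raw: pd.DataFrame,
    child_cutoffs: Optional[pd.DataFrame] = None,
    config: Optional[CovariateConfig] = None,
) -> pd.DataFrame:
    """Map raw questionnaire-style fields to the categorical covariate scheme.

    Expects one row per child with columns: sex, age_years, height_cm,
    weight_kg, nap_h, night_sleep_h, outdoor_weekday_h, outdoor_weekend_h,
    screen_weekday_h, screen_weekend_h; maternal_/paternal_ age_band, bmi,
    education_band, occupation, smoking; grandparents (bool), siblings_band,
    income_yen, household_size.  Parent age/education bands and occupations
    arrive pre-coded (free-text coding is out of scope).
    """
    config = config or CovariateConfig()
    if child_cutoffs is None:
        child_cutoffs = load_child_bmi_cutoffs()
    out = pd.DataFrame(index=raw.index)
    out["sex"] = raw["sex"]
    out["age"] = raw["age_years"].astype(int).astype(str)
    out["weight_status"] = [
        child_weight_status(bmi(w, h), int(a), s, child_cutoffs)
        for w, h, a, s in zip(
            raw["weight_kg"], raw["height_cm"], raw["age_years"], raw["sex"]
        )
    ]
    out["sleep"] = [
        categorize(total_sleep(nap, night), config.sleep_cuts, SLEEP_LABELS)
        for nap, night in zip(raw["nap_h"], raw["night_sleep_h"])
    ]
    out["outdoor"] = [
        categorize(weekly_weighted_hours(wd, we), config.outdoor_cuts, OUTDOOR_LABELS)
        for wd, we in zip(raw["outdoor_weekday_h"], raw["outdoor_weekend_h"])
    ]
    out["screen"] = [
        categorize(weekly_weighted_hours(wd, we), config.screen_cuts, SCREEN_LABELS)
        for wd, we in zip(raw["screen_weekday_h"], raw["screen_weekend_h"])
    ]
    for parent in ("maternal", "paternal"):
        out[f"{parent}_age"] = raw[f"{parent}_age_band"]
        out[f"{parent}_weight_status"] = [
            adult_weight_status(v) for v in raw[f"{parent}_bmi"]
        ]
        out[f"{parent}_education"] = raw[f"{parent}_education_band"]
        out[f"{parent}_occupation"] = raw[f"{parent}_occupation"]
        out[f"{parent}_smoking"] = raw[f"{parent}_smoking"].map(
            lambda v: "Yes" if v in (True, 1, "Yes", "yes") else "No"
        )
    out["grandparents"] = raw["grandparents"].map(
        lambda v: "Yes" if v in (True, 1, "Yes", "yes") else "No"
    )
    out["siblings"] = raw["siblings_band"]
    out["income"] = [
        equivalized_income_tertile(inc, int(size), config.income_scale)
        for inc, size in zip(raw["income_yen"], raw["household_size"])
    ]
    for var, (categories, _) in COVARIATE_SCHEME.items():
        bad = set(out[var]) - set(categories)
        if bad:
            raise ValueError(f"{var}: derived unknown categories {sorted(bad)}")
    return out
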