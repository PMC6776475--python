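"""Seeded generators for every input of the analysis.

The study data (a national food-composition table, 3-day weighed dietary
records, and questionnaire covariates for a cohort of nursery-school children)
are not publicly available, so this module generates statistically matched
stand-ins:

* a ground-truthed food table whose items exercise every assignment step of
  both sugar cascades,
* a cohort of children whose covariate marginals, outcome model and intake
  distribution match the published cohort: n = 332 (166 boys / 166 girls,
  ages 3-6 at 87/86/85/74), energy ~ N(1371, 231) kcal/d, free-sugar %-energy
  gamma-distributed with mean 7.8 and SD 3.2, and an excessive-intake outcome
  driven by a logistic model over the covariates,
* 3-day dietary records (2 weekday + 1 weekend) whose computed energy and
  free-sugar %-energy hit each child's generated targets to within 0.1 %,
  with the free sugar spread over food groups so that confectionaries,
  sugar-sweetened beverages and sugars/jams dominate.

Hidden ground truth (true per-food sugar contents, true covariate effects and
latent outcome probabilities) is returned alongside every output so that the
engine and the estimators can be checked against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.special import expit

from .composition import (
    FOOD_GROUPS,
    FoodItem,
    ForeignTableRef,
    RuleSet,
    SaccharideProfile,
    SugarAssignment,
    build_database,
)
from .covariates import COVARIATE_SCHEME, load_child_bmi_cutoffs

# ---------------------------------------------------------------- configuration

#: per-category cohort counts (totals column of the published association table)
DEFAULT_MARGINALS: Mapping[str, Mapping[str, int]] = {
    "weight_status": {"Underweight": 35, "Normal": 269, "Overweight and obese": 28},
    "sleep": {"<10": 52, "≥10": 280},
    "outdoor": {"<1": 85, "≥1 to <2": 158, "≥2": 89},
    "screen": {"<0.5": 44, "≥0.5 to <1": 173, "≥1": 115},
    "maternal_age": {"20 to 29": 20, "30 to 39": 224, "≥40": 88},
    "maternal_weight_status": {"Underweight": 47, "Normal": 258, "Overweight and obese": 27},
    "maternal_education": {"≤12": 63, "13 to 14": 153, "≥15": 116},
    "maternal_occupation": {
        "Professional and manager": 162,
        "Office work, service, and sales": 129,
        "Manual": 28,
        "Unemployed": 13,
    },
    "maternal_smoking": {"No": 308, "Yes": 24},
    "paternal_age": {"20 to 29": 12, "30 to 39": 198, "≥40": 122},
    "paternal_weight_status": {"Underweight": 12, "Normal": 235, "Overweight and obese": 85},
    "paternal_education": {"≤12": 113, "13 to 14": 76, "≥15": 143},
    "paternal_occupation": {
        "Professional and manager": 148,
        "Office work, service, and sales": 90,
        "Manual": 92,
        "Unemployed": 2,
    },
    "paternal_smoking": {"No": 186, "Yes": 146},
    "grandparents": {"No": 272, "Yes": 60},
    "siblings": {"0": 54, "1": 182, "≥2": 96},
    "income": {"Low": 91, "Middle": 144, "High": 97},
}

#: generating adjusted odds ratios per non-reference category (log-odds enter the
#: outcome model); categories absent here have effect 0 (includes the paternal
#: "Unemployed" cell, whose published estimate is undefined by separation)
DEFAULT_ADJUSTED_OR: Mapping[tuple[str, str], float] = {
    ("sex", "Girls"): 0.91,
    ("age", "4"): 0.61,
    ("age", "5"): 0.43,
    ("age", "6"): 0.36,
    ("weight_status", "Underweight"): 0.83,
    ("weight_status", "Overweight and obese"): 0.86,
    ("sleep", "≥10"): 0.41,
    ("outdoor", "≥1 to <2"): 0.79,
    ("outdoor", "≥2"): 0.67,
    ("screen", "≥0.5 to <1"): 3.81,
    ("screen", "≥1"): 4.36,
    ("maternal_age", "30 to 39"): 2.08,
    ("maternal_age", "≥40"): 4.60,
    ("maternal_weight_status", "Underweight"): 0.77,
    ("maternal_weight_status", "Overweight and obese"): 0.65,
    ("maternal_education", "13 to 14"): 1.37,
    ("maternal_education", "≥15"): 0.85,
    ("maternal_occupation", "Office work, service, and sales"): 2.14,
    ("maternal_occupation", "Manual"): 1.53,
    ("maternal_occupation", "Unemployed"): 2.50,
    ("maternal_smoking", "Yes"): 1.78,
    ("paternal_age", "30 to 39"): 0.42,
    ("paternal_age", "≥40"): 0.52,
    ("paternal_weight_status", "Underweight"): 0.81,
    ("paternal_weight_status", "Overweight and obese"): 0.74,
    ("paternal_education", "13 to 14"): 1.30,
    ("paternal_education", "≥15"): 1.36,
    ("paternal_occupation", "Office work, service, and sales"): 0.58,
    ("paternal_occupation", "Manual"): 1.01,
    ("paternal_smoking", "Yes"): 0.74,
    ("grandparents", "Yes"): 1.95,
    ("siblings", "1"): 1.42,
    ("siblings", "≥2"): 0.78,
    ("income", "Middle"): 0.48,
    ("income", "High"): 0.45,
}

#: free-sugar allocation weights across food groups (proportional to the
#: published per-group mean contributions, g/d)
GROUP_ALLOCATION: Mapping[str, float] = {
    "Confectionaries": 10.3,
    "Sugar-sweetened beverages": 6.0,
    "Sugars and jams": 3.9,
    "Fruit and vegetable juices": 2.2,
    "Seasonings": 2.0,
    "Protein rich animal foods": 1.3,
    "Cereals and potatoes": 0.5,
    "Fruits and vegetables": 0.3,
    "Other foods": 0.3,
    "Pulses and nuts": 0.1,
}


@dataclass
class GeneratorConfig:
    """Study conditions emulated by the generators.

    Defaults reproduce the published cohort: size and sex/age structure,
    covariate marginals, the adjusted-OR outcome model, energy ~ N(1371, 231)
    kcal/d, and right-skewed free-sugar %-energy with mean 7.8 / SD 3.2
    (gamma; the excessive threshold of 10 %-energy then isolates ~22 % of
    children, matching the published prevalence of 21.7 %).
    """

    n_children: int = 332
    n_boys: int = 166
    age_counts: Mapping[int, int] = field(
        default_factory=lambda: {3: 87, 4: 86, 5: 85, 6: 74}
    )
    marginals: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
    )
    adjusted_or: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ADJUSTED_OR)
    )
    energy_mean: float = 1371.0
    energy_sd: float = 231.0
    energy_min: float = 600.0
    free_sugar_pct_mean: float = 7.8
    free_sugar_pct_sd: float = 3.2
    excessive_threshold_pct: float = 10.0
    group_allocation: Mapping[str, float] = field(
        default_factory=lambda: dict(GROUP_ALLOCATION)
    )
    allocation_jitter: float = 0.15  # per-child-day relative jitter of group weights

    def __post_init__(self) -> None:
        if self.n_children < 2:
            raise ValueError("need at least 2 children")
        if sum(self.age_counts.values()) != self.n_children:
            raise ValueError("age counts must sum to n_children")
        if self.free_sugar_pct_mean <= 0 or self.free_sugar_pct_sd <= 0:
            raise ValueError("free-sugar calibration must be positive")

    @property
    def gamma_shape(self) -> float:
        return (self.free_sugar_pct_mean / self.free_sugar_pct_sd) ** 2

    @property
    def gamma_scale(self) -> float:
        return self.free_sugar_pct_sd**2 / self.free_sugar_pct_mean

    @property
    def target_prevalence(self) -> float:
        """P(%E >= threshold) under the calibrated gamma — the latent outcome
        rate that keeps the %-energy mixture mean at its calibrated value."""
        return float(
            sps.gamma.sf(self.excessive_threshold_pct, self.gamma_shape, scale=self.gamma_scale)
        )


# ------------------------------------------------------------------- food db


def _profile(glucose=0.0, fructose=0.0, galactose=0.0, sucrose=0.0, lactose=0.0, maltose=0.0):
    return SaccharideProfile(glucose, fructose, galactose, sucrose, lactose, maltose)


def gen_food_db(
    config: Optional[GeneratorConfig] = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[FoodItem], pd.DataFrame]:
    """Synthetic food table plus hidden ground truth.

    Covers every total-sugar step (1-7) and every added/free step (1-11) with
    at least one item, provides sugar "carrier" foods with positive free sugar
    in all ten groups for the dietary-record generator, and zero-sugar fillers.
    Ground truth is computed here from the construction constants — never by
    running the assignment engine — so it can serve as an independent oracle.
    Carrier sugar contents are jittered (+/-10 %) by the seeded generator.
    """
    del config  # db layout is fixed; kept for interface symmetry
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    items: list[FoodItem] = []
    truth_rows: list[dict] = []

    def add(item: FoodItem, total: float, added: float, free: float) -> None:
        items.append(item)
        truth_rows.append(
            {"food_code": item.food_code, "true_total": total, "true_added": added,
             "true_free": free, "group": item.group}
        )

    j = lambda x: float(x * rng.uniform(0.9, 1.1))  # noqa: E731

    # --- carriers: one sugar-rich food per group, fully characterised -------
    bread_s = j(4.0)
    add(FoodItem("C_BREAD", "sweet roll", "Cereals and potatoes", 280, 50, 2.0, 30,
                 protein=8, fat=4, saturated_fat=1.5,
                 saccharides=_profile(glucose=0.5, sucrose=bread_s),
                 added_sugar_label=bread_s),
        bread_s + 0.5, bread_s, bread_s)
    add(FoodItem("C_SUGAR", "white sugar", "Sugars and jams", 387, 99.5, 0, 0.5,
                 saccharides=_profile(sucrose=99.0), all_sugar_added=True),
        99.0, 99.0, 99.0)
    paste_s = j(28.0)
    add(FoodItem("C_PASTE", "sweetened bean paste", "Pulses and nuts", 240, 54, 5.0, 38,
                 protein=5, fat=0.5,
                 saccharides=_profile(sucrose=paste_s, glucose=1.0),
                 added_sugar_label=paste_s),
        paste_s + 1.0, paste_s, paste_s)
    comp_s = j(8.0)
    add(FoodItem("C_COMPOTE", "fruit compote", "Fruits and vegetables", 70, 17, 1.2, 80,
                 saccharides=_profile(glucose=1.0, fructose=2.0, sucrose=comp_s),
                 added_sugar_label=comp_s),
        comp_s + 3.0, comp_s, comp_s)
    yog_s = j(6.0)
    add(FoodItem("C_YOGURT", "sweetened yogurt", "Protein rich animal foods", 90, 14, 0, 80,
                 protein=3.5, fat=3.0, saturated_fat=1.9,
                 saccharides=_profile(lactose=4.0, sucrose=yog_s),
                 natural_sugar=4.0),
        yog_s + 4.0, yog_s, yog_s)
    bisc_s = j(22.0)
    add(FoodItem("C_BISCUIT", "biscuit", "Confectionaries", 480, 65, 1.5, 3,
                 protein=6, fat=22, saturated_fat=11,
                 saccharides=_profile(glucose=2.0, sucrose=bisc_s),
                 added_sugar_label=bisc_s + 2.0),
        bisc_s + 2.0, bisc_s + 2.0, bisc_s + 2.0)
    oj_g, oj_f, oj_s = j(2.4), j(2.6), j(4.6)
    add(FoodItem("C_JUICE", "orange juice", "Fruit and vegetable juices", 45, 11, 0.2, 88,
                 saccharides=_profile(glucose=oj_g, fructose=oj_f, sucrose=oj_s),
                 no_added_sugar=True, is_fruit_juice_or_honey_or_syrup=True),
        oj_g + oj_f + oj_s, 0.0, oj_g + oj_f + oj_s)
    cola_c = j(11.2)
    add(FoodItem("C_COLA", "cola", "Sugar-sweetened beverages", 45, cola_c, 0, 88.5,
                 carbohydrate_is_all_sugar=True, all_sugar_added=True),
        cola_c, cola_c, cola_c)
    mirin_t = j(40.0)
    add(FoodItem("C_MIRIN", "sweet cooking wine", "Seasonings", 240, 45, 0, 47,
                 literature_total_sugar=mirin_t, assume_half_added=True),
        mirin_t, 0.5 * mirin_t, 0.5 * mirin_t)
    cocoa_s = j(20.0)
    add(FoodItem("C_COCOA", "sweetened cocoa mix", "Other foods", 400, 80, 6.0, 3,
                 protein=7, fat=6, saturated_fat=3.5,
                 saccharides=_profile(sucrose=cocoa_s, glucose=1.0),
                 added_sugar_label=cocoa_s),
        cocoa_s + 1.0, cocoa_s, cocoa_s)

    # --- fillers: zero free sugar, used to balance energy -------------------
    add(FoodItem("F_RICE", "cooked rice", "Cereals and potatoes", 168, 37.1, 0.3, 60,
                 protein=2.5, fat=0.3, saturated_fat=0.1,
                 saccharides=_profile(), no_added_sugar=True),
        0.0, 0.0, 0.0)
    add(FoodItem("F_CHICKEN", "grilled chicken", "Protein rich animal foods", 190, 0, 0, 64,
                 protein=25, fat=9, saturated_fat=2.6,
                 saccharides=_profile(), no_added_sugar=True),
        0.0, 0.0, 0.0)
    add(FoodItem("F_SPINACH", "boiled spinach", "Fruits and vegetables", 25, 4, 3.6, 91,
                 protein=2.6, fat=0.5,
                 saccharides=_profile(glucose=0.2, fructose=0.2), no_added_sugar=True),
        0.4, 0.0, 0.0)

    # --- step-coverage items (fixed values, independent hand-computed truth) -
    # total step 1 / free step 1: whole fruit, analytical profile
    add(FoodItem("S_APPLE", "apple, raw", "Fruits and vegetables", 57, 14.6, 1.9, 84,
                 saccharides=_profile(glucose=1.5, fructose=6.0, sucrose=3.6),
                 no_added_sugar=True),
        11.1, 0.0, 0.0)
    # total step 2 / free step 2: honey (carbohydrate is all sugar, all free)
    add(FoodItem("S_HONEY", "honey", "Sugars and jams", 303, 81.9, 0, 17.6,
                 carbohydrate_is_all_sugar=True, no_added_sugar=True,
                 is_fruit_juice_or_honey_or_syrup=True),
        81.9, 0.0, 81.9)
    # total step 3 / free step 9: literature value + fixed-proportion fallback
    add(FoodItem("S_CRACKER", "rice cracker, glazed", "Confectionaries", 380, 84, 1.0, 4,
                 literature_total_sugar=12.0, assume_half_added=True),
        12.0, 6.0, 6.0)
    # total step 4: dried form borrows from the raw form, dry-weight adjusted
    # ratio (100-20)/(100-84) = 5 -> 11.1 * 5 = 55.5
    add(FoodItem("S_DRIEDAPPLE", "apple, dried", "Fruits and vegetables", 300, 60, 3.0, 20,
                 raw_form_ref="S_APPLE", no_added_sugar=True),
        55.5, 0.0, 0.0)
    # total step 5: similar item (same family), dry-weight ratio (100-83)/(100-84)
    add(FoodItem("S_QUINCE", "quince, raw", "Fruits and vegetables", 55, 15, 1.8, 83,
                 similar_ref="S_APPLE", no_added_sugar=True),
        11.1 * 17.0 / 16.0, 0.0, 0.0)
    # total step 6 / free step 3: UK table, disaccharides as monosaccharide
    # equivalents -> 5 + 5 + 0.95 * 70 = 76.5
    add(FoodItem("S_CANDY", "imported boiled sweet", "Confectionaries", 390, 98, 0, 1,
                 foreign=ForeignTableRef(
                     "UK", _profile(glucose=5.0, fructose=5.0, sucrose=70.0),
                     disaccharide_as_monosaccharide_equivalent=True),
                 all_sugar_added=True),
        76.5, 76.5, 76.5)
    # total step 7 / free step 11: nothing known -> 0 g by residual assignment
    add(FoodItem("S_TEA", "herbal tea infusion", "Other foods", 1, 0.3, 0, 99.5),
        0.0, 0.0, 0.0)
    # free step 4: label value (total from literature)
    add(FoodItem("S_JELLY", "fruit jelly cup", "Confectionaries", 80, 19, 0.5, 80,
                 literature_total_sugar=15.0, added_sugar_label=12.0,
                 free_sugar_label=13.0),
        15.0, 12.0, 13.0)
    # free step 5: recipe decomposition: 0.2 x sugar (99 added) + 0.5 x apple (0)
    add(FoodItem("S_JAMBUN", "jam-filled bun", "Confectionaries", 290, 30, 1.0, 30,
                 literature_total_sugar=25.35,
                 recipe=[("C_SUGAR", 0.2), ("S_APPLE", 0.5), ("F_RICE", 0.3)]),
        25.35, 0.2 * 99.0, 0.2 * 99.0)
    # free step 6: borrow the added/free *fractions* of a similar item (cola: 1.0)
    add(FoodItem("S_SODA", "fruit-flavoured soda", "Sugar-sweetened beverages", 41, 10.2, 0, 89.5,
                 literature_total_sugar=10.0, similar_ref="C_COLA"),
        10.0, 10.0, 10.0)
    # free step 7: subtract the unsweetened equivalent (9.0 - 3.0)
    add(FoodItem("S_SOYMILK", "soymilk, plain", "Pulses and nuts", 46, 3.5, 0.2, 90,
                 protein=3.6, fat=2.0,
                 saccharides=_profile(glucose=0.5, sucrose=2.5), no_added_sugar=True),
        3.0, 0.0, 0.0)
    add(FoodItem("S_SWEETSOY", "soymilk, sweetened", "Pulses and nuts", 60, 9.8, 0.2, 84,
                 protein=3.2, fat=1.8,
                 saccharides=_profile(glucose=0.5, sucrose=8.5),
                 unsweetened_ref="S_SOYMILK"),
        9.0, 6.0, 6.0)
    # free step 8: subtract naturally occurring lactose (10.5 - 4.5)
    add(FoodItem("S_MILKDRINK", "sweetened milk drink", "Protein rich animal foods", 72, 11, 0, 81,
                 protein=3.0, fat=2.0, saturated_fat=1.3,
                 saccharides=_profile(lactose=4.5, sucrose=6.0),
                 natural_sugar=4.5),
        10.5, 6.0, 6.0)
    # free step 10: foreign-table added/free values (total from foreign sacchs)
    add(FoodItem("S_CEREAL", "imported breakfast cereal", "Cereals and potatoes", 380, 84, 3.0, 3,
                 foreign=ForeignTableRef(
                     "US", _profile(glucose=3.0, fructose=2.0, sucrose=20.0),
                     added_sugar=20.0, free_sugar=20.0)),
        25.0, 20.0, 20.0)

    truth = pd.DataFrame(truth_rows).set_index("food_code")
    return items, truth


# -------------------------------------------------------------------- cohort


def _design_matrix(categories: pd.DataFrame) -> pd.DataFrame:
    """Reference-coded indicator matrix over the covariate scheme."""
    cols = {}
    for var, (cats, ref) in COVARIATE_SCHEME.items():
        for cat in cats:
            if cat != ref:
                cols[f"{var}[{cat}]"] = (categories[var] == cat).astype(float)
    return pd.DataFrame(cols, index=categories.index)


def _effect_vector(design: pd.DataFrame, adjusted_or: Mapping[tuple[str, str], float]) -> pd.Series:
    beta = pd.Series(0.0, index=design.columns)
    for (var, cat), or_ in adjusted_or.items():
        col = f"{var}[{cat}]"
        if col in beta.index:
            beta[col] = math.log(or_)
    return beta


def calibrate_intercept(design: pd.DataFrame, beta: pd.Series, target: float) -> float:
    """Intercept making the mean latent outcome probability equal ``target``."""
    eta = design.to_numpy() @ beta.to_numpy()
    f = lambda a: expit(a + eta).mean() - target  # noqa: E731
    return float(optimize.brentq(f, -30.0, 30.0))


def _truncated_gamma(rng, shape, scale, low=None, high=None, size=1):
    """Inverse-CDF sampling of a gamma restricted to [low, high)."""
    lo = sps.gamma.cdf(low, shape, scale=scale) if low is not None else 0.0
    hi = sps.gamma.cdf(high, shape, scale=scale) if high is not None else 1.0
    u = rng.uniform(lo, hi, size=size)
    return sps.gamma.ppf(u, shape, scale=scale)


def gen_cohort(
    config: Optional[GeneratorConfig] = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort of children: raw questionnaire-style fields plus ground truth.

    Returns ``(raw, truth)``.  ``raw`` holds the fields the covariate module
    consumes (heights, durations, incomes, pre-coded parent bands); ``truth``
    holds the generating categories, latent probability, the excessive outcome,
    and each child's target energy (kcal/d), free-sugar %-energy and free-sugar
    g/d.  Covariates are drawn independently from the configured marginals;
    the outcome comes from the configured logistic model with the intercept
    calibrated so the mean latent probability equals the gamma tail mass above
    the excessive threshold (≈ 0.222 at default calibration) — conditioning the
    %-energy draw on the outcome then leaves its mixture mean at 7.8 exactly.
    """
    config = config or GeneratorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = config.n_children
    ids = [f"CH{i:04d}" for i in range(1, n + 1)]
    cutoffs = load_child_bmi_cutoffs()

    # fixed sex and age structure
    sex = np.array(["Boys"] * config.n_boys + ["Girls"] * (n - config.n_boys))
    rng.shuffle(sex)
    ages = np.concatenate([[a] * c for a, c in sorted(config.age_counts.items())]).astype(int)
    rng.shuffle(ages)

    cats = pd.DataFrame(index=ids)
    cats["sex"] = sex
    cats["age"] = ages.astype(str)
    for var, counts in config.marginals.items():
        labels = list(counts)
        p = np.array(list(counts.values()), dtype=float)
        cats[var] = rng.choice(labels, size=n, p=p / p.sum())

    raw = pd.DataFrame(index=ids)
    raw.index.name = "child_id"
    raw["sex"] = sex
    raw["age_years"] = ages
    # anthropometry consistent with the drawn weight-status category
    height = 95.0 + 6.0 * (ages - 3) + rng.normal(0, 3.5, n)
    bmis = np.empty(n)
    for i, (cat, a, s) in enumerate(zip(cats["weight_status"], ages, sex)):
        lo, hi = cutoffs.loc[(a, s), "lower"], cutoffs.loc[(a, s), "upper"]
        if cat == "Underweight":
            bmis[i] = rng.uniform(12.5, lo)
        elif cat == "Normal":
            bmis[i] = rng.uniform(lo, hi)
        else:
            bmis[i] = rng.uniform(hi, hi + 4.0)
    raw["height_cm"] = height
    raw["weight_kg"] = bmis * (height / 100.0) ** 2

    sleep_total = np.where(
        cats["sleep"] == "<10", rng.uniform(8.0, 10.0, n), rng.uniform(10.0, 12.5, n)
    )
    raw["nap_h"] = rng.uniform(0.5, 1.5, n)
    raw["night_sleep_h"] = sleep_total - raw["nap_h"]

    def duration_within(var: str, bounds: Mapping[str, tuple[float, float]]) -> np.ndarray:
        lo = cats[var].map(lambda c: bounds[c][0]).to_numpy()
        hi = cats[var].map(lambda c: bounds[c][1]).to_numpy()
        return rng.uniform(lo, hi)

    outdoor = duration_within("outdoor", {"<1": (0.1, 1.0), "≥1 to <2": (1.0, 2.0), "≥2": (2.0, 3.5)})
    screen = duration_within("screen", {"<0.5": (0.05, 0.5), "≥0.5 to <1": (0.5, 1.0), "≥1": (1.0, 3.0)})
    raw["outdoor_weekday_h"] = outdoor
    raw["outdoor_weekend_h"] = outdoor
    raw["screen_weekday_h"] = screen
    raw["screen_weekend_h"] = screen

    bmi_bounds = {"Underweight": (16.0, 18.5), "Normal": (18.5, 25.0), "Overweight and obese": (25.0, 31.0)}
    for parent in ("maternal", "paternal"):
        raw[f"{parent}_age_band"] = cats[f"{parent}_age"]
        lo = cats[f"{parent}_weight_status"].map(lambda c: bmi_bounds[c][0]).to_numpy()
        hi = cats[f"{parent}_weight_status"].map(lambda c: bmi_bounds[c][1]).to_numpy()
        raw[f"{parent}_bmi"] = rng.uniform(lo, hi)
        raw[f"{parent}_education_band"] = cats[f"{parent}_education"]
        raw[f"{parent}_occupation"] = cats[f"{parent}_occupation"]
        raw[f"{parent}_smoking"] = (cats[f"{parent}_smoking"] == "Yes").astype(int)
    raw["grandparents"] = (cats["grandparents"] == "Yes").astype(int)
    raw["siblings_band"] = cats["siblings"]
    size = rng.integers(3, 6, n)
    inc_bounds = {"Low": (1.0e6, 2.38e6), "Middle": (2.38e6, 3.34e6), "High": (3.34e6, 6.0e6)}
    lo = cats["income"].map(lambda c: inc_bounds[c][0]).to_numpy()
    hi = cats["income"].map(lambda c: inc_bounds[c][1]).to_numpy()
    raw["household_size"] = size
    raw["income_yen"] = rng.uniform(lo, hi) * np.sqrt(size)

    # outcome model
    design = _design_matrix(cats)
    beta = _effect_vector(design, config.adjusted_or)
    alpha = calibrate_intercept(design, beta, config.target_prevalence)
    p = expit(alpha + design.to_numpy() @ beta.to_numpy())
    y = rng.uniform(size=n) < p

    # intake targets
    thr = config.excessive_threshold_pct
    sh, sc = config.gamma_shape, config.gamma_scale
    pct = np.where(
        y,
        _truncated_gamma(rng, sh, sc, low=thr, size=n),
        _truncated_gamma(rng, sh, sc, high=thr, size=n),
    )
    a_trunc = (config.energy_min - config.energy_mean) / config.energy_sd
    energy = sps.truncnorm.rvs(
        a_trunc, np.inf, loc=config.energy_mean, scale=config.energy_sd,
        size=n, random_state=rng,
    )
    free_sugar_g = pct / 100.0 * energy / 4.0

    truth = cats.copy()
    truth.index.name = "child_id"
    truth["latent_p"] = p
    truth["excessive"] = y
    truth["intercept"] = alpha
    truth["target_energy_kcal"] = energy
    truth["target_free_sugar_pct"] = pct
    truth["target_free_sugar_g"] = free_sugar_g
    return raw, truth


# ------------------------------------------------------------ dietary records


def gen_dietary_records(
    truth: pd.DataFrame,
    items: Sequence[FoodItem],
    assignments: Mapping[str, SugarAssignment],
    config: Optional[GeneratorConfig] = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """3-day weighed records hitting each child's energy and free-sugar targets.

    Per child-day: the free-sugar target is split over the ten food groups by
    the (jittered) allocation weights; within each group one sugar carrier is
    drawn and its grams set so its free-sugar contribution is exact; fixed side
    portions (chicken, spinach) add protein and fat; cooked rice fills the
    remaining energy.  Amount rescaling, not rejection, makes the computed
    intake match the targets essentially exactly (well within 0.1 %).
    """
    config = config or GeneratorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_code = {it.food_code: it for it in items}
    carriers: dict[str, list[str]] = {g: [] for g in FOOD_GROUPS}
    for code, a in assignments.items():
        if a.free_sugar > 0.5:
            carriers[by_code[code].group].append(code)
    missing = [g for g, lst in carriers.items() if not lst and g in config.group_allocation]
    if missing:
        raise ValueError(f"no free-sugar carrier foods in groups: {missing}")

    side = [("F_CHICKEN", 70.0), ("F_SPINACH", 60.0)]
    filler = "F_RICE"
    base_w = np.array([config.group_allocation[g] for g in FOOD_GROUPS if g in config.group_allocation])
    alloc_groups = [g for g in FOOD_GROUPS if g in config.group_allocation]

    rows = []
    for child_id, child in truth.iterrows():
        e_target = child["target_energy_kcal"]
        f_target = child["target_free_sugar_g"]
        for day in (1, 2, 3):
            day_type = "weekend" if day == 3 else "weekday_school_lunch"
            w = base_w * rng.uniform(1 - config.allocation_jitter, 1 + config.allocation_jitter, len(base_w))
            w = w / w.sum()
            picks = [carriers[g][rng.integers(len(carriers[g]))] for g in alloc_groups]
            grams = {}
            for g, code, wi in zip(alloc_groups, picks, w):
                fs100 = assignments[code].free_sugar
                grams[code] = grams.get(code, 0.0) + wi * f_target / (fs100 / 100.0)
            energy_so_far = sum(
                amt / 100.0 * by_code[code].energy for code, amt in grams.items()
            )
            side_energy = sum(amt / 100.0 * by_code[code].energy for code, amt in side)
            remaining = e_target - energy_so_far - side_energy
            if remaining < 0:
                # sugar-dense day: move the energy-heavy carriers' free sugar
                # onto plain sugar (lowest kcal per g of free sugar) and retry
                heavy = [c for c in grams if by_code[c].group in
                         ("Confectionaries", "Cereals and potatoes", "Protein rich animal foods")]
                moved = sum(grams[c] * assignments[c].free_sugar / 100.0 for c in heavy)
                for c in heavy:
                    del grams[c]
                grams["C_SUGAR"] = grams.get("C_SUGAR", 0.0) + moved / (
                    assignments["C_SUGAR"].free_sugar / 100.0
                )
                energy_so_far = sum(
                    amt / 100.0 * by_code[code].energy for code, amt in grams.items()
                )
                remaining = e_target - energy_so_far - side_energy
            filler_grams = max(remaining, 0.0) / (by_code[filler].energy / 100.0)
            portions = list(grams.items()) + list(side) + [(filler, filler_grams)]
            for code, amt in portions:
                rows.append(
                    {"child_id": child_id, "day_index": day, "day_type": day_type,
                     "food_code": code, "amount": amt}
                )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ one-stop


@dataclass
class SimulatedStudy:
    """All generated inputs plus their ground truth."""

    food_items: list[FoodItem]
    food_truth: pd.DataFrame
    assignments: dict[str, SugarAssignment]
    cohort_raw: pd.DataFrame
    cohort_truth: pd.DataFrame
    records: pd.DataFrame


def simulate_study(
    seed: int = 0,
    config: Optional[GeneratorConfig] = None,
    rules: Optional[RuleSet] = None,
) -> SimulatedStudy:
    """Generate food table, cohort and records with one master seed.

    Independent child generators are spawned from the master seed, so each
    stage is individually reproducible.
    """
    config = config or GeneratorConfig()
    ss = np.random.SeedSequence(seed)
    r_food, r_cohort, r_records = (np.random.default_rng(s) for s in ss.spawn(3))
    items, food_truth = gen_food_db(config, r_food)
    assignments = build_database(items, rules)
    raw, truth = gen_cohort(config, r_cohort)
    records = gen_dietary_records(truth, items, assignments, config, r_records)
    return SimulatedStudy(items, food_truth, assignments, raw, truth, records)
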