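# Methods

## Sugar definitions and the assignment cascades

Total sugar is the sum of glucose, fructose, galactose, sucrose, lactose and
maltose per 100 g edible portion.  Added sugar covers sugars and syrups added
during processing or preparation; free sugar additionally includes the sugars
naturally present in honey, syrups and fruit juice (the WHO definition), but
never the intrinsic sugar of intact fruit or milk lactose.  Available
carbohydrate is carbohydrate − dietary fiber and is the physical ceiling for
any sugar value; every estimator's output is capped at it.

Missing data are a distinct state from a measured 0 g.  Absence of a
saccharide analysis drives the cascade to its next step; only the terminal
steps (total step 7, free step 11) convert absence of *all* information into
an assigned 0 g.

**Total sugar (7 steps, first applicable wins).**
1. Sum of the six saccharides when all are analysed.
2. Available carbohydrate for items flagged as consisting entirely of sugar.
   The flag is explicit input data, never inferred — there is no reliable
   inference rule from macronutrients alone.
3. A literature value.
4. The assigned total of the item's raw (or cooked/dried) form, scaled by the
   dry-weight ratio (100 − water_target)/(100 − water_referred).
5. As 4, but borrowing from a biologically similar item (same family/order).
6. A foreign composition-table entry: monosaccharides as printed,
   disaccharides multiplied by 0.95 when the source prints monosaccharide
   equivalents (hydrolysis adds one water per glycosidic bond).  The choice
   among candidate foreign sources is assumed pre-resolved into a single
   link in the input data.
7. 0 g.

**Added/free sugar (11 steps).**  The published description of this cascade
is not printed in full anywhere public, so the step vocabulary follows the
stepwise-estimation convention of the field, with configurable step ids:
(1) unprocessed foods with nothing added → added = free = 0;
(2) fruit juice/honey/syrup with nothing added → added = 0, free = total;
(3) items whose sugar is entirely added (granulated sugar, soft drinks) →
added = free = total; (4) analytical/label values; (5) recipe decomposition
(proportion-weighted sums over assigned ingredients, resolved recursively);
(6) borrowing the added/free *fractions* of a similar item; (7) subtracting
the total of an unsweetened equivalent; (8) subtracting the naturally
occurring sugar (e.g. lactose in sweetened dairy); (9) a fixed-proportion
fallback, `fallback_proportion × total` (default 0.5), fired by an explicit
per-item flag so that the foreign-table step stays reachable; (10) foreign
added/free values; (11) 0 g.  The chain added ≤ free ≤ total is enforced by
clamping with a logged warning.

Cross-references are resolved by memoised recursion, so input row order can
never change an assignment, re-runs are bit-identical, and genuine reference
cycles raise an error.  An unresolvable link logs a warning and falls through
to the next step.

## Intake estimation

Per child-day, nutrient intake is Σ grams consumed/100 × content per 100 g;
the child's mean is the unweighted average over the recorded days (the survey
design fixes 2 weekdays + 1 weekend day but states no weighting; optional
day weights exist for sensitivity analyses).  % of energy uses 4 kcal/g for
protein, carbohydrate and all sugar quantities and 9 kcal/g for fats, all
configurable.  Excessive free-sugar intake is free sugar ≥ 10 % of energy,
with the boundary in the excessive class.  Food-group contributions are
reported as the mean of per-child percentages rather than the ratio of cohort
means: the two differ under between-child heterogeneity, and the per-child
convention matches how such contributions are usually reported.

## Covariates

All printed "≥x" boundaries are inclusive upward, uniformly.  Weekday/weekend
durations combine with weights 5/7 and 2/7.  Child weight status uses age-
and sex-specific BMI cutoffs mapped to adult BMI 18.5/25; the packaged cutoff
table is a synthetic stand-in (the published IOTF table is licensed) and is
replaceable by a user file.  Household income is equivalized before
tertile-bucketing; the equivalence scale defaults to the square root of
household size (the specific published scale is cited but not printed in the
source) and is configurable.  Parent age/education bands and the four
occupation classes arrive pre-coded; free-text occupation coding is out of
scope, as is imputation — analyses are complete-case.

## Association analysis

Crude ORs are 2×2 cross-products against the per-variable reference category,
with Wald 95 % CIs on the log-odds scale (z = 1.959964).  The multivariable
model enters all covariates simultaneously as reference-coded indicators and
is fitted by Newton/IRLS maximum likelihood (statsmodels).  A category with
zero events (or zero non-events) has no finite MLE; such categories are
detected up front, excluded from the design, and reported "—" — matching how
the source table renders its separated cell — rather than patched with a
continuity correction (a Haldane–Anscombe +0.5 option exists behind a flag).
A fitted |log-OR| > 15 is likewise flagged as diverged.  Group-difference
tests are pooled-variance t-tests by default ("independent t-test" is
ambiguous; Welch via flag).  No multiple-testing adjustment is applied, as
none was in the source analysis; α = 0.05 two-sided.

## Synthetic data

The generators emulate the study conditions: 332 children (166/166 by sex,
ages 3–6 at 87/86/85/74), covariate categories drawn independently from the
published per-category counts, and an outcome ("excessive") drawn from a
logistic model whose coefficients are the published adjusted log-ORs (0 where
the published estimate is undefined).  Daily energy is truncated-normal
(mean 1371, SD 231, floor 600 kcal/d).  Free-sugar % energy is gamma with
mean 7.8 and SD 3.2 — gamma because the quantity is positive and
right-skewed; only mean and SD are published, so the shape is a modelling
choice.  Under that gamma, P(%E ≥ 10) = 0.2218, within sampling error of the
published prevalence 21.7 % at n = 332; the logistic intercept is calibrated
(by root-finding on the realised covariates) so the mean latent probability
equals exactly this tail mass, and each child's %E is then drawn from the
gamma truncated to [10, ∞) or [0, 10) according to the outcome.  This keeps
the %E mixture mean at 7.8 exactly and makes the excessive flag consistent
with the recorded diet by construction.

Dietary records are built by amount rescaling, not rejection: each day's
free-sugar target is split across the ten food groups by jittered weights
proportional to the published per-group contributions (confectionaries >
sugar-sweetened beverages > sugars and jams > …), one carrier food per group
gets the grams that deliver its share exactly, fixed side portions add
protein and fat, and plain rice fills the energy remainder.  If a
sugar-dense day would overshoot its energy target, the energy-heavy
carriers' share is moved onto plain sugar before filling.  Computed intakes
therefore reproduce each child's targets to machine precision (the tests
require 0.1 %).

The synthetic food table covers every cascade step at least once and carries
hand-computed ground truth derived from its construction constants, never
from the engine.  What the generator does **not** emulate: real Japanese
food names and recipes, day-to-day within-child variance beyond what a 3-day
mean needs, covariate correlations (drawn independently by default; a
correlation hook exists for stress tests), and realistic macronutrient
distributions beyond energy and free sugar — so passing tests validate the
pipeline's arithmetic, calibration and estimator behaviour, not nutritional
realism of the menus.

## Numerical choices and problem sizes

Sugar values are stored at full float precision; rounding (1 decimal for
intakes, 2 for ORs) happens only at render time.  The invariant chain uses a
1e-9 tolerance.  The logistic fit requires gradient convergence (statsmodels
Newton, maxiter 200) and reports non-convergence; the separation threshold
is |coefficient| > 15.  Parameter-recovery checks use one cohort of 50,000
children; because 36 coefficients are tested simultaneously, the
per-coefficient 3-SE convention is applied family-wise (Bonferroni bound
|z| < 3.96 plus a χ²₃₆ global calibration check at the 0.999 point) — a
literal per-coefficient 3-SE rule would reject a correct estimator in ~10 %
of runs.  Wald-CI coverage is checked over 600 simulated 2×2 tables (n = 150
per arm, true OR 2) against the 90–98 % band.  Calibration checks pool 10
cohorts of 332.

## Known limitations

The 11-step added/free vocabulary is a reconstruction; step ids are
configurable precisely because the authoritative mapping is unpublished.
Foreign-source selection and the literature search that yields step-3 values
are out of scope (pre-resolved inputs).  The crude-OR desk checks reproduce
the published table to its printed precision except two child-weight rows
that differ by ≤ 0.006 beyond rounding, and one upper CI bound that computes
16.74 vs a printed 16.73 — consistent with the source using a slightly
different CI convention for that digit.
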