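"""Association analysis for excessive free-sugar intake.

Implements the two estimators used in cross-sectional nutrition epidemiology
tables: crude odds ratios with Wald 95 % confidence intervals from 2x2
contingency tables, and multivariable-adjusted odds ratios from a single
logistic regression entering all categorical covariates simultaneously with
reference-level indicator coding.  Categories with an empty outcome cell
(complete separation) are flagged undefined rather than papered over with a
continuity correction; a Haldane-Anscombe correction is available behind a
flag for sensitivity use.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

#: two-sided 95 % normal critical value
Z_95 = 1.959964

#: |log-odds coefficient| beyond which a fitted effect is treated as diverged
_SEPARATION_COEF = 15.0


@dataclass
class ContingencyCell:
    """One category of one covariate: total count and count with the outcome."""

    category: str
    n_total: int
    n_excessive: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_excessive <= self.n_total:
            raise ValueError(
                f"{self.category}: need 0 <= n_excessive <= n_total, "
                f"got {self.n_excessive}/{self.n_total}"
            )


@dataclass
class OddsResult:
    """Odds ratio with its Wald CI; ``undefined`` marks separation (a zero cell)."""

    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    undefined: bool = False


def crude_or_ci(
    ref: ContingencyCell,
    cmp: ContingencyCell,
    z: float = Z_95,
    continuity_correction: bool = False,
) -> OddsResult:
    """Cross-product odds ratio of ``cmp`` vs ``ref`` with a Wald 95 % CI.

    With cells a = cmp cases, b = cmp non-cases, c = ref cases, d = ref
    non-cases: OR = ad/bc and CI = exp(ln OR +/- z * sqrt(1/a+1/b+1/c+1/d)).
    Any zero cell makes the estimate undefined (rendered "—" in reports)
    unless the Haldane-Anscombe +0.5 correction is requested.
    """
    a = cmp.n_excessive
    b = cmp.n_total - cmp.n_excessive
    c = ref.n_excessive
    d = ref.n_total - ref.n_excessive
    if min(a, b, c, d) == 0:
        if not continuity_correction:
            return OddsResult(None, None, None, undefined=True)
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    return OddsResult(or_, math.exp(log_or - z * se), math.exp(log_or + z * se))


def two_sample_t(
    x: Sequence[float], y: Sequence[float], equal_variance: bool = True
) -> tuple[float, float]:
    """Independent two-sample t-test (pooled variance by default, Welch optional).

    Returns (t, two-sided p).  If both groups are constant with equal means the
    statistic is undefined; (nan, nan) is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
        warnings.warn("degenerate t-test: both groups constant with equal means")
        return (math.nan, math.nan)
    res = scipy.stats.ttest_ind(x, y, equal_var=equal_variance)
    return (float(res.statistic), float(res.pvalue))


@dataclass
class LogisticFit:
    """Joint logistic fit: per-column coefficients, SEs and separation flags."""

    params: pd.Series
    bse: pd.Series
    converged: bool
    separated: pd.Series  # bool per column
    n_obs: int

    def odds_ratio(self, col: str, z: float = Z_95) -> OddsResult:
        if self.separated[col]:
            return OddsResult(None, None, None, undefined=True)
        coef, se = self.params[col], self.bse[col]
        return OddsResult(
            math.exp(coef), math.exp(coef - z * se), math.exp(coef + z * se)
        )


def fit_logistic(design: pd.DataFrame, outcome: Sequence[int]) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary outcome on an
    indicator-coded design matrix (intercept added here).

    Newton/IRLS fit via statsmodels; a coefficient whose magnitude diverges
    (|beta| > 15 on the log-odds scale) is flagged as separated and its OR is
    reported undefined.  Perfect-separation errors from the optimiser are
    caught and handled the same way by refitting without the offending column.
    """
    y = np.asarray(outcome, dtype=float)
    X = sm.add_constant(design.astype(float), has_constant="add")
    separated = pd.Series(False, index=X.columns)
    # a category with no events (or no non-events) among its members can not
    # have a finite MLE: detect up front and drop from the fit
    for col in design.columns:
        mask = design[col].to_numpy() > 0
        if mask.any() and (y[mask].sum() == 0 or y[mask].sum() == mask.sum()):
            separated[col] = True
    fit_cols = [c for c in X.columns if not separated[c]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X[fit_cols]).fit(disp=False, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            res = sm.Logit(y, X[fit_cols]).fit_regularized(disp=False, alpha=1e-8)
            converged = False
    params = pd.Series(0.0, index=X.columns)
    bse = pd.Series(np.inf, index=X.columns)
    params[fit_cols] = pd.Series(np.asarray(res.params), index=fit_cols)
    bse[fit_cols] = pd.Series(np.asarray(res.bse), index=fit_cols)
    diverged = params.abs() > _SEPARATION_COEF
    separated |= diverged
    return LogisticFit(
        params=params, bse=bse, converged=converged, separated=separated, n_obs=len(y)
    )


# --------------------------------------------------------------------- report


@dataclass
class AssociationRow:
    """One category of one covariate in the association table."""

    variable: str
    category: str
    n_total: int
    n_excessive: int
    is_reference: bool
    crude: OddsResult
    adjusted: OddsResult


def _fmt(result: OddsResult, is_reference: bool) -> str:
    if is_reference:
        return "1.0 (ref)"
    if result.undefined:
        return "—"
    return f"{result.odds_ratio:.2f} ({result.ci_low:.2f}, {result.ci_high:.2f})"


def association_table(
    covariates: pd.DataFrame,
    excessive: Sequence[bool],
    variables: Mapping[str, tuple[Sequence[str], str]],
    continuity_correction: bool = False,
) -> tuple[list[AssociationRow], LogisticFit]:
    """Crude and multivariable-adjusted ORs for every covariate category.

    ``variables`` maps each covariate column of ``covariates`` to its ordered
    category labels and its reference category.  Crude ORs come from per-
    variable 2x2 tables against the reference; adjusted ORs from one joint
    logistic fit of all indicator columns simultaneously.  A covariate that is
    constant in the data is dropped from the joint fit with a warning.
    Rounding to 2 decimals happens only in :func:`render_association_table`.
    """
    y = np.asarray(excessive, dtype=int)
    cells: dict[tuple[str, str], ContingencyCell] = {}
    for var, (categories, _ref) in variables.items():
        observed = set(covariates[var])
        unknown = observed - set(categories)
        if unknown:
            raise ValueError(f"{var}: unexpected categories {sorted(unknown)}")
        for cat in categories:
            mask = (covariates[var] == cat).to_numpy()
            cells[(var, cat)] = ContingencyCell(cat, int(mask.sum()), int(y[mask].sum()))

    design_cols: dict[str, np.ndarray] = {}
    for var, (categories, ref_cat) in variables.items():
        non_ref = [c for c in categories if c != ref_cat]
        if all(cells[(var, c)].n_total == 0 for c in non_ref) or cells[(var, ref_cat)].n_total == len(y):
            warnings.warn(f"{var}: constant in the data, dropped from the joint fit")
            continue
        for cat in non_ref:
            if cells[(var, cat)].n_total == 0:
                continue
            design_cols[f"{var}[{cat}]"] = (covariates[var] == cat).to_numpy(dtype=float)
    design = pd.DataFrame(design_cols, index=covariates.index)
    fit = fit_logistic(design, y)

    rows: list[AssociationRow] = []
    for var, (categories, ref_cat) in variables.items():
        ref_cell = cells[(var, ref_cat)]
        for cat in categories:
            cell = cells[(var, cat)]
            is_ref = cat == ref_cat
            if is_ref:
                crude = adjusted = OddsResult(1.0, None, None)
            else:
                crude = crude_or_ci(
                    ref_cell, cell, continuity_correction=continuity_correction
                )
                col = f"{var}[{cat}]"
                adjusted = (
                    fit.odds_ratio(col)
                    if col in fit.params.index
                    else OddsResult(None, None, None, undefined=True)
                )
            rows.append(
                AssociationRow(
                    variable=var,
                    category=cat,
                    n_total=cell.n_total,
                    n_excessive=cell.n_excessive,
                    is_reference=is_ref,
                    crude=crude,
                    adjusted=adjusted,
                )
            )
    return rows, fit


def association_frame(rows: Sequence[AssociationRow]) -> pd.DataFrame:
    """Numeric association table (full precision) as a DataFrame."""
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "category": r.category,
                "n_total": r.n_total,
                "n_excessive": r.n_excessive,
                "reference": r.is_reference,
                "crude_or": r.crude.odds_ratio,
                "crude_ci_low": r.crude.ci_low,
                "crude_ci_high": r.crude.ci_high,
                "crude_undefined": r.crude.undefined,
                "adjusted_or": r.adjusted.odds_ratio,
                "adjusted_ci_low": r.adjusted.ci_low,
                "adjusted_ci_high": r.adjusted.ci_high,
                "adjusted_undefined": r.adjusted.undefined,
            }
            for r in rows
        ]
    )


def render_association_table(rows: Sequence[AssociationRow]) -> str:
    """Formatted text table (ORs rounded to 2 decimals, '—' for separation)."""
    lines = [
        f"{'variable':<24}{'category':<28}{'n':>6}{'n excl.':>9}  "
        f"{'crude OR (95% CI)':<22}{'adjusted OR (95% CI)':<22}"
    ]
    for r in rows:
        lines.append(
            f"{r.variable:<24}{r.category:<28}{r.n_total:>6}{r.n_excessive:>9}  "
            f"{_fmt(r.crude, r.is_reference):<22}{_fmt(r.adjusted, r.is_reference):<22}"
        )
    return "\n".join(lines)
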