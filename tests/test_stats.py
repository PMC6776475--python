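"""Odds ratios, Wald CIs, t-tests and the joint logistic fit."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sugarintake.covariates import COVARIATE_SCHEME
from sugarintake.stats import (
    ContingencyCell,
    OddsResult,
    association_frame,
    association_table,
    crude_or_ci,
    fit_logistic,
    two_sample_t,
)


class TestCrudeOr:
    def test_published_screen_time_row(self):
        res = crude_or_ci(ContingencyCell("<0.5", 44, 3), ContingencyCell("mid", 173, 39))
        assert round(res.odds_ratio, 2) == 3.98
        assert round(res.ci_low, 2) == 1.17
        assert round(res.ci_high, 2) == 13.54

    def test_published_sleep_row(self):
        res = crude_or_ci(ContingencyCell("<10", 52, 15), ContingencyCell("≥10", 280, 57))
        assert round(res.odds_ratio, 2) == 0.63

    def test_identical_cells_give_unity(self):
        cell = ContingencyCell("x", 50, 10)
        assert crude_or_ci(cell, cell).odds_ratio == pytest.approx(1.0)

    def test_zero_cell_is_undefined(self):
        res = crude_or_ci(ContingencyCell("r", 50, 10), ContingencyCell("c", 2, 0))
        assert res.undefined and res.odds_ratio is None

    def test_continuity_correction_defines_zero_cell(self):
        res = crude_or_ci(
            ContingencyCell("r", 50, 10), ContingencyCell("c", 2, 0),
            continuity_correction=True,
        )
        assert not res.undefined and res.odds_ratio > 0

    @given(k=st.integers(2, 50))
    @settings(deadline=None)
    def test_count_scaling_preserves_or_and_narrows_ci(self, k):
        ref, cmp_ = ContingencyCell("r", 40, 10), ContingencyCell("c", 60, 30)
        base = crude_or_ci(ref, cmp_)
        scaled = crude_or_ci(
            ContingencyCell("r", 40 * k, 10 * k), ContingencyCell("c", 60 * k, 30 * k)
        )
        assert scaled.odds_ratio == pytest.approx(base.odds_ratio)
        assert scaled.ci_high - scaled.ci_low < base.ci_high - base.ci_low

    def test_invalid_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyCell("x", 5, 6)


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_hand_computation(self):
        # {1,2,3} vs {4,5,6}: pooled s2 = 1, se = sqrt(2/3), t = -3/se
        t, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.0 / math.sqrt(2.0 / 3.0))

    def test_swap_flips_sign_only(self):
        x, y = [1.0, 2.0, 4.0], [3.0, 5.0, 8.0]
        t1, p1 = two_sample_t(x, y)
        t2, p2 = two_sample_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_groups_warn_nan(self):
        with pytest.warns(UserWarning):
            t, p = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert math.isnan(p)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestLogisticFit:
    def test_saturated_single_covariate_equals_closed_form(self):
        # 2x2 table as individual rows: exp(beta) must equal the cross-product OR
        a, b, c, d = 39, 134, 3, 41
        x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        closed = crude_or_ci(ContingencyCell("r", c + d, c), ContingencyCell("c", a + b, a))
        assert math.exp(fit.params["x"]) == pytest.approx(closed.odds_ratio, abs=1e-6)

    def test_null_model_or_near_one(self, rng):
        n = 20000
        x = rng.integers(0, 2, n).astype(float)
        y = rng.integers(0, 2, n)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.odds_ratio("x").odds_ratio == pytest.approx(1.0, abs=0.1)

    def test_separated_column_flagged_undefined(self):
        x = np.array([1.0] * 5 + [0.0] * 20)
        y = np.array([0] * 5 + [1] * 10 + [0] * 10)  # no events where x = 1
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.separated["x"]
        assert fit.odds_ratio("x").undefined


class TestAssociationTable:
    def test_reference_rows_carry_or_one(self, study, study_summaries):
        from sugarintake.covariates import derive_covariates

        covs = derive_covariates(study.cohort_raw)
        rows, _ = association_table(covs, study_summaries["excessive"], COVARIATE_SCHEME)
        for row in rows:
            if row.is_reference:
                assert row.crude.odds_ratio == 1.0
                assert row.adjusted.odds_ratio == 1.0

    def test_counts_partition_cohort(self, study, study_summaries):
        from sugarintake.covariates import derive_covariates

        covs = derive_covariates(study.cohort_raw)
        rows, _ = association_table(covs, study_summaries["excessive"], COVARIATE_SCHEME)
        frame = association_frame(rows)
        per_var = frame.groupby("variable")["n_total"].sum()
        assert (per_var == len(covs)).all()

    def test_constant_covariate_dropped_with_warning(self):
        covs = pd.DataFrame({"a": ["x"] * 30 + ["y"] * 30, "b": ["only"] * 60})
        y = [True, False] * 30
        scheme = {"a": (("x", "y"), "x"), "b": (("only", "other"), "only")}
        with pytest.warns(UserWarning, match="constant"):
            rows, _ = association_table(covs, y, scheme)
        b_rows = [r for r in rows if r.variable == "b" and not r.is_reference]
        assert all(r.adjusted.undefined for r in b_rows)


class TestWaldCoverage:
    def test_ci_coverage_between_90_and_98(self, rng):
        """Wald 95 % CI covers the true OR in 90-98 % of simulated 2x2 tables."""
        true_or = 2.0
        p_ref = 0.3
        odds_cmp = true_or * p_ref / (1 - p_ref)
        p_cmp = odds_cmp / (1 + odds_cmp)
        n = 150
        covered = total = 0
        for _ in range(600):
            a = rng.binomial(n, p_cmp)
            c = rng.binomial(n, p_ref)
            res = crude_or_ci(ContingencyCell("r", n, int(c)), ContingencyCell("c", n, int(a)))
            if res.undefined:
                continue
            total += 1
            covered += res.ci_low <= true_or <= res.ci_high
        assert total >= 500
        assert 0.90 <= covered / total <= 0.98
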