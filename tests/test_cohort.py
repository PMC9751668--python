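"""Cohort summaries, increment percentages, ANOVA + LSD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from perfpaint import anova_lsd, increment_percent, summarize


class TestIncrementPercent:
    @pytest.mark.parametrize(
        "reference,comparator,expected",
        [
            (64.42, 77.42, 20.18),
            (8.92, 9.39, 5.27),
            (63.43, 75.86, 19.60),
            (0.64, 0.72, 12.50),
        ],
    )
    def test_reported_increments(self, reference, comparator, expected):
        assert round(increment_percent(reference, comparator), 2) == expected

    def test_identity_is_zero(self):
        for x in (0.5, 60.0, -3.0):
            assert increment_percent(x, x) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero reference"):
            increment_percent(0.0, 5.0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.floats(0.1, 1e4),
        st.floats(-1e4, 1e4),
    )
    def test_roundtrip_recovers_comparator(self, reference, comparator):
        pct = increment_percent(reference, comparator)
        assert reference * (1.0 + pct / 100.0) == pytest.approx(comparator, abs=1e-9, rel=1e-9)


class TestAnovaLsd:
    def test_identical_groups_f_zero_p_one(self):
        g = {"a": [3.0, 3.0, 3.0], "b": [3.0, 3.0, 3.0], "c": [3.0, 3.0, 3.0]}
        res = anova_lsd(g)
        assert res["F"] == 0.0
        assert res["p"] == 1.0

    def test_textbook_three_group_anova(self):
        res = anova_lsd({"g1": [1, 2, 3], "g2": [2, 3, 4], "g3": [3, 4, 5]})
        assert res["F"] == pytest.approx(3.0)
        assert res["df"] == (2, 6)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(loc, 1.0, 20) for k, loc in [("a", 0.0), ("b", 0.5), ("c", 1.3)]}
        res = anova_lsd(groups)
        f_ref, p_ref = sps.f_oneway(*groups.values())
        assert res["F"] == pytest.approx(float(f_ref), rel=1e-10)
        assert res["p"] == pytest.approx(float(p_ref), rel=1e-10)

    def test_separated_tight_groups_significant(self):
        res = anova_lsd({"a": [1.0, 1.01, 0.99], "b": [10.0, 10.01, 9.99]})
        assert res["pairwise"][("a", "b")]["p"] < 0.001
        assert res["pairwise"][("a", "b")]["significant"]

    def test_two_group_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 15), rng.normal(0.7, 1, 12)
        res = anova_lsd({"a": a, "b": b})
        t_ref, p_ref = sps.ttest_ind(a, b)  # pooled-variance t test
        assert res["F"] == pytest.approx(float(t_ref) ** 2, rel=1e-10)
        assert res["pairwise"][("a", "b")]["p"] == pytest.approx(float(p_ref), rel=1e-10)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            anova_lsd({"a": [1.0], "b": [2.0, 3.0]})
        with pytest.raises(ValueError):
            anova_lsd({"a": [1.0, 2.0]})


def make_table(values_by_plan: dict[str, list[float]], structure="ptv", metric="d_mean"):
    rows = []
    for plan, values in values_by_plan.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "subject": f"s{i}",
                    "plan": plan,
                    "structure": structure,
                    "metric": metric,
                    "value": v,
                }
            )
    return pd.DataFrame(rows)


class TestSummarize:
    def test_mean_and_sample_sd(self):
        table = make_table({"plan1": [10.0, 20.0], "plan2": [11.0, 21.0]})
        summary = summarize(table)
        row = summary.stats.loc[("ptv", "d_mean")]
        assert row["plan1_mean"] == pytest.approx(15.0)
        assert row["plan1_sd"] == pytest.approx(np.std([10, 20], ddof=1))
        assert round(row["plan1_sd"], 2) == 7.07

    def test_proportional_plans_give_expected_increment(self):
        base = [55.0, 60.0, 65.0, 70.0]
        table = make_table({"plan1": base, "plan2": [1.2 * v for v in base]})
        summary = summarize(table)
        row = summary.stats.loc[("ptv", "d_mean")]
        assert row["pct_plan1_plan2"] == pytest.approx(20.0)

    def test_increments_from_reported_table_means(self):
        """Feeding the published per-plan means through the summary increments
        reproduces the full printed increment set for the target Dmean."""
        from perfpaint.reference import REFERENCE_DOSE_MEANS_GY

        expected = {
            ("ptv", "d2"): (20.18, 24.05),
            ("ptv", "d98"): (8.34, 6.77),
            ("ptv", "d_mean"): (18.38, 17.00),
            ("ptv_h", "d2"): (20.50, 24.88),
            ("ptv_h", "d98"): (19.32, 17.22),
            ("ptv_h", "d_mean"): (19.60, 19.22),
            ("ptv_n", "d2"): (18.81, 19.69),
            ("ptv_n", "d98"): (7.17, 5.15),
            ("ptv_n", "d_mean"): (14.31, 11.80),
        }
        for (structure, metric), (pct12, pct13) in expected.items():
            means = REFERENCE_DOSE_MEANS_GY[structure][metric]
            assert round(increment_percent(means["plan1"], means["plan2"]), 2) == pct12
            assert round(increment_percent(means["plan1"], means["plan3"]), 2) == pct13

    def test_permutation_invariance(self):
        table = make_table({"plan1": [1.0, 2.0, 3.0], "plan2": [2.0, 3.0, 4.0]})
        shuffled = table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = summarize(table).stats
        b = summarize(shuffled).stats
        pd.testing.assert_frame_equal(a, b)

    def test_duplicate_rows_rejected(self):
        table = make_table({"plan1": [1.0, 2.0]})
        dup = pd.concat([table, table.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            summarize(dup)

    def test_missing_plan_cells_reported_nan(self):
        table = make_table({"plan1": [1.0, 2.0], "plan2": [2.0, 3.0]})
        extra = make_table({"plan1": [5.0, 6.0]}, structure="ptv_h")
        summary = summarize(pd.concat([table, extra], ignore_index=True))
        row = summary.stats.loc[("ptv_h", "d_mean")]
        assert np.isnan(row["plan2_mean"])
        assert np.isnan(row["pct_plan1_plan2"])

    def test_anova_columns_present(self):
        table = make_table(
            {"plan1": [1.0, 2.0, 3.0], "plan2": [2.0, 3.0, 4.0], "plan3": [3.0, 4.0, 5.0]}
        )
        row = summarize(table).stats.loc[("ptv", "d_mean")]
        assert row["F"] == pytest.approx(3.0)
        for col in ("p_plan1_plan2", "p_plan1_plan3", "p_plan2_plan3"):
            assert 0.0 <= row[col] <= 1.0
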