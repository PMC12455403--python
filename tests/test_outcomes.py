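"""Outcome coding, survival analysis, and the group-comparison statistics."""

import numpy as np
import pytest
from scipy import stats

from dwiclust.outcomes import (
    SubjectOutcome,
    SurvivalRecord,
    chisq_yates,
    compare_counts,
    km_logrank,
    proportion_ci90,
    seizure_free_at,
    to_survival,
    wilcoxon_ranksum,
)


def _outcome(ilae, sid="s"):
    return SubjectOutcome(subject_id=sid, ilae_by_year=ilae)


class TestSeizureFreedomCoding:
    def test_ilae_1_and_2_are_free_3plus_not(self):
        assert seizure_free_at(_outcome([1]), 1) is True
        assert seizure_free_at(_outcome([2]), 1) is True
        assert seizure_free_at(_outcome([5]), 1) is False

    def test_missing_followup_is_none(self):
        assert seizure_free_at(_outcome([1, 1]), 3) is None

    def test_validation(self):
        with pytest.raises(ValueError):
            _outcome([])
        with pytest.raises(ValueError):
            _outcome([7])
        with pytest.raises(ValueError):
            seizure_free_at(_outcome([1]), 6)


class TestToSurvival:
    @pytest.mark.parametrize(
        "ilae, time, event",
        [
            ([1, 1, 4], 3, True),  # first relapse at year 3
            ([1, 1], 2, False),  # lost to follow-up: censored
            ([3], 1, True),  # immediate relapse
            ([1, 4, 1, 1], 2, True),  # relapse then remission still counts
            ([2, 2, 2, 2, 2], 5, False),
        ],
    )
    def test_event_coding(self, ilae, time, event):
        rec = to_survival(_outcome(ilae))
        assert (rec.time_years, rec.event) == (time, event)


class TestKmLogrank:
    def test_identical_groups_give_null_test(self):
        recs = [SurvivalRecord(f"s{i}", t, e) for i, (t, e) in
                enumerate([(1, True), (3, True), (5, False)])]
        curves, test = km_logrank({"a": recs, "b": list(recs)})
        assert test.statistic == pytest.approx(0.0, abs=1e-12)
        assert test.p_value == pytest.approx(1.0)

    def test_matches_hand_computed_risk_tables(self):
        # events at years {1,1,2} vs all censored at 5: O-E = 1.75,
        # V = 0.5875 from the 2x2 risk tables, chi2 = 1.75^2 / 0.5875
        a = [SurvivalRecord("a1", 1, True), SurvivalRecord("a2", 1, True),
             SurvivalRecord("a3", 2, True)]
        b = [SurvivalRecord(f"b{i}", 5, False) for i in range(3)]
        _, test = km_logrank({"a": a, "b": b})
        assert test.statistic == pytest.approx(1.75**2 / 0.5875, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank({"a": [SurvivalRecord("s", 1, True)], "b": []})

    def test_curves_are_proper_survival_functions(self):
        rng = np.random.default_rng(0)
        groups = {
            g: [SurvivalRecord(f"{g}{i}", int(t), bool(e)) for i, (t, e) in
                enumerate(zip(rng.integers(1, 6, 20), rng.random(20) < 0.6))]
            for g in ("x", "y")
        }
        curves, _ = km_logrank(groups)
        for g, sub in curves.groupby("group"):
            s = sub.sort_values("time_years")["survival"].to_numpy()
            assert s[0] == 1.0
            assert (np.diff(s) <= 1e-12).all()


class TestChisqYates:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[80, 59], [24, 37]], 4.93),  # side, left:right
            ([[56, 83], [33, 28]], 2.74),  # sex, male:female
            ([[108, 31], [47, 14]], 0.00),  # type, temporal:extratemporal
            ([[18, 121], [14, 47]], 2.45),  # MRI, nonlesional:lesional
        ],
    )
    def test_reproduces_printed_statistics(self, table, expected):
        assert chisq_yates(table).statistic == pytest.approx(expected, abs=0.005)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_yates([[0, 0], [5, 5]])


class TestWilcoxonRanksum:
    def test_identical_samples_give_p_one(self):
        res = wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_w_is_minimum_when_x_below_y(self):
        res = wilcoxon_ranksum([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 3.0  # ranks 1+2, the smallest possible

    def test_label_swap_mirrors_statistic(self):
        x, y = [1.0, 5.0, 2.0], [4.0, 3.0, 6.0, 7.0]
        a = wilcoxon_ranksum(x, y)
        b = wilcoxon_ranksum(y, x)
        n = len(x) + len(y)
        assert a.statistic + b.statistic == n * (n + 1) / 2
        assert a.p_value == pytest.approx(b.p_value)

    def test_all_tied_data_degenerate_p_one(self):
        assert wilcoxon_ranksum([2.0, 2.0], [2.0, 2.0, 2.0]).p_value == 1.0


class TestProportionCI:
    def test_zero_successes_lower_bound_zero(self):
        est, lo, hi = proportion_ci90(0, 10)
        assert est == 0.0
        assert lo == 0.0

    def test_reported_rate_28_of_35(self):
        est, lo, hi = proportion_ci90(28, 35)
        assert est == pytest.approx(0.80)
        assert lo < 0.80 < hi

    def test_matches_numeric_score_test_inversion(self):
        n, k = 100, 50
        zc = stats.norm.ppf(0.95)
        grid = np.linspace(1e-6, 1 - 1e-6, 200001)
        accept = np.abs(k / n - grid) <= zc * np.sqrt(grid * (1 - grid) / n)
        lo_oracle, hi_oracle = grid[accept][0], grid[accept][-1]
        est, lo, hi = proportion_ci90(k, n)
        assert lo == pytest.approx(lo_oracle, abs=1e-4)
        assert hi == pytest.approx(hi_oracle, abs=1e-4)
        # interval shrinks toward 1/2: symmetric about the point estimate here
        assert lo < 0.5 < hi

    def test_validation(self):
        with pytest.raises(ValueError):
            proportion_ci90(1, 0)
        with pytest.raises(ValueError):
            proportion_ci90(5, 3)


class TestCompareCounts:
    def test_identical_distributions_p_one(self):
        assert compare_counts([2, 3, 2, 3], [3, 2, 3, 2]).p_value == pytest.approx(1.0)

    def test_extreme_separation_reaches_smallest_attainable_p(self):
        res = compare_counts([1, 1, 1], [9, 9, 9])
        # closed-form tie-corrected normal approximation at the extreme
        # arrangement (W = 6, mu = 10.5, tie-corrected var = 4.05)
        z = (6 - 10.5) / np.sqrt(4.05)
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(z)))
        assert res.p_value < 0.05

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            counts = rng.poisson(3.0, size=40) + 1
            rejections += compare_counts(counts[:20], counts[20:]).p_value < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07
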