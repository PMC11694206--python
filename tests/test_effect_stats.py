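"""Paired/independent mean differences, effect sizes, magnitude bands."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.weightstats import CompareMeans, DescrStatsW

from sprintwindow import (
    InsufficientDataError,
    MissingPositionError,
    classify_effect_size,
    consecutive_interval_diffs,
    independent_mean_diff,
    paired_mean_diff,
    pooled_position_means,
)
from sprintwindow.effect_stats import CONSECUTIVE_PAIRS, MAGNITUDE_LABELS
from sprintwindow.reference import reference_position_summary
from sprintwindow.windowing import PerSecondProfile


def make_profile(values, position="CM", player="P01", match="M1"):
    values = np.asarray(values, dtype=float)
    return PerSecondProfile(
        player_id=player, match_id=match, position=position,
        values_kmh=values, available=~np.isnan(values),
    )


class TestClassifyEffectSize:
    @pytest.mark.parametrize(
        "d,ci,expected",
        [
            (0.68, (0.64, 0.73), "moderate"),
            (0.03, (-0.02, 0.07), "unclear"),
            (-0.73, (-0.78, -0.68), "moderate"),  # sign ignored for banding
            (0.19, (0.1, 0.2), "trivial"),
            (0.2, (0.1, 0.3), "small"),  # cut-point belongs to larger band
            (1.40, (0.63, 2.40), "large"),
            (4.5, (4.1, 5.0), "extremely large"),
            (0.5, (0.0, 1.0), "unclear"),  # endpoint touching zero
            (-0.5, (-1.0, 0.0), "unclear"),
        ],
    )
    def test_examples(self, d, ci, expected):
        assert classify_effect_size(d, ci) == expected

    def test_invalid_ci_rejected(self):
        with pytest.raises(ValueError):
            classify_effect_size(0.5, (1.0, 0.5))

    @given(
        d1=st.floats(0.01, 10),
        d2=st.floats(0.01, 10),
        lo=st.floats(0.01, 1),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_monotone_in_magnitude(self, d1, d2, lo):
        """With a fixed CI off zero, a larger |d| never gets a smaller band."""
        ci = (lo, lo + 1)
        small, big = sorted([d1, d2])
        bands = [MAGNITUDE_LABELS.index(classify_effect_size(d, ci)) for d in (small, big)]
        assert bands[0] <= bands[1]


class TestPairedMeanDiff:
    def test_identical_vectors_are_unclear(self):
        res = paired_mean_diff([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.mean_diff_kmh == 0.0
        assert res.d == 0.0
        assert res.magnitude == "unclear"

    def test_pure_shift_is_degenerate(self):
        res = paired_mean_diff([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.mean_diff_kmh == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0)  # zero-variance differences
        assert res.ci_high == pytest.approx(1.0)
        assert res.d == pytest.approx(1.0)  # s_av = 1
        assert res.magnitude == "moderate"

    def test_mean_of_diffs_equals_diff_of_means(self):
        rng = np.random.default_rng(3)
        a = rng.normal(18, 6, 50)
        b = rng.normal(22, 6, 50)
        res = paired_mean_diff(a, b)
        assert res.mean_diff_kmh == pytest.approx(b.mean() - a.mean(), abs=1e-12)

    def test_incomplete_pairs_dropped(self):
        a = [1.0, 2.0, np.nan, 4.0]
        b = [2.0, np.nan, 3.0, 5.0]
        res = paired_mean_diff(a, b)
        assert res.n == 2

    def test_fewer_than_two_pairs_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            paired_mean_diff([1.0, np.nan], [2.0, 3.0])

    def test_ci_matches_statsmodels_paired_interval(self):
        rng = np.random.default_rng(4)
        a = rng.normal(20, 5, 40)
        b = a + rng.normal(3, 2, 40)
        res = paired_mean_diff(a, b)
        lo, hi = DescrStatsW(b - a).tconfint_mean(alpha=0.05)
        assert res.ci_low == pytest.approx(lo, abs=1e-10)
        assert res.ci_high == pytest.approx(hi, abs=1e-10)

    def test_d_uses_average_condition_sd(self):
        rng = np.random.default_rng(5)
        a = rng.normal(20, 5, 60)
        b = a + rng.normal(4, 1, 60)
        res = paired_mean_diff(a, b)
        s_av = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        assert res.d == pytest.approx((b - a).mean() / s_av, abs=1e-12)


class TestIndependentMeanDiff:
    def test_identical_groups_unclear(self):
        res = independent_mean_diff([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_diff_kmh == 0.0
        assert res.magnitude == "unclear"

    def test_degenerate_zero_variance_groups(self):
        res = independent_mean_diff([29.11] * 20, [31.64] * 10)
        assert res.mean_diff_kmh == pytest.approx(2.53)
        assert res.ci_low == pytest.approx(2.53)
        assert res.ci_high == pytest.approx(2.53)
        assert abs(res.d) > 4  # essentially infinite standardized effect
        assert res.magnitude == "extremely large"

    def test_insufficient_group_size(self):
        with pytest.raises(InsufficientDataError):
            independent_mean_diff([1.0], [2.0, 3.0])

    @pytest.mark.parametrize("equal_var", [True, False])
    def test_matches_statsmodels_two_sample_interval(self, equal_var):
        rng = np.random.default_rng(6)
        x = rng.normal(29.5, 1.8, 10)
        y = rng.normal(30.5, 2.4, 19)
        res = independent_mean_diff(x, y, equal_var=equal_var)
        cm = CompareMeans(DescrStatsW(y), DescrStatsW(x))
        usevar = "pooled" if equal_var else "unequal"
        lo, hi = cm.tconfint_diff(alpha=0.05, usevar=usevar)
        assert res.mean_diff_kmh == pytest.approx(y.mean() - x.mean(), abs=1e-12)
        assert res.ci_low == pytest.approx(lo, abs=1e-10)
        assert res.ci_high == pytest.approx(hi, abs=1e-10)


class TestConsecutiveIntervalDiffs:
    def test_eighteen_intervals_in_report_order(self):
        assert len(CONSECUTIVE_PAIRS) == 18
        labels = [p[0] for p in CONSECUTIVE_PAIRS]
        assert labels[0] == "10-9"
        assert labels[8] == "2-1"
        assert labels[9] == "1-2"
        assert labels[-1] == "9-10"

    def test_constant_profiles_give_zero_differences(self):
        profiles = [make_profile(np.full(21, 15.0)) for _ in range(5)]
        diffs = consecutive_interval_diffs(profiles)
        assert len(diffs) == 18
        assert all(d.mean_diff_kmh == 0.0 for d in diffs)

    def test_decomposes_into_paired_mean_diff(self):
        rng = np.random.default_rng(7)
        profiles = [make_profile(rng.uniform(5, 30, 21)) for _ in range(6)]
        diffs = consecutive_interval_diffs(profiles)
        # spot-check the "4-3" interval against a direct column comparison
        a = [p.value(-4) for p in profiles]
        b = [p.value(-3) for p in profiles]
        direct = paired_mean_diff(a, b, pair="4-3")
        d43 = next(d for d in diffs if d.pair == "4-3")
        assert d43 == direct

    def test_missing_offsets_reduce_n(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(5, 30, (4, 21))
        values[0, 20] = np.nan  # offset +10 unavailable in one window
        profiles = [make_profile(v) for v in values]
        diffs = consecutive_interval_diffs(profiles)
        by_pair = {d.pair: d for d in diffs}
        assert by_pair["9-10"].n == 3
        assert by_pair["8-9"].n == 4


class TestPooledPositionMeans:
    def test_equal_means_pool_to_that_mean(self):
        summary = reference_position_summary().copy()
        for pos in ("CD", "FB", "CM", "WM", "FW"):
            summary.loc[-3, (pos, "mean")] = 17.5
        assert pooled_position_means(summary, -3) == pytest.approx(17.5)

    def test_reference_row_minus3(self):
        summary = reference_position_summary()
        assert pooled_position_means(summary, -3) == pytest.approx(20.27, abs=0.005)

    def test_reference_acceleration_peak_interval(self):
        summary = reference_position_summary()
        diff = pooled_position_means(summary, -3) - pooled_position_means(summary, -4)
        assert diff == pytest.approx(4.25, abs=0.005)

    def test_missing_position_is_an_error(self):
        summary = reference_position_summary().drop(columns=["FW"], level=0)
        with pytest.raises(MissingPositionError):
            pooled_position_means(summary, -3)
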