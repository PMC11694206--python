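"""Spike filtering, bout segmentation, peak validation, sprint typing."""



import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sprintwindow import (
    ConfigError,
    FilterConfig,
    SprintWindowError,
    classify_sprint,
    filter_speeds,
    find_match_peak,
    segment_bouts,
)
from sprintwindow.synthetic_data import SimConfig, simulate_trace

from conftest import make_trace


class TestFilterSpeeds:
    def test_implausible_sample_marked_missing(self, filter_cfg):
        trace = make_trace([20.0, 50.0, 22.0])
        res = filter_speeds(trace, filter_cfg)
        assert res.n_removed == 1
        assert np.isnan(res.trace.v_kmh[1])
        np.testing.assert_allclose(res.trace.v_kmh[[0, 2]], [20.0, 22.0])

    def test_plausible_trace_untouched(self, filter_cfg):
        trace = make_trace([10.0, 44.45, 30.0])  # cap itself is retained
        res = filter_speeds(trace, filter_cfg)
        assert res.n_removed == 0
        np.testing.assert_array_equal(res.trace.v_kmh, trace.v_kmh)

    def test_seeded_simulator_spikes_removed_exactly(self, filter_cfg):
        cfg = SimConfig(duration_s=600.0, n_sprints=2, spike_rate_per_trace=5.0)
        for seed in (3, 4, 5):
            trace, truth = simulate_trace(cfg, "CM", seed=seed)
            res = filter_speeds(trace, filter_cfg)
            assert res.removed_indices.tolist() == truth.spike_indices
            assert res.n_removed == len(truth.spike_indices)


class TestSegmentBouts:
    def test_no_sample_reaches_threshold(self):
        assert segment_bouts(make_trace(np.full(50, 10.0)), 25.2) == []

    def test_two_bouts_with_expected_maxima(self):
        trace = make_trace([20, 26, 27, 26, 20, 26, 20])
        bouts = segment_bouts(trace, 25.2)
        assert [(b.start, b.end) for b in bouts] == [(1, 3), (5, 5)]
        assert [b.v_max_kmh for b in bouts] == [27, 26]

    def test_filtered_sample_splits_a_run(self):
        trace = make_trace([26.0, np.nan, 26.5])
        bouts = segment_bouts(trace, 25.2)
        assert [(b.start, b.end) for b in bouts] == [(0, 0), (2, 2)]

    @given(
        speeds=st.lists(
            st.one_of(st.floats(0, 35), st.just(float("nan"))),
            min_size=1, max_size=60,
        ),
        threshold=st.floats(5, 30),
    )
    @settings(deadline=None, derandomize=True, max_examples=300)
    def test_matches_bruteforce_threshold_scan(self, speeds, threshold):
        """Segmentation equals a naive one-pass scan over threshold crossings."""
        trace = make_trace(speeds)
        got = [(b.start, b.end, b.v_max_kmh, b.i_max) for b in segment_bouts(trace, threshold)]
        expected = []
        i, n = 0, len(speeds)
        while i < n:
            if not speeds[i] >= threshold:  # NaN compares False
                i += 1
                continue
            j = i
            while j + 1 < n and speeds[j + 1] >= threshold:
                j += 1
            seg = speeds[i : j + 1]
            vmax = max(seg)
            expected.append((i, j, vmax, i + seg.index(vmax)))
            i = j + 1
        assert got == expected


class TestFindMatchPeak:
    def two_effort_trace(self, v1, v2, filler=10.0):
        """Two well-separated efforts peaking at v1 and v2."""
        ramp = [filler, 18.0, 23.0]
        return make_trace(
            ramp + [v1] + ramp[::-1] + [filler] * 10 + ramp + [v2] + ramp[::-1]
        )

    def test_corroborated_global_maximum_is_the_peak(self, filter_cfg):
        trace = self.two_effort_trace(30.0, 29.5)
        peak = find_match_peak(trace, filter_cfg)
        assert peak.peak_kmh == 30.0
        assert peak.corroborating_kmh == 29.5
        assert peak.candidate_rank == 1

    def test_lone_effort_is_rejected(self, filter_cfg):
        trace = make_trace([10.0, 18.0, 23.0, 30.0, 23.0, 18.0, 10.0])
        assert find_match_peak(trace, filter_cfg) is None

    def test_uncorroborated_maximum_is_demoted(self, filter_cfg):
        # efforts at 30.0, 28.0, 27.5: nothing within 1 km/h of 30.0, but
        # 28.0 is corroborated by 27.5 (>= 27.0)
        ramp = [10.0, 18.0, 23.0]
        sep = [10.0] * 10
        trace = make_trace(
            ramp + [30.0] + ramp[::-1] + sep
            + ramp + [28.0] + ramp[::-1] + sep
            + ramp + [27.5] + ramp[::-1]
        )
        peak = find_match_peak(trace, filter_cfg)
        assert peak.peak_kmh == 28.0
        # both 27.5 and the (uncorroborated) 30.0 effort qualify as
        # witnesses for 28.0; the fastest is reported
        assert peak.corroborating_kmh == 30.0
        assert peak.candidate_rank == 2

    def test_peak_example_margin_rule(self, filter_cfg):
        # a 32.7 km/h peak is valid iff another effort reached >= 31.7
        valid = self.two_effort_trace(32.7, 31.7)
        assert find_match_peak(valid, filter_cfg).peak_kmh == 32.7
        invalid = self.two_effort_trace(32.7, 31.6)
        peak = find_match_peak(invalid, filter_cfg)
        assert peak is None or peak.peak_kmh != 32.7

    def test_never_returns_subthreshold_peak(self, filter_cfg):
        trace = self.two_effort_trace(25.0, 24.8)
        assert find_match_peak(trace, filter_cfg) is None

    def test_returned_peak_bounded_by_global_max(self, filter_cfg):
        rng = np.random.default_rng(0)
        for _ in range(200):
            trace = make_trace(rng.uniform(0, 35, size=rng.integers(5, 50)))
            peak = find_match_peak(trace, filter_cfg)
            if peak is not None:
                assert peak.peak_kmh <= np.nanmax(trace.v_kmh)
                assert peak.peak_kmh > filter_cfg.sprint_threshold_kmh

    def test_corroborated_global_max_is_always_chosen(self, filter_cfg):
        """Whenever the global maximum is corroborated, it is the peak."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            trace = make_trace(rng.uniform(20, 34, size=40))
            peak = find_match_peak(trace, filter_cfg)
            gmax = float(np.nanmax(trace.v_kmh))
            if peak is not None and peak.candidate_rank == 1:
                assert peak.peak_kmh == gmax


class TestClassifySprint:
    def run_case(self, speeds, cfg):
        trace = make_trace(speeds)
        bout = segment_bouts(trace, cfg.sprint_threshold_kmh)[0]
        return classify_sprint(trace, bout, cfg)

    def test_jump_without_hsr_passage_is_explosive(self, filter_cfg):
        assert self.run_case([15.0, 15.0, 15.0, 26.0, 27.0], filter_cfg) == "explosive"

    def test_gradual_ramp_is_leading(self, filter_cfg):
        assert self.run_case([20.0, 22.0, 24.0, 26.0], filter_cfg) == "leading"

    def test_subthreshold_bout_rejected(self, filter_cfg):
        trace = make_trace([20.0, 22.0, 20.0])
        bout = segment_bouts(trace, 19.0)[0]
        with pytest.raises(SprintWindowError):
            classify_sprint(trace, bout, filter_cfg)

    def test_matches_bruteforce_lookback_check(self, filter_cfg):
        """Label equals a naive scan of the 5 samples before threshold crossing."""
        rng = np.random.default_rng(2)
        lo, hi = filter_cfg.hsr_band_kmh
        n_checked = 0
        for _ in range(300):
            speeds = list(rng.uniform(5, 24, size=8)) + list(rng.uniform(25.3, 30, size=3))
            trace = make_trace(speeds)
            bouts = segment_bouts(trace, filter_cfg.sprint_threshold_kmh)
            bout = bouts[0]
            got = classify_sprint(trace, bout, filter_cfg)
            i_first = next(
                i for i in range(bout.start, bout.end + 1)
                if speeds[i] > filter_cfg.sprint_threshold_kmh
            )
            lookback = speeds[max(i_first - 5, 0) : i_first]
            expected = "leading" if any(lo <= v <= hi for v in lookback) else "explosive"
            assert got == expected
            n_checked += 1
        assert n_checked == 300


def test_filter_config_invariants():
    with pytest.raises(ConfigError):
        FilterConfig(v_cap_kmh=20.0)  # cap below sprint threshold
    with pytest.raises(ConfigError):
        FilterConfig(corroboration_margin_kmh=0.0)


def test_filter_config_from_file(tmp_path):
    p = tmp_path / "cfg.txt"
    p.write_text("v_cap_kmh = 40.0\ncorroboration_margin_kmh = 0.5\n")
    cfg = FilterConfig.from_file(p)
    assert cfg.v_cap_kmh == 40.0
    assert cfg.corroboration_margin_kmh == 0.5
    p.write_text('{"sprint_threshold_kmh": 24.0, "bogus": 1}')
    with pytest.raises(ConfigError):
        FilterConfig.from_file(p)
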