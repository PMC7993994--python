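"""Transient detection rule, clearance time, per-cell summaries, t-test."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from catrace import (
    CellMetrics,
    DetectionParams,
    DetectionResult,
    TransientEvent,
    clearance_time,
    compare_groups,
    detect_transients,
    is_transient_frame,
    summarize_cell,
)
from conftest import brute_force_events, make_trace

PAPER_PARAMS = DetectionParams(delta=3, theta=7, gamma=0.25)


def _impulse(n=30, at=10, height=1.0, floor=0.0):
    v = np.full(n, floor)
    v[at] = height
    return make_trace(v)


class TestIsTransientFrame:
    def test_isolated_impulse_qualifies(self):
        # local mean = 1/15, threshold 1.25/15 ~ 0.083 < 1.0
        assert is_transient_frame(_impulse(), 10, PAPER_PARAMS)

    def test_constant_trace_never_qualifies(self):
        tr = make_trace([0.7] * 40)
        assert not any(
            is_transient_frame(tr, n, PAPER_PARAMS) for n in range(7, 33))

    def test_plateau_frames_both_qualify(self):
        # >= tie handling: adjacent equal maxima each pass condition (i)
        v = np.zeros(30)
        v[9] = v[10] = 1.0
        tr = make_trace(v)
        assert is_transient_frame(tr, 9, PAPER_PARAMS)
        assert is_transient_frame(tr, 10, PAPER_PARAMS)

    def test_incomplete_neighbourhood_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            is_transient_frame(_impulse(), 3, PAPER_PARAMS)


class TestDetectTransients:
    def test_monotone_decreasing_has_no_events(self):
        tr = make_trace(np.linspace(2.0, 0.1, 100))
        assert detect_transients(tr, PAPER_PARAMS).events == ()

    def test_plateau_merges_to_single_event_earliest_tie(self):
        v = np.zeros(30)
        v[9] = v[10] = 1.0
        res = detect_transients(make_trace(v), PAPER_PARAMS)
        assert res.peak_frames == [9]

    def test_planted_well_separated_transients_all_found(self):
        spec_frames = [50, 120, 200, 290, 360, 450, 520, 600]
        v = np.full(700, 0.1)
        rng = np.random.default_rng(3)
        v += rng.normal(0, 0.004, 700)  # noise sd far below amplitude
        for p in spec_frames:
            v[p:p + 30] += 0.5 * np.exp(-np.arange(30) * 0.478 / 1.5)
        res = detect_transients(make_trace(v), PAPER_PARAMS)
        assert len(res.events) == len(spec_frames)
        for found, true in zip(res.peak_frames, spec_frames):
            assert abs(found - true) <= PAPER_PARAMS.delta

    def test_matches_bruteforce_oracle_on_random_traces(self, rng):
        for _ in range(200):
            n = int(rng.integers(60, 300))
            v = rng.uniform(0.05, 1.0, n)
            params = DetectionParams(
                delta=int(rng.integers(1, 6)),
                theta=int(rng.integers(3, 11)),
                gamma=float(rng.uniform(0.1, 1.0)),
            )
            tr = make_trace(v)
            expected = brute_force_events(
                v, 0, n - 1, params.delta, params.theta, params.gamma, params.gap)
            assert detect_transients(tr, params).peak_frames == expected

    @given(c=st.floats(1e-2, 1e2))
    def test_scale_invariant_peak_frames(self, c):
        rng = np.random.default_rng(11)
        v = 0.1 + rng.uniform(0, 0.05, 400)
        for p in (60, 180, 300):
            v[p:p + 20] += 0.4 * np.exp(-np.arange(20) * 0.3)
        base_peaks = detect_transients(make_trace(v), PAPER_PARAMS).peak_frames
        assert detect_transients(make_trace(c * v), PAPER_PARAMS).peak_frames == base_peaks

    def test_additive_offset_suppresses_detection(self):
        rng = np.random.default_rng(11)
        v = 0.1 + rng.uniform(0, 0.05, 400)
        for p in (60, 180, 300):
            v[p:p + 20] += 0.4 * np.exp(-np.arange(20) * 0.3)
        with_offset = detect_transients(make_trace(v + 10.0), PAPER_PARAMS)
        without = detect_transients(make_trace(v), PAPER_PARAMS)
        assert len(without.events) >= 3
        assert len(with_offset.events) == 0

    def test_gamma_monotone_qualifying_set_shrinks(self, rng):
        v = rng.uniform(0.05, 1.0, 300)
        tr = make_trace(v)
        qual = {}
        for gamma in (0.1, 0.5, 2.0):
            p = DetectionParams(delta=3, theta=7, gamma=gamma)
            qual[gamma] = {n for n in range(7, 293) if is_transient_frame(tr, n, p)}
        assert qual[2.0] <= qual[0.5] <= qual[0.1]

    def test_trace_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            detect_transients(make_trace([1.0] * 14), PAPER_PARAMS)


class TestClearanceTime:
    def _event(self, peak_frame, peak_value, baseline=0.0):
        return TransientEvent(peak_frame, peak_value, baseline,
                              peak_value - baseline, None)

    @pytest.mark.parametrize("tau", [0.5, 1.0, 1.5, 3.0])
    def test_exponential_decay_gives_tau_ln2(self, tau):
        dt = 0.01
        n = int(10 * tau / dt)
        v = np.exp(-np.arange(n) * dt / tau)
        t_half = clearance_time(make_trace(v, dt=dt), self._event(0, 1.0))
        assert abs(t_half - tau * np.log(2)) <= dt

    def test_linear_decay_gives_half_duration(self):
        dt = 0.478
        n = 101
        v = np.linspace(1.0, 0.0, n)  # decays over D = 100*dt seconds
        t_half = clearance_time(make_trace(v, dt=dt), self._event(0, 1.0))
        assert abs(t_half - 50 * dt) <= dt

    def test_peak_at_window_end_is_missing(self):
        v = np.concatenate([np.zeros(20), [1.0]])
        assert clearance_time(make_trace(v), self._event(20, 1.0)) is None

    def test_truncation_at_next_event_is_missing(self):
        # slow decay interrupted by the next peak before half amplitude
        v = np.concatenate([[1.0], np.full(10, 0.9), [2.0], np.zeros(5)])
        ev = self._event(0, 1.0)
        assert clearance_time(make_trace(v), ev, truncate_frame=11) is None
        assert clearance_time(make_trace(v), ev) is not None  # reaches it later

    def test_interpolates_between_frames(self):
        v = np.array([1.0, 0.25, 0.0, 0.0, 0.0, 0.0, 0.0])
        # level 0.5 crossed 2/3 of the way through the first interval
        t_half = clearance_time(make_trace(v, dt=0.3), self._event(0, 1.0))
        assert t_half == pytest.approx(0.3 * 2 / 3)


class TestSummarizeCell:
    def test_constant_trace_zero_events(self):
        tr = make_trace([0.3] * 200, window=(0, 199))
        m = summarize_cell(detect_transients(tr, PAPER_PARAMS), tr)
        assert (m.n_transients, m.firing_rate_per_min) == (0, 0.0)
        assert m.clearance_time_s is None and m.amplitude is None
        assert m.mean_signal == pytest.approx(0.3)

    def test_means_over_events(self):
        tr = make_trace([0.1] * 100, window=(0, 99))
        events = (
            TransientEvent(20, 0.3, 0.1, 0.2, 1.0),
            TransientEvent(60, 0.5, 0.1, 0.4, 2.0),
        )
        res = DetectionResult("c0", events, PAPER_PARAMS, (0, 99))
        m = summarize_cell(res, tr)
        assert m.clearance_time_s == pytest.approx(1.5)
        assert m.amplitude == pytest.approx(0.3)
        assert m.firing_rate_per_min == pytest.approx(2 / (100 * 0.478 / 60))

    def test_undefined_half_decays_excluded_from_mean(self):
        tr = make_trace([0.1] * 100, window=(0, 99))
        events = (
            TransientEvent(20, 0.3, 0.1, 0.2, 1.0),
            TransientEvent(60, 0.5, 0.1, 0.4, None),
        )
        m = summarize_cell(DetectionResult("c0", events, PAPER_PARAMS, (0, 99)), tr)
        assert m.clearance_time_s == pytest.approx(1.0)
        assert m.n_transients == 2

    def test_cell_id_mismatch_rejected(self):
        tr = make_trace([0.1] * 100)
        res = DetectionResult("other", (), PAPER_PARAMS, (0, 99))
        with pytest.raises(ValueError, match="mismatch"):
            summarize_cell(res, tr)


def _cells(values, field="clearance_time_s"):
    out = []
    for i, v in enumerate(values):
        kw = dict(cell_id=f"c{i}", n_transients=1, firing_rate_per_min=0.1,
                  clearance_time_s=1.0, amplitude=0.3, mean_signal=0.2)
        kw[field] = v
        out.append(CellMetrics(**kw))
    return out


class TestCompareGroups:
    def test_identical_groups_give_t0_p1(self):
        g = _cells([1.0, 2.0, 3.0, 4.0])
        c = compare_groups(g, _cells([1.0, 2.0, 3.0, 4.0]), "clearance_time_s")
        assert c.statistic == pytest.approx(0.0)
        assert c.p_value == pytest.approx(1.0)

    def test_separated_groups_give_tiny_p(self, rng):
        a = _cells(rng.normal(0.0, 1e-6, 4))
        b = _cells(1.0 + rng.normal(0.0, 1e-6, 4))
        assert compare_groups(a, b, "clearance_time_s").p_value < 1e-6

    def test_missing_values_excluded_and_counted(self):
        a = _cells([1.0, 2.0, None, 3.0])
        b = _cells([1.5, 2.5, 3.5])
        c = compare_groups(a, b, "clearance_time_s")
        assert (c.n_a, c.n_missing_a, c.n_b, c.n_missing_b) == (3, 1, 3, 0)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match="non-missing"):
            compare_groups(_cells([1.0, None]), _cells([1.0, 2.0]), "clearance_time_s")
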