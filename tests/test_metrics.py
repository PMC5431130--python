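"""Peak calling, damping, fold increase and the per-cell panel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfkbdyn.io import RatioTrace
from nfkbdyn.metrics import (
    NoiseModel,
    Peak,
    compute_damping,
    compute_fold_increase,
    detect_peaks,
    estimate_noise_level,
    metrics_table,
    summarize_cell,
)
from nfkbdyn.params import PulseTrainParams
from nfkbdyn.simulate import simulate_nfkb_trace
from nfkbdyn.traces import smooth_trace


def trace_of(values, dt=3.0, cell_id=1):
    v = np.asarray(values, dtype=float)
    return RatioTrace(cell_id, "nfkb_nuc_cyt", np.arange(v.size) * dt, v)


def brute_force_peaks(values, level, min_sep):
    """Independent oracle: exhaustive scan for thresholded local maxima.

    A plateau's leftmost index stands for the plateau; endpoints count.
    Maxima closer than ``min_sep`` are merged left to right keeping the
    higher one, ties resolved toward the earlier index.
    """
    v = list(values)
    n = len(v)
    runs = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        runs.append((i, j))
        i = j + 1
    maxima = []
    for a, b in runs:
        lower_left = a == 0 or v[a - 1] < v[a]
        lower_right = b == n - 1 or v[b + 1] < v[b]
        if lower_left and lower_right and v[a] > level:
            maxima.append(a)
    surviving = []
    for idx in maxima:
        merged = False
        while surviving and idx - surviving[-1] < min_sep:
            if v[idx] > v[surviving[-1]]:
                surviving.pop()
            else:
                merged = True
                break
        if not merged:
            surviving.append(idx)
    return surviving


class TestNoiseModel:
    def test_constant_curves_give_zero_threshold(self):
        curves = [trace_of(np.full(30, 0.7)), trace_of(np.full(30, 0.9))]
        noise = estimate_noise_level(curves)
        assert noise.threshold == 0.0
        assert noise.n_source == 2

    def test_square_wave_threshold_is_amplitude(self):
        # symmetric +-0.1 square wave: every |deviation from median| is 0.1
        v = 1.0 + 0.1 * np.tile([1.0, -1.0], 20)
        noise = estimate_noise_level([trace_of(v)])
        assert noise.threshold == pytest.approx(0.1)

    def test_single_curve_is_valid_input(self):
        noise = estimate_noise_level([trace_of([1.0, 1.2, 0.8, 1.0])])
        assert noise.n_source == 1
        assert noise.threshold >= 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_level([])

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(threshold=-0.1)


class TestDetectPeaks:
    def test_constant_curve_has_no_peaks(self):
        assert detect_peaks(trace_of(np.full(40, 0.8)), NoiseModel(0.05)) == []

    def test_three_pulses_called_at_true_times(self):
        params = PulseTrainParams(
            first_peak_time_mean=30.0, first_peak_time_sd=0.0,
            interval_mean=90.0, interval_sd=0.0, n_pulses=3,
            first_peak_amplitude=1.3, damping_factor=0.5, pulse_width_sd=8.0,
        )
        raw, pulses = simulate_nfkb_trace(params, 120, 3.0, seed=0)
        smooth = smooth_trace(raw, 10)
        peaks = detect_peaks(smooth, NoiseModel(0.05))
        assert len(peaks) == 3
        for p, (tau, _) in zip(peaks, pulses):
            assert abs(p.peak_time - tau) <= 6.0
        assert [p.index for p in peaks] == [1, 2, 3]

    def test_initiation_time_linear_interpolation(self):
        # hand-built: baseline 0 (median), threshold 0.5; values cross the
        # level between frames 1 and 2 -> crossing at t = 3 + 0.5/1.0 * 3
        v = [0.0, 0.0, 1.0, 2.0, 1.0, 0.0, 0.0, 0.0, 0.0]
        peaks = detect_peaks(trace_of(v), NoiseModel(0.5), min_separation_frames=2)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.peak_time == 9.0
        assert p.initiation_time == pytest.approx(3.0 + 0.5 * 3.0)
        assert p.duration == pytest.approx(p.peak_time - p.initiation_time)

    def test_curve_starting_above_level_initiates_at_first_frame(self):
        v = [2.0, 3.0, 1.0, 0.0, 0.0, 0.0, 0.0]
        peaks = detect_peaks(trace_of(v), NoiseModel(0.5), min_separation_frames=2)
        assert peaks[0].initiation_time == 0.0

    def test_merge_keeps_higher_tie_earlier(self):
        v = [0.0, 2.0, 0.5, 2.0, 0.0, 0.0, 0.0, 0.0, 2.5, 0.0]
        peaks = detect_peaks(trace_of(v), NoiseModel(0.4), min_separation_frames=4)
        # maxima at 1 and 3 tie -> earlier (1) survives; 8 is separate
        assert [p.peak_time for p in peaks] == [3.0, 24.0]
        assert peaks[0].height == 2.0 and peaks[1].height == 2.5

    @given(
        values=st.lists(
            st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0]),
            min_size=1, max_size=40,
        ),
        threshold=st.sampled_from([0.0, 0.1, 0.4, 0.8]),
        min_sep=st.integers(1, 8),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, values, threshold, min_sep):
        curve = trace_of(values)
        peaks = detect_peaks(curve, NoiseModel(threshold), min_sep)
        level = float(np.median(values)) + threshold
        expected = brute_force_peaks(values, level, min_sep)
        assert [int(p.peak_time / 3.0) for p in peaks] == expected

    @given(
        values=st.lists(st.floats(0.0, 3.0), min_size=2, max_size=40),
        thresholds=st.tuples(st.floats(0.0, 1.0), st.floats(0.0, 1.0)),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_raising_threshold_never_adds_peaks(self, values, thresholds):
        lo, hi = sorted(thresholds)
        curve = trace_of(values)
        n_lo = len(detect_peaks(curve, NoiseModel(lo)))
        n_hi = len(detect_peaks(curve, NoiseModel(hi)))
        assert n_hi <= n_lo

    @given(values=st.lists(st.floats(0.0, 3.0), min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_duration_identity(self, values):
        for p in detect_peaks(trace_of(values), NoiseModel(0.2)):
            assert p.duration == p.peak_time - p.initiation_time
            assert p.initiation_time <= p.peak_time


class TestDamping:
    def test_halving_heights(self):
        peaks = [
            Peak(i + 1, 0.0, 10.0 * i, h, 10.0 * i)
            for i, h in enumerate([2.0, 1.0, 0.5])
        ]
        assert compute_damping(peaks) == pytest.approx([0.5, 0.5])

    def test_equal_heights_zero_rate(self):
        peaks = [Peak(1, 0.0, 0.0, 1.5, 0.0), Peak(2, 0.0, 90.0, 1.5, 0.0)]
        assert compute_damping(peaks) == [0.0]

    def test_growing_peak_negative_rate(self):
        peaks = [Peak(1, 0.0, 0.0, 1.0, 0.0), Peak(2, 0.0, 90.0, 1.2, 0.0)]
        assert compute_damping(peaks) == pytest.approx([-0.2])

    def test_fewer_than_two_peaks_undefined(self):
        assert compute_damping([]) == []
        assert compute_damping([Peak(1, 0.0, 0.0, 1.0, 0.0)]) == []

    def test_absolute_mode(self):
        peaks = [Peak(1, 0.0, 0.0, 2.0, 0.0), Peak(2, 0.0, 90.0, 0.5, 0.0)]
        assert compute_damping(peaks, mode="absolute") == pytest.approx([1.5])


class TestFoldIncrease:
    def test_constant_trace_is_one_fold(self):
        tr = RatioTrace(1, "mcherry_cell_bg", np.arange(30) * 3.0, np.full(30, 1.3))
        assert compute_fold_increase(tr) == pytest.approx(1.0)

    def test_known_profile_fold(self):
        from nfkbdyn.params import ReporterParams
        from nfkbdyn.simulate import simulate_mcherry_profile

        tr = simulate_mcherry_profile(ReporterParams(fold=2.1), 200, 3.0)
        assert compute_fold_increase(tr) == pytest.approx(2.1, rel=0.01)

    def test_short_trace_rejected(self):
        tr = RatioTrace(1, "mcherry_cell_bg", np.arange(5) * 3.0, np.ones(5))
        with pytest.raises(ValueError):
            compute_fold_increase(tr, baseline_frames=10)


class TestSummarizeCell:
    def test_flat_cell_zero_peaks_unit_fold(self):
        nfkb = trace_of(np.full(60, 0.7))
        mch = RatioTrace(1, "mcherry_cell_bg", np.arange(60) * 3.0, np.ones(60))
        m = summarize_cell(nfkb, mch, NoiseModel(0.05), genotype="DKO")
        assert m.n_peaks == 0
        assert m.intervals == [] and m.damping_rates == []
        assert m.mcherry_fold_increase == pytest.approx(1.0)

    def test_intervals_match_ninety_minute_spacing(self):
        params = PulseTrainParams(
            first_peak_time_mean=9.0, first_peak_time_sd=0.0,
            interval_mean=90.0, interval_sd=0.0, n_pulses=3,
        )
        raw, pulses = simulate_nfkb_trace(params, 120, 3.0, seed=0)
        m = summarize_cell(smooth_trace(raw), None, NoiseModel(0.05))
        assert m.n_peaks == 3
        # the first pulse peaks within half a smoothing window of t = 0,
        # so its called time carries the edge-truncation bias of the
        # ten-frame average; later peaks are clean
        assert m.intervals == pytest.approx([90.0, 90.0], abs=15.0)
        assert m.intervals[1] == pytest.approx(90.0, abs=6.0)

    def test_single_peak_no_intervals_or_damping(self):
        params = PulseTrainParams(n_pulses=1, first_peak_time_mean=60.0,
                                  first_peak_time_sd=0.0)
        raw, _ = simulate_nfkb_trace(params, 80, 3.0, seed=0)
        m = summarize_cell(smooth_trace(raw), None, NoiseModel(0.05))
        assert m.n_peaks == 1
        assert m.intervals == [] and m.damping_rates == []

    def test_mismatched_cell_ids_rejected(self):
        nfkb = trace_of(np.full(30, 0.7), cell_id=1)
        mch = RatioTrace(2, "mcherry_cell_bg", np.arange(30) * 3.0, np.ones(30))
        with pytest.raises(ValueError, match="different cells"):
            summarize_cell(nfkb, mch, NoiseModel(0.1))

    def test_metrics_table_layout(self):
        params = PulseTrainParams(n_pulses=2, first_peak_time_sd=0.0,
                                  interval_sd=0.0)
        raw, _ = simulate_nfkb_trace(params, 80, 3.0, seed=0)
        m = summarize_cell(smooth_trace(raw), None, NoiseModel(0.05), genotype="WT")
        df = metrics_table([m])
        assert df.loc[0, "n_peaks"] == 2
        assert df.loc[0, "genotype"] == "WT"
        assert np.isnan(df.loc[0, "t_peak_3"])
        assert np.isnan(df.loc[0, "fold"])
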