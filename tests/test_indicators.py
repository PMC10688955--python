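"""Signal conditioning, SCR detection, windowed indicators, transforms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riskbn import (
    SCREvent,
    SignalTrace,
    TransformSpec,
    TrialWindow,
    apply_transforms,
    compute_isa,
    compute_msa,
    count_and_max_scr,
    detect_scrs,
    preprocess_eda,
    simulate_scr_events,
)
from riskbn.indicators import IndicatorTransformer


def _trace(values, rate=100.0, t0=0.0):
    v = np.asarray(values, dtype=float)
    return SignalTrace(t=t0 + np.arange(v.size) / rate, v=v, rate=rate)


class TestPreprocess:
    def test_constant_trace_passes_through(self):
        tr = preprocess_eda(_trace(np.full(1000, 3.7)))
        interior = tr.v[50:-50]
        np.testing.assert_allclose(interior, 3.7, atol=1e-9)
        assert tr.rate == 50.0

    def test_ten_hz_ripple_attenuated_tenfold(self):
        t = np.arange(2000) / 100.0
        tr = preprocess_eda(_trace(5.0 + 0.5 * np.sin(2 * np.pi * 10.0 * t)))
        interior = tr.v[100:-100]
        residual = np.max(np.abs(interior - 5.0))
        assert residual < 0.5 / 10.0

    def test_single_sample_spike_removed_by_moving_median(self):
        v = np.full(1000, 1.0)
        v[500] = 9.0
        tr = preprocess_eda(_trace(v))
        assert np.max(np.abs(tr.v[100:-100] - 1.0)) < 0.01

    def test_short_or_slow_traces_rejected(self):
        with pytest.raises(ValueError):
            preprocess_eda(_trace(np.ones(50)))  # 0.5 s
        with pytest.raises(ValueError):
            preprocess_eda(_trace(np.ones(100), rate=20.0))  # below 50 Hz


def _bump(center_idx, height, width, n, base=0.0):
    v = np.full(n, base)
    idx = np.arange(n)
    mask = np.abs(idx - center_idx) < width
    v[mask] += height * np.cos(np.pi * (idx[mask] - center_idx) / (2 * width)) ** 2
    return v


class TestDetectScrs:
    def test_flat_trace_yields_nothing(self):
        assert detect_scrs(_trace(np.zeros(500))) == []

    def test_single_bump_amplitude_and_onset(self):
        tr = _trace(_bump(250, 0.10, 60, 500))
        events = detect_scrs(tr, amplitude_threshold=0.05)
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(0.10, rel=1e-6)
        assert events[0].onset < 2.5  # trough precedes the peak

    def test_subthreshold_bump_ignored(self):
        v = _bump(150, 0.10, 40, 600) + _bump(450, 0.02, 40, 600)
        events = detect_scrs(_trace(v), amplitude_threshold=0.05)
        assert len(events) == 1

    def test_two_bumps_two_events_sorted(self):
        v = _bump(150, 0.2, 40, 600) + _bump(450, 0.3, 40, 600)
        events = detect_scrs(_trace(v), amplitude_threshold=0.05)
        assert len(events) == 2
        assert events[0].onset < events[1].onset


class TestSubjectiveIndicators:
    def test_constant_rectangle_area(self):
        tr = _trace(np.ones(301), rate=20.0)  # 15 s of 1.0
        assert compute_isa(tr, TrialWindow(2.0, 12.0)) == pytest.approx(10.0)

    def test_zero_trace_zero_area(self):
        tr = _trace(np.zeros(301), rate=20.0)
        assert compute_isa(tr, TrialWindow(0.0, 10.0)) == pytest.approx(0.0)

    def test_triangle_closed_form(self):
        # rises 0 -> 1 over 5 s then back: area 5, max 1
        t = np.arange(301) / 20.0
        v = np.clip(1.0 - np.abs(t - 5.0) / 5.0, 0.0, None)
        tr = SignalTrace(t=t, v=v, rate=20.0)
        win = TrialWindow(0.0, 10.0)
        assert compute_isa(tr, win) == pytest.approx(5.0, rel=1e-12)
        assert compute_msa(tr, win) == pytest.approx(1.0)

    def test_msa_ignores_peaks_outside_the_window(self):
        t = np.arange(301) / 20.0
        v = np.where(t < 2.0, 0.9, 0.0) + np.where((t > 5) & (t < 7), 0.4, 0.0)
        tr = SignalTrace(t=t, v=v, rate=20.0)
        assert compute_msa(tr, TrialWindow(3.0, 10.0)) == pytest.approx(0.4)

    def test_disjoint_window_rejected(self):
        tr = _trace(np.ones(100), rate=20.0)
        with pytest.raises(ValueError):
            compute_isa(tr, TrialWindow(50.0, 60.0))


class TestScrIndicators:
    def test_empty_window(self):
        assert count_and_max_scr([], TrialWindow(0, 10)) == (0, 0.0)

    def test_four_events_counted_with_max(self):
        evs = [SCREvent(1.0, 0.1), SCREvent(2.0, 0.4), SCREvent(3.0, 0.2),
               SCREvent(4.0, 0.05), SCREvent(20.0, 9.0)]
        n, m = count_and_max_scr(evs, TrialWindow(0.0, 13.0))
        assert (n, m) == (4, 0.4)

    def test_boundary_event_at_pass_plus_three_included(self):
        evs = [SCREvent(13.0, 0.2)]
        assert count_and_max_scr(evs, TrialWindow(4.0, 13.0)) == (1, 0.2)

    def test_zero_count_iff_zero_amplitude(self, rng):
        for _ in range(200):
            evs = [
                SCREvent(float(o), float(a))
                for o, a in zip(rng.uniform(0, 30, rng.integers(0, 6)),
                                rng.uniform(0.01, 2.0, 6))
            ]
            win = TrialWindow(*np.sort(rng.uniform(0, 30, 2) + [0.0, 1.0]))
            n, m = count_and_max_scr(sorted(evs, key=lambda e: e.onset), win)
            assert (n == 0) == (m == 0.0)

    def test_windowed_count_matches_simulator(self, dynamics_gt):
        from riskbn import TrialTiming

        timing = TrialTiming()
        win = TrialWindow(*timing.window)
        for seed in range(20):
            evs = simulate_scr_events(1.0, dynamics_gt, timing, seed=seed)
            n, _ = count_and_max_scr(evs, win)
            assert n == len(evs)  # the simulator plants only in-window events


class TestTransforms:
    def test_per_participant_standardisation(self, fullscale_table):
        out = apply_transforms(fullscale_table)
        keep = out[~out.is_collision]
        stats_ = keep.groupby("participant_id").iSA.agg(["mean", "std"])
        np.testing.assert_allclose(stats_["mean"], 0.0, atol=1e-10)
        np.testing.assert_allclose(stats_["std"], 1.0, atol=1e-10)

    def test_scr_scaling_is_ratio_invariant(self, fullscale_table):
        base = apply_transforms(fullscale_table)
        rescaled = fullscale_table.copy()
        first = rescaled.participant_id == "P01"
        rescaled.loc[first, "nSCR"] *= 7.3
        out = apply_transforms(rescaled)
        np.testing.assert_allclose(out.nSCR, base.nSCR, rtol=1e-12)
        assert (out.nSCR >= 0).all()
        # exact zeros survive scaling
        assert ((fullscale_table.nSCR == 0) == (out.nSCR == 0)).all()

    def test_square_root_reduces_right_skew(self, fullscale_table):
        keep = fullscale_table[~fullscale_table.is_collision]
        spec = TransformSpec(standardize=False, scr_scale=False)
        out = apply_transforms(keep, spec=spec)
        assert stats.skew(out.iSA) < stats.skew(keep.iSA)

    def test_zero_variance_participant_warns_not_fails(self):
        t = pd.DataFrame({
            "participant_id": ["a"] * 4 + ["b"] * 4,
            "is_collision": [False] * 8,
            "iSA": [4.0] * 4 + [1.0, 2.0, 3.0, 4.0],
            "nSCR": [0.0, 1.0, 2.0, 1.0] * 2,
        })
        with pytest.warns(UserWarning, match="zero variance"):
            out = apply_transforms(t)
        assert np.allclose(out.iSA[:4], 0.0)

    def test_too_few_trials_rejected(self):
        t = pd.DataFrame({"participant_id": ["a"], "is_collision": [False],
                          "iSA": [1.0], "nSCR": [0.0]})
        with pytest.raises(ValueError):
            apply_transforms(t)

    def test_transformer_wrapper_matches_function(self, fullscale_table):
        a = IndicatorTransformer().fit_transform(fullscale_table)
        b = apply_transforms(fullscale_table)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            TransformSpec(isa_power=1.5)
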