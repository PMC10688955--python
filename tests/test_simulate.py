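"""Synthetic-data generator: planted effects, determinism, event laws."""

import numpy as np
import pandas as pd
import pytest

from riskbn import (
    GroundTruth,
    TrialTiming,
    default_ground_truth,
    sample_compound_poisson_gamma,
    simulate_indicator_pairs,
    simulate_indicator_table,
    simulate_sa_trace,
    simulate_scr_events,
    simulate_trace_tables,
    zero_probability,
)


class TestGroundTruth:
    def test_default_dynamics_plants_the_reported_contrasts(self, dynamics_gt):
        cm = dynamics_gt.sa_cell_means
        c15 = cm[("1.5 m", "First")] - cm[("1.5 m", "Second")]
        c25 = cm[("2.5 m", "First")] - cm[("2.5 m", "Second")]
        assert c15 == pytest.approx(0.98)
        assert c25 == pytest.approx(0.72)
        assert dynamics_gt.scr_slope == 0.14

    def test_default_maxima_orientation_modulates_order(self, maxima_gt):
        cm = maxima_gt.sa_cell_means
        for margin in ("1.5 m", "2.5 m"):
            back = cm[(margin, "First", "Back")] - cm[(margin, "Second", "Back")]
            face = cm[(margin, "First", "Face")] - cm[(margin, "Second", "Face")]
            assert back == pytest.approx(1.0)
            assert face == pytest.approx(0.23)
        assert maxima_gt.scr_slope == 0.2

    def test_standardised_scale_self_consistency(self, dynamics_gt):
        # cell variance + residual variance = 1 on the standardised scale
        total = dynamics_gt.cell_variance + dynamics_gt.sa_sd_effective**2
        assert total == pytest.approx(1.0)

    def test_yaml_round_trip(self, tmp_path, maxima_gt):
        path = tmp_path / "truth.yaml"
        maxima_gt.to_yaml(path)
        back = GroundTruth.from_yaml(path)
        assert back == maxima_gt

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth("dynamics", ("Margin",), {("1.5 m",): 0.0},
                        scr_slope=0.1, scr_p=2.5)
        with pytest.raises(ValueError):
            default_ground_truth("nonsense")


class TestIndicatorTable:
    def test_fullscale_dimensions(self, fullscale_table):
        t = fullscale_table
        assert t.participant_id.nunique() == 27
        assert len(t) == 27 * 36
        assert (~t.is_collision).sum() == 27 * 32  # 864 modelling records
        assert {"iSA", "nSCR"} <= set(t.columns)
        assert (t.iSA >= 0).all() and (t.nSCR >= 0).all()

    def test_deterministic_given_seed(self, design, dynamics_gt):
        a = simulate_indicator_table(design, 3, dynamics_gt, seed=5)
        b = simulate_indicator_table(design, 3, dynamics_gt, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_noiseless_limit_recovers_planted_cell_means(self, design):
        gt = default_ground_truth("dynamics")
        gt.sa_sd = 1e-9
        gt.participant_sd = 0.0
        t = simulate_indicator_table(design, 2, gt, seed=0, collisions=False)
        transformed = np.sqrt(t.iSA) - gt.sa_shift
        means = transformed.groupby(
            [t.Margin, t.Order]
        ).mean()
        for (margin, order), m in means.items():
            assert m == pytest.approx(gt.sa_cell_means[(margin, order)], abs=1e-6)

    def test_zero_slope_decouples_the_indicators(self, maxima_gt):
        gt = default_ground_truth("maxima")
        gt.scr_slope = 0.0
        pairs = simulate_indicator_pairs(gt, 10_000, seed=8)
        corr = np.corrcoef(pairs.mSA, pairs.mSCR)[0, 1]
        assert abs(corr) < 0.04  # ~4 sampling SEs of zero

    def test_planted_order_contrast_recovered(self, fullscale_transformed):
        keep = fullscale_transformed[~fullscale_transformed.is_collision]
        cells = keep.groupby(["Margin", "Order"]).iSA.mean()
        contrast = cells[("1.5 m", "First")] - cells[("1.5 m", "Second")]
        se = np.sqrt(2 / (27 * 8))  # unit-variance cells of n=216
        assert abs(contrast - 0.98) < 3 * se

    def test_needs_two_participants(self, design, dynamics_gt):
        with pytest.raises(ValueError):
            simulate_indicator_table(design, 1, dynamics_gt, seed=0)


class TestSampler:
    def test_rejects_empty_sample(self):
        with pytest.raises(ValueError):
            sample_compound_poisson_gamma(1.0, 1.0, 1.5, n=0, seed=0)

    def test_mean_matches_mu(self):
        y = sample_compound_poisson_gamma(1.0, 1.0, 1.5, n=100_000, seed=3)
        assert abs(y.mean() - 1.0) < 3 * y.std() / np.sqrt(y.size)


class TestTraces:
    def test_bounded_supported_and_deterministic(self, dynamics_gt):
        gt = default_ground_truth("dynamics")
        gt.trace_noise = 0.0
        timing = TrialTiming()
        tr = simulate_sa_trace(0.5, gt, participant_offset=0.0,
                               trial_timing=timing, seed=1)
        tr2 = simulate_sa_trace(0.5, gt, participant_offset=0.0,
                                trial_timing=timing, seed=99)
        np.testing.assert_array_equal(tr.v, tr2.v)  # no randomness left
        assert tr.v.min() >= 0.0 and tr.v.max() <= 1.0
        # zero outside the interaction window
        outside = (tr.t < timing.cross_start) | (tr.t > timing.duration - 3.0)
        assert np.all(tr.v[(tr.t < 2.0)] == 0.0)
        assert tr.v[np.argmin(np.abs(tr.t - timing.pass_time))] == tr.v.max()

    def test_peak_monotone_in_planted_mean(self, dynamics_gt):
        lo_cell = min(dynamics_gt.sa_cell_means.values())
        hi_cell = max(dynamics_gt.sa_cell_means.values())
        for seed in range(5):
            lo = simulate_sa_trace(lo_cell, dynamics_gt, seed=seed)
            hi = simulate_sa_trace(hi_cell, dynamics_gt, seed=seed)
            assert lo.v.max() < hi.v.max()


class TestEvents:
    def test_onsets_inside_the_closed_window(self, dynamics_gt):
        timing = TrialTiming()
        lo, hi = timing.window
        for seed in range(10):
            for ev in simulate_scr_events(2.0, dynamics_gt,
                                          trial_timing=timing, seed=seed):
                assert lo <= ev.onset <= hi
                assert ev.amplitude > 0

    def test_vanishing_rate_gives_empty_lists(self, dynamics_gt):
        gt = default_ground_truth("dynamics")
        gt.scr_intercept, gt.scr_slope = -20.0, 0.0
        events = [simulate_scr_events(0.0, gt, seed=s) for s in range(50)]
        assert all(len(e) == 0 for e in events)

    def test_zero_response_fraction_matches_the_closed_form(self, dynamics_gt):
        """Windowed no-response probability equals the Tweedie zero mass."""
        z = 0.4
        mu = np.exp(dynamics_gt.scr_intercept + dynamics_gt.scr_slope * z)
        p0 = zero_probability(mu, dynamics_gt.scr_phi, dynamics_gt.scr_p)
        n = 4000
        empty = sum(
            len(simulate_scr_events(z, dynamics_gt, seed=s)) == 0
            for s in range(n)
        )
        se = np.sqrt(p0 * (1 - p0) / n)
        assert abs(empty / n - p0) < 3 * se


class TestTraceTables:
    def test_long_format_and_stream_independence(self, design, dynamics_gt):
        plan, traces, events = simulate_trace_tables(design, 2, dynamics_gt, seed=4)
        assert len(plan) == 72
        assert set(traces.columns) == {"participant_id", "rank", "t", "value"}
        assert traces.groupby(["participant_id", "rank"]).ngroups == 72
        assert ((traces.value >= 0) & (traces.value <= 1)).all()
        if len(events):
            assert (events.amplitude > 0).all()
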