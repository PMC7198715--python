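"""Transient detection, half-max segmentation and per-event metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_half_max_split, random_piecewise_linear_region
from microca.events import (
    detect_events,
    fraction_active_per_mouse,
    match_events,
    measure_event,
    split_by_half_max,
    summarize_cell,
)
from microca.synth import TraceGenParams, simulate_trace
from microca.traces import FluorescenceTrace, process_trace


def make_trace(dff, dt=0.1, noise_sd=0.01):
    """A trace with a prescribed filtered ΔF/F, bypassing processing."""
    dff = np.asarray(dff, dtype=float)
    t = np.arange(len(dff)) * dt
    tr = FluorescenceTrace(
        t_s=t, f_raw=100 * (1 + dff), f_background=np.zeros_like(dff), dt_s=dt
    )
    tr.dff = dff
    tr.dff_filtered = dff
    tr.f0 = 100.0
    tr.noise_sd = noise_sd
    tr.noise_sd_raw = noise_sd
    return tr


def two_peak_segment(trough_frac, peak=1.0, n=41):
    up = np.linspace(0, peak, n)
    down = np.linspace(peak, trough_frac * peak, n)[1:]
    up2 = np.linspace(trough_frac * peak, peak, n)[1:]
    down2 = np.linspace(peak, 0, n)[1:]
    return np.concatenate([up, down, up2, down2])


class TestSplitByHalfMax:
    def test_monotone_rise_then_decay_is_single_event(self):
        seg = np.concatenate([np.linspace(0, 1, 20), np.linspace(1, 0, 20)[1:]])
        assert split_by_half_max(seg, 0.1) == [(0, len(seg) - 1)]

    def test_trough_below_half_splits_two_peaks(self):
        seg = two_peak_segment(0.4)
        bounds = split_by_half_max(seg, 0.1)
        assert len(bounds) == 2
        # boundary at the trough minimum
        assert seg[bounds[0][1]] == pytest.approx(0.4)

    def test_trough_above_half_keeps_one_event(self):
        seg = two_peak_segment(0.6)
        assert len(split_by_half_max(seg, 0.1)) == 1

    def test_three_separated_peaks_split_at_minima(self):
        parts = []
        for _ in range(3):
            parts += [np.linspace(0.1, 1, 15), np.linspace(1, 0.1, 15)[1:-1]]
        seg = np.concatenate(parts + [np.array([0.1])])
        bounds = split_by_half_max(seg, 0.2)
        assert len(bounds) == 3
        for _, e in bounds[:-1]:
            assert seg[e] == pytest.approx(0.1)

    def test_small_rise_after_decay_does_not_split(self):
        # falls below half, then re-rises by less than the guard
        seg = np.concatenate(
            [np.linspace(0, 1, 20), np.linspace(1, 0.2, 20)[1:],
             np.linspace(0.2, 0.45, 10)[1:], np.linspace(0.45, 0.05, 10)[1:]]
        )
        assert len(split_by_half_max(seg, rise_delta=0.5)) == 1
        assert len(split_by_half_max(seg, rise_delta=0.2)) == 2

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            split_by_half_max(np.array([]), 0.1)

    def test_matches_brute_force_oracle_on_random_regions(self, rng):
        for _ in range(300):
            seg = random_piecewise_linear_region(rng)
            delta = float(rng.uniform(0.05, 3.0))
            assert split_by_half_max(seg, delta) == brute_force_half_max_split(
                seg, delta
            )

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=60)
    def test_oracle_agreement_property(self, seed):
        rng = np.random.default_rng(seed)
        seg = random_piecewise_linear_region(rng)
        delta = float(rng.uniform(0.05, 3.0))
        assert split_by_half_max(seg, delta) == brute_force_half_max_split(seg, delta)


class TestMeasureEvent:
    def test_exponential_decay_closed_forms(self):
        tau, amp, dt = 10.0, 0.2, 0.1
        t = np.arange(0, 80, dt)
        tr = make_trace(amp * np.exp(-t / tau), dt=dt)
        a, th, auc = measure_event(tr, 0, len(t) - 1)
        assert a == pytest.approx(20.0)
        assert th == pytest.approx(tau * np.log(2), rel=0.02)
        assert auc == pytest.approx(amp * tau, rel=0.02)

    def test_triangular_pulse_geometry(self):
        dt = 0.1
        up = np.linspace(0, 0.1, int(10 / dt) + 1)
        down = np.linspace(0.1, 0, int(10 / dt) + 1)[1:]
        tr = make_trace(np.concatenate([up, down]), dt=dt)
        a, th, auc = measure_event(tr, 0, tr.n_samples - 1)
        assert a == pytest.approx(10.0)
        assert th == pytest.approx(10.0, rel=0.01)
        assert auc == pytest.approx(1.0, rel=0.01)

    def test_single_sample_event_rejected(self):
        tr = make_trace(np.array([0.0, 0.5, 0.0]))
        with pytest.raises(ValueError, match="degenerate"):
            measure_event(tr, 1, 1)

    def test_noisy_event_metrics_within_ten_percent(self):
        # isolated events at SNR 10: median relative error < 10% for all three
        errs = {"amp": [], "th": [], "auc": []}
        for seed in range(80):
            tr, truth = simulate_trace(
                TraceGenParams(event_rate_per_min=0.1, seed=seed)
            )
            process_trace(tr)
            tru = truth.events
            for ev in detect_events(tr):
                if len(tru) == 0:
                    continue
                j = int(np.argmin(np.abs(tru["onset_s"].to_numpy() - ev.onset_s)))
                if abs(tru["onset_s"].iloc[j] - ev.onset_s) > 2:
                    continue
                errs["amp"].append(ev.amplitude_pct / tru["amplitude_pct"].iloc[j] - 1)
                errs["th"].append(ev.t_half_s / tru["t_half_s"].iloc[j] - 1)
                errs["auc"].append(ev.auc / tru["auc"].iloc[j] - 1)
        assert len(errs["amp"]) > 100
        for key, vals in errs.items():
            assert np.median(np.abs(vals)) < 0.10, key


class TestDetectEvents:
    def test_flat_trace_yields_no_events(self):
        tr = make_trace(np.zeros(500), noise_sd=0.0)
        assert detect_events(tr) == []

    def test_single_suprathreshold_transient(self):
        t = np.arange(0, 100, 0.5)
        dff = 0.12 * np.exp(-((t - 30) ** 2) / 18) * (t > 20)  # peak = 12 x SD
        tr = make_trace(dff, dt=0.5, noise_sd=0.01)
        evs = detect_events(tr)
        assert len(evs) == 1
        assert evs[0].amplitude_pct == pytest.approx(12.0, rel=0.05)

    def test_two_separated_transients_vs_fused_pair(self):
        dt = 0.5
        t = np.arange(0, 120, dt)

        def kernel(t0):
            x = np.clip(t - t0, 0, None)
            return np.exp(-x / 6.0) * (1 - np.exp(-x / 0.5)) * (t >= t0)

        two = 0.2 * (kernel(20) + kernel(60))  # decays fully in between
        tr = make_trace(two, dt=dt, noise_sd=0.005)
        assert len(detect_events(tr)) == 2

        fused = 0.2 * (kernel(20) + kernel(24))  # trough above half of peak
        tr2 = make_trace(fused, dt=dt, noise_sd=0.005)
        assert len(detect_events(tr2)) == 1

    def test_raising_threshold_never_adds_events(self, processed_default_trace):
        trace, _ = processed_default_trace
        counts = [len(detect_events(trace, k_sd=k)) for k in (3, 4, 6, 8, 12)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_every_event_peak_exceeds_amplitude_criterion(self):
        for seed in range(10):
            tr, _ = simulate_trace(TraceGenParams(seed=seed))
            process_trace(tr)
            base = np.median(tr.dff_filtered)
            for ev in detect_events(tr):
                i = int(round(ev.peak_s / tr.dt_s))
                assert tr.dff_filtered[i] - base > 6 * tr.noise_sd

    def test_zero_noise_with_signal_demands_explicit_threshold(self):
        tr = make_trace(np.sin(np.linspace(0, 3, 200)) ** 2, noise_sd=0.0)
        with pytest.raises(ValueError, match="explicit"):
            detect_events(tr)
        assert len(detect_events(tr, noise_sd=0.01)) >= 1

    def test_events_ordered_by_onset(self, processed_default_trace):
        trace, _ = processed_default_trace
        evs = detect_events(trace)
        onsets = [e.onset_s for e in evs]
        assert onsets == sorted(onsets)


class TestSummaries:
    MD = dict(cell_id="c1", mouse_id="m1", sex="male", age_group="young", diet="AL")

    def _events(self, n):
        return [
            __import__("microca.events", fromlist=["CaEvent"]).CaEvent(
                onset_s=10.0 * i, peak_s=10.0 * i + 1, end_s=10.0 * i + 5,
                amplitude_pct=20.0, t_half_s=5.0, auc=1.0,
            )
            for i in range(n)
        ]

    def test_three_events_in_15_min(self):
        s = summarize_cell(self._events(3), self.MD)
        assert s.frequency_per_min == pytest.approx(0.2)
        assert s.is_active
        assert s.median_amplitude_pct == 20.0

    def test_zero_events_inactive_with_no_metric_medians(self):
        s = summarize_cell([], self.MD)
        assert s.frequency_per_min == 0.0
        assert not s.is_active
        assert s.median_amplitude_pct is None

    def test_default_duration_is_15_min(self):
        assert summarize_cell([], self.MD).recording_duration_min == 15.0

    def test_truncated_events_count_but_skip_metric_medians(self):
        evs = self._events(2)
        evs[1].edge_truncated = True
        evs[1].t_half_s = 99.0
        s = summarize_cell(evs, self.MD)
        assert s.n_events == 2
        assert s.median_t_half_s == 5.0

    def test_fraction_active_per_mouse(self):
        cells = []
        for i, active in enumerate([True, True, False, False]):
            s = summarize_cell(self._events(1 if active else 0),
                               {**self.MD, "cell_id": f"c{i}"})
            cells.append(s)
        out = fraction_active_per_mouse(cells)
        assert len(out) == 1
        assert out[0].fraction_active_pct == 50.0
        assert out[0].n_cells == 4

    def test_all_active_is_100_percent(self):
        cells = [
            summarize_cell(self._events(2), {**self.MD, "cell_id": f"c{i}"})
            for i in range(3)
        ]
        assert fraction_active_per_mouse(cells)[0].fraction_active_pct == 100.0


class TestMatching:
    def test_greedy_matching_counts(self):
        m, d, t = match_events([10.0, 50.0, 90.0], [10.5, 49.0], tolerance_s=2.0)
        assert (m, d, t) == (2, 3, 2)

    def test_tolerance_respected(self):
        m, _, _ = match_events([10.0], [13.0], tolerance_s=2.0)
        assert m == 0
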