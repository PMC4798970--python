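"""Peak detection, phase assignment and synchrony statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nfkbsync.model_core import ForcingSignal
from nfkbsync.trace_analysis import (
    TraceSet,
    assign_phase,
    detect_peaks,
    experimental_periods,
    peak_heights_per_cycle,
    phase_difference,
    synchrony_intensity,
    synchrony_per_cycle,
)

T6 = lambda n: np.arange(n) * 6.0


class TestDetectPeaks:
    def test_three_point_bump_is_noise_never_significant(self):
        v = np.array([0.5, 0.3, 0.05, 0.30, 0.10, 0.3, 0.5, 0.6, 0.4, 0.3])
        pl = detect_peaks(T6(len(v)), v, min_track_min=0.0)
        bump = [p for p in pl.peaks if p.time == 18.0][0]
        assert bump.noise and not bump.significant
        assert bump.height == pytest.approx(0.30 - 0.10)

    def test_height_is_measured_from_highest_flanking_minimum(self):
        # minima 0.05 and 0.10 around a broad 0.30 maximum -> height 0.20
        v = np.array([0.3, 0.2, 0.05, 0.15, 0.30, 0.22, 0.10, 0.2, 0.3, 0.2, 0.1])
        pl = detect_peaks(T6(len(v)), v, min_track_min=0.0)
        peak = [p for p in pl.peaks if p.value == 0.30][0]
        assert peak.height == pytest.approx(0.30 - 0.10)
        assert peak.significant

    def test_monotone_trace_has_no_peaks(self):
        v = np.linspace(0.0, 1.0, 30)
        pl = detect_peaks(T6(30), v, min_track_min=0.0)
        assert pl.peaks == []

    def test_sub_threshold_peak_detected_but_not_significant(self):
        v = 0.05 + 0.12 * np.exp(-((T6(40) - 120) / 40) ** 2)
        pl = detect_peaks(T6(40), v, min_track_min=0.0)
        assert len(pl.peaks) == 1
        assert not pl.peaks[0].significant
        assert pl.peaks[0].height <= 0.15

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError):
            detect_peaks(np.array([0.0, 6.0]), np.array([0.1, 0.2]))

    def test_track_length_flag(self):
        v = np.zeros(30)
        assert not detect_peaks(T6(30), v).long_enough          # 174 min < 7 h
        assert detect_peaks(T6(71), np.zeros(71)).long_enough   # 420 min

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(deadline=None, max_examples=25)
    def test_raising_threshold_never_increases_significant_count(self, theta):
        rng = np.random.default_rng(7)
        v = np.abs(np.cumsum(rng.normal(0, 0.1, 120)))
        lo = detect_peaks(T6(120), v, threshold=theta, min_track_min=0.0)
        hi = detect_peaks(T6(120), v, threshold=theta + 0.1, min_track_min=0.0)
        assert len(hi.significant_times()) <= len(lo.significant_times())
        assert len(lo.significant_times()) <= len(lo.peaks)

    def test_planted_peaks_recovered_exactly_without_noise(self):
        t = T6(160)
        v = np.full(len(t), 0.05)
        planted = [200.0, 420.0, 640.0]
        for c in planted:
            v += 0.4 * np.exp(-(((t - c) / 30.0) ** 2))
        pl = detect_peaks(t, v, min_track_min=0.0)
        found = pl.significant_times()
        assert len(found) == len(planted)
        assert np.allclose(found, planted, atol=6.0)


class TestPhase:
    def test_anchor_values_at_maxima_and_minima(self):
        t = T6(60)
        v = 0.1 + 0.3 * (1 - np.cos(2 * np.pi * t / 120.0))  # maxima at 60,180,300
        pl = detect_peaks(t, v, min_track_min=0.0)
        ph = assign_phase(pl)
        sig = pl.significant_times()
        for ts in sig:
            assert ph.phase[np.argmin(np.abs(t - ts))] == pytest.approx(2 * np.pi)
        # minima between maxima carry phase pi
        for p in pl.peaks[:-1]:
            idx = np.argmin(np.abs(t - p.right_min_time))
            assert ph.phase[idx] == pytest.approx(np.pi)

    def test_linear_interpolation_midpoint(self):
        t = T6(60)
        v = 0.1 + 0.3 * (1 - np.cos(2 * np.pi * t / 120.0))
        pl = detect_peaks(t, v, min_track_min=0.0)
        ph = assign_phase(pl)
        peak_t = pl.significant_times()[0]
        min_t = [p for p in pl.peaks if p.significant][0].right_min_time
        mid_idx = np.argmin(np.abs(t - 0.5 * (peak_t + min_t)))
        assert ph.phase[mid_idx] == pytest.approx(np.pi / 2, abs=0.2)

    def test_masked_outside_anchors(self):
        t = T6(80)
        v = 0.05 + 0.4 * np.exp(-(((t - 240) / 30) ** 2)) + 0.4 * np.exp(-(((t - 360) / 30) ** 2))
        ph = assign_phase(detect_peaks(t, v, min_track_min=0.0))
        assert np.isnan(ph.phase[0]) and np.isnan(ph.phase[-1])
        assert ph.defined().any()

    def test_no_significant_peaks_gives_empty_phase(self):
        t = T6(30)
        ph = assign_phase(detect_peaks(t, np.full(30, 0.2), min_track_min=0.0))
        assert not ph.defined().any()


class TestPeriods:
    def test_successive_differences(self):
        t = T6(80)
        v = np.full(len(t), 0.05)
        for c in (30.0, 120.0, 210.0):
            v += 0.4 * np.exp(-(((t - c) / 12.0) ** 2))
        pl = detect_peaks(t, v, min_track_min=0.0)
        assert np.allclose(experimental_periods(pl), [90.0, 90.0], atol=6.0)

    def test_single_peak_contributes_nothing(self):
        t = T6(80)
        v = 0.05 + 0.4 * np.exp(-(((t - 120) / 20.0) ** 2))
        assert len(experimental_periods(detect_peaks(t, v, min_track_min=0.0))) == 0


class TestHeightsPerCycle:
    def test_bucket_indexing(self):
        t = T6(60)
        v = 0.05 + 0.4 * np.exp(-(((t - 102) / 15.0) ** 2))  # peak near t=100
        pl = detect_peaks(t, v, min_track_min=0.0)
        table = peak_heights_per_cycle(pl, T_ref=90.0)
        assert list(table["interval"]) == [2]     # floor(100/90)+1

    def test_empty_intervals_absent(self):
        t = T6(60)
        table = peak_heights_per_cycle(detect_peaks(t, np.full(60, 0.1), min_track_min=0.0), 90.0)
        assert len(table) == 0


class TestPhaseDifference:
    def make_peaklist(self, peak_times, t_max=720.0):
        t = np.arange(0.0, t_max, 6.0)
        v = np.full(len(t), 0.05)
        for c in peak_times:
            v += 0.4 * np.exp(-(((t - c) / 12.0) ** 2))
        return detect_peaks(t, v, min_track_min=0.0)

    def test_peak_at_cycle_start_gives_zero(self):
        forcing = ForcingSignal(kind="square", S_high=2.0, T1=45, T2=45)
        pl = self.make_peaklist([90.0, 180.0, 270.0])
        dphi = phase_difference(pl, forcing)
        # cycle starts at 0,90,...; peaks sit exactly on starts
        assert np.allclose(np.minimum(dphi, 2 * np.pi - dphi), 0.0, atol=0.5)

    def test_fixed_lag_gives_constant_delta_phi(self):
        forcing = ForcingSignal(kind="square", S_high=2.0, T1=45, T2=45)
        pl = self.make_peaklist([20.0, 110.0, 200.0, 290.0, 380.0])
        dphi = phase_difference(pl, forcing, forward_only=True)
        expected = 2 * np.pi * 20.0 / 90.0
        assert np.allclose(dphi[:5], expected, atol=0.3)

    def test_half_period_lag_gives_pi(self):
        forcing = ForcingSignal(kind="square", S_high=2.0, T1=45, T2=45)
        pl = self.make_peaklist([45.0, 135.0, 225.0])
        dphi = phase_difference(pl, forcing)
        wrapped = np.minimum(dphi, 2 * np.pi - dphi)
        assert np.allclose(wrapped, np.pi, atol=0.45)

    def test_constant_forcing_rejected(self):
        pl = self.make_peaklist([90.0])
        with pytest.raises(ValueError):
            phase_difference(pl, ForcingSignal(kind="constant", S_high=2.0))


class TestSynchrony:
    def test_flat_distribution_gives_zero(self):
        centers = (np.arange(8) + 0.5) * 2 * np.pi / 8
        res = synchrony_intensity(np.repeat(centers, 10))
        assert res.eta == pytest.approx(0.0, abs=1e-12)
        assert res.probabilities.sum() == pytest.approx(1.0)

    def test_delta_distribution_gives_one(self):
        res = synchrony_intensity(np.full(50, 1.3))
        assert res.eta == pytest.approx(1.0)

    def test_two_equal_bins_closed_form(self):
        dphi = np.concatenate([np.full(20, 0.3), np.full(20, 3.5)])
        res = synchrony_intensity(dphi)
        assert res.eta == pytest.approx(1 - np.log(2) / np.log(8))

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            synchrony_intensity(np.array([]))

    @given(st.integers(min_value=-3, max_value=3))
    @settings(deadline=None, max_examples=10)
    def test_invariant_under_2pi_shifts(self, k):
        rng = np.random.default_rng(3)
        dphi = rng.uniform(0, 2 * np.pi, 64)
        base = synchrony_intensity(dphi).eta
        shifted = synchrony_intensity(dphi + 2 * np.pi * k).eta
        assert shifted == pytest.approx(base)

    def test_eta_monotone_in_concentration(self):
        from nfkbsync.synthetic_data import generate_phase_samples
        etas = [synchrony_intensity(
            generate_phase_samples("concentrated", 4000, seed=5, kappa=k)).eta
            for k in (0.5, 1, 2, 4, 8)]
        assert all(b > a for a, b in zip(etas, etas[1:]))

    def test_eta_within_unit_interval_for_random_samples(self, rng):
        for _ in range(20):
            dphi = rng.uniform(0, 2 * np.pi, rng.integers(1, 50))
            assert 0.0 <= synchrony_intensity(dphi).eta <= 1.0


class TestSynchronyPerCycle:
    def test_identical_lag_every_cycle_gives_one(self):
        forcing = ForcingSignal(kind="square", S_high=2.0, T1=45, T2=45)
        t = np.arange(0.0, 720.0, 6.0)
        pls = []
        for _ in range(5):
            v = np.full(len(t), 0.05)
            for c in np.arange(24.0, 700.0, 90.0):
                v += 0.4 * np.exp(-(((t - c) / 12.0) ** 2))
            pls.append(detect_peaks(t, v, min_track_min=0.0))
        etas = synchrony_per_cycle(pls, forcing, n_cycles=6)
        assert all(e == pytest.approx(1.0) for e in etas if e is not None)
        assert sum(e is not None for e in etas) >= 5

    def test_random_peaks_give_low_eta(self):
        forcing = ForcingSignal(kind="square", S_high=2.0, T1=45, T2=45)
        rng = np.random.default_rng(11)
        t = np.arange(0.0, 720.0, 6.0)
        pls = []
        for _ in range(200):
            v = np.full(len(t), 0.05)
            for c in rng.uniform(30, 690, 4):
                v += 0.4 * np.exp(-(((t - c) / 12.0) ** 2))
            pls.append(detect_peaks(t, v, min_track_min=0.0))
        etas = [e for e in synchrony_per_cycle(pls, forcing, n_cycles=6) if e is not None]
        assert np.mean(etas) < 0.15


class TestTraceSet:
    def test_non_uniform_sampling_rejected(self):
        with pytest.raises(ValueError):
            TraceSet({"c": (np.array([0.0, 6.0, 18.0]), np.array([0.1, 0.2, 0.1]))})

    def test_negative_nci_rejected(self):
        with pytest.raises(ValueError):
            TraceSet({"c": (np.array([0.0, 6.0]), np.array([0.1, -0.2]))})
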