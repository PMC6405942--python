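import numpy as np
import pytest

from mtdyn.kymo import (Event, RansacConfig, analyze_track,
                        assign_polarity, classify_transitions,
                        compute_frequencies, estimate_noise,
                        find_growth_events, find_shrink_events,
                        length_distribution)


def sawtooth(vg=5.0, vs=-50.0, period_up=60, period_down=6, n_cycles=4,
             dt=1.0, noise=0.0, seed=0):
    """Piecewise-linear growth/shrink track; returns (t, length)."""
    rng = np.random.default_rng(seed)
    t, L = [0.0], [0.0]
    for _ in range(n_cycles):
        for _ in range(period_up):
            t.append(t[-1] + dt)
            L.append(L[-1] + vg * dt)
        for _ in range(period_down):
            t.append(t[-1] + dt)
            L.append(max(L[-1] + vs * dt, 0.0))
    t, L = np.array(t), np.array(L)
    return t, L + rng.normal(0, noise, L.size)


class TestGrowthEvents:
    def test_perfect_line_yields_one_event_with_exact_slope(self):
        t = np.arange(60.0)
        events = find_growth_events(t, 7.0 * t + 3.0)
        assert len(events) == 1
        assert events[0].slope == pytest.approx(7.0)
        assert events[0].indices.size == 60

    def test_four_phase_track_yields_four_growth_events(self):
        t, L = sawtooth(n_cycles=4, noise=1.0)
        events = find_growth_events(t, L)
        assert len(events) == 4
        # found in order of decreasing length per the removal loop
        sizes = [e.indices.size for e in events]
        assert sizes == sorted(sizes, reverse=True)

    def test_two_slopes_recovered_within_five_percent(self):
        rng = np.random.default_rng(3)
        cfg = RansacConfig(epsilon_nm=6.0)
        t1 = np.arange(80.0)
        seg1 = 5.0 * t1
        seg2 = seg1[-1] - 400.0 + 8.0 * t1   # jump down, slope 8
        t = np.concatenate([t1, t1[-1] + 1 + t1])
        L = np.concatenate([seg1, seg2]) + rng.normal(0, 2.0, 160)
        events = find_growth_events(t, L, cfg)
        slopes = sorted(e.slope for e in events)
        assert len(events) == 2
        assert slopes[0] == pytest.approx(5.0, rel=0.05)
        assert slopes[1] == pytest.approx(8.0, rel=0.05)

    def test_inlier_sets_are_disjoint_and_quasi_consecutive(self):
        t, L = sawtooth(n_cycles=5, noise=1.5, seed=4)
        events = find_growth_events(t, L)
        seen = set()
        for ev in events:
            assert not (seen & set(ev.indices.tolist()))
            seen |= set(ev.indices.tolist())
            assert (np.diff(ev.indices) <= 3).all()

    def test_fixed_seed_is_reproducible(self):
        t, L = sawtooth(noise=2.0, seed=5)
        a = find_growth_events(t, L)
        b = find_growth_events(t, L)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert np.array_equal(x.indices, y.indices)


class TestShrinkEvents:
    def test_monotone_growth_has_no_shrink_events(self):
        t = np.arange(100.0)
        L = 3.0 * t
        growth = find_growth_events(t, L)
        assert find_shrink_events(t, L, growth) == []

    def test_sawtooth_shrink_slopes_within_ten_percent(self):
        t, L = sawtooth(vg=5.0, vs=-50.0, noise=1.0, seed=6)
        growth = find_growth_events(t, L)
        shrink = find_shrink_events(t, L, growth)
        assert len(shrink) >= 3
        for ev in shrink:
            assert ev.slope == pytest.approx(-50.0, rel=0.1)

    def test_shallow_decline_is_not_a_shrink_event(self):
        # decline at -1.2 vg is slower than the -2 vg gate
        t = np.arange(120.0)
        L = np.where(t < 60, 5.0 * t, 300.0 - 6.0 * (t - 60))
        growth = find_growth_events(t, L)
        shrink = find_shrink_events(t, L, growth)
        assert shrink == []


class TestFrequencies:
    @staticmethod
    def ev(kind, t0, t1, slope, icpt=0.0):
        n = max(int(t1 - t0) + 1, 2)
        return Event(kind=kind, indices=np.arange(n), t_start=t0, t_end=t1,
                     slope=slope, intercept=icpt)

    def test_catastrophe_frequency_arithmetic(self):
        # three complete growth events of total 100 s, each ending in shrink
        events = []
        t = 0.0
        for k in range(3):
            dur = [30.0, 40.0, 30.0][k]
            events.append(self.ev("growth", t, t + dur, 2.0, icpt=-2.0 * t))
            t += dur
            events.append(self.ev("shrink", t, t + 3.0, -20.0,
                                  icpt=1000.0 + 20.0 * t))
            t += 3.0
        fc, fr = compute_frequencies(events)
        assert fc == pytest.approx(3.0 / 100.0)

    def test_no_shrink_events_give_zero_fc_and_undefined_fr(self):
        events = [self.ev("growth", 0.0, 100.0, 2.0)]
        fc, fr = compute_frequencies(events)
        assert fc == 0.0
        assert np.isnan(fr)

    def test_empty_track_frequencies_are_undefined(self):
        fc, fr = compute_frequencies([])
        assert np.isnan(fc) and np.isnan(fr)


class TestTransitions:
    @staticmethod
    def ev(kind, t0, t1, slope, icpt):
        return Event(kind=kind, indices=np.arange(3), t_start=t0, t_end=t1,
                     slope=slope, intercept=icpt)

    def test_shrink_to_baseline_is_total_catastrophe(self):
        events = [
            self.ev("growth", 0, 50, 2.0, 0.0),
            self.ev("shrink", 50, 55, -20.0, 1100.0),     # reaches 0
            self.ev("growth", 55, 80, 2.0, -110.0),       # restarts at 0
        ]
        assert classify_transitions(events) == ["total_catastrophe"]

    def test_shrink_stopping_high_is_rescue(self):
        events = [
            self.ev("growth", 0, 50, 40.0, 0.0),
            self.ev("shrink", 50, 55, -100.0, 7000.0),
            self.ev("growth", 55, 80, 40.0, -200.0),      # restarts at 2 um
        ]
        assert classify_transitions(events) == ["rescued"]

    def test_track_ending_mid_shrink_is_incomplete(self):
        events = [
            self.ev("growth", 0, 50, 2.0, 0.0),
            self.ev("shrink", 50, 55, -20.0, 1100.0),
        ]
        assert classify_transitions(events) == ["incomplete"]


class TestPolarity:
    def test_faster_end_is_plus(self):
        a = analyze_track(np.arange(100.0), 2.0 * np.arange(100.0))
        b = analyze_track(np.arange(100.0), 0.5 * np.arange(100.0))
        assert assign_polarity(a, b) == ("plus", "minus")
        assert assign_polarity(b, a) == ("minus", "plus")

    def test_asymmetric_ends_identified_across_noisy_tracks(self):
        rng = np.random.default_rng(8)
        correct = 0
        for k in range(10):
            t = np.arange(150.0)
            fast = 3.0 * t + rng.normal(0, 3.0, t.size)
            slow = 1.0 * t + rng.normal(0, 3.0, t.size)
            a, b = analyze_track(t, fast), analyze_track(t, slow)
            correct += assign_polarity(a, b) == ("plus", "minus")
        assert correct == 10


class TestLengthDistribution:
    def test_unbounded_regime_raises(self):
        with pytest.raises(ValueError):
            length_distribution(2.0, 20.0, 0.0, 0.01)      # fc = 0
        with pytest.raises(ValueError):
            length_distribution(2.0, 4.0, 0.01, 0.05)      # vg fr > vs fc

    def test_finite_time_distribution_is_normalized_and_bounded(self):
        c, d = length_distribution(30.0, 300.0, 0.01, 0.05, t=100.0)
        assert d.min() >= 0
        assert np.trapezoid(d, c) == pytest.approx(1.0, rel=1e-2)
        # the bulk stays behind the advection front vg * t (the upwind
        # scheme smears the front itself over ~sqrt(vg dl t))
        assert np.trapezoid(d * c, c) < 30.0 * 100.0
        assert d[-1] < 0.05 * d.max()


def test_noise_estimate_recovers_sigma_on_piecewise_linear_track():
    t, L = sawtooth(noise=7.0, seed=9, n_cycles=3)
    assert estimate_noise(L) == pytest.approx(7.0, rel=0.25)
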