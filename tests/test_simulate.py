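import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from mtdyn.simulate import (GroundTruthFilament, SimImageConfig,
                            apply_poisson_noise, measure_snr,
                            render_filament, simulate_length_trajectory)


def hline(y=20.0, x0=8.0, x1=32.0):
    return GroundTruthFilament("line", (0.0, y), x0, x1)


CFG = SimImageConfig(width_px=48, height_px=48, background=0.0,
                     amplitude=50.0, rng_seed=0)


class TestRender:
    def test_ridge_equals_amplitude_and_background_far_away(self):
        img = render_filament(CFG, hline())
        assert img[20, 20] == pytest.approx(50.0, rel=0.02)
        assert img[40, 20] == pytest.approx(0.0, abs=1e-6)

    def test_zero_length_filament_is_a_single_spot(self):
        img = render_filament(CFG, hline(x0=20.0, x1=20.0))
        peak = np.unravel_index(np.argmax(img), img.shape)
        assert peak == (20, 20)
        # radially symmetric decay of an isolated Gaussian
        assert img[20, 22] == pytest.approx(img[22, 20], rel=1e-6)

    def test_out_of_bounds_path_rejected(self):
        with pytest.raises(ValueError):
            render_filament(CFG, hline(x0=-5.0))

    def test_integer_translation_equivariance(self):
        a = render_filament(CFG, hline(y=20.0, x0=10.0, x1=30.0))
        b = render_filament(CFG, hline(y=23.0, x0=10.0, x1=30.0))
        assert np.allclose(a[15:26, :], b[18:29, :], atol=1e-9)

    def test_cubic_ridge_intensity_constant_per_arc_length(self):
        fil = GroundTruthFilament("cubic", (3e-4, 0.0, 0.0, 22.0),
                                  6.0, 40.0)
        cfg = SimImageConfig(width_px=48, height_px=48, background=0.0,
                             amplitude=50.0, psf_sigma_px=(1.5, 1.5),
                             rng_seed=0)
        img = render_filament(cfg, fil)
        pts = fil.sample_arc(0.5)[5:-5]   # away from the tips
        ridge = map_coordinates(img, [pts[:, 1], pts[:, 0]], order=3)
        assert ridge.std() / ridge.mean() < 0.02


class TestPoissonNoise:
    def test_ridge_mean_is_snr_squared_on_zero_background(self):
        img = render_filament(CFG, hline())
        noisy = np.stack([apply_poisson_noise(img, 6.0, seed)
                          for seed in range(40)])
        ridge = noisy[:, 20, 12:28].mean()
        assert ridge == pytest.approx(36.0, rel=0.05)

    def test_deterministic_given_seed(self):
        img = render_filament(CFG, hline())
        a = apply_poisson_noise(img, 5.0, 123)
        b = apply_poisson_noise(img, 5.0, 123)
        assert np.array_equal(a, b)

    def test_negative_pixels_rejected(self):
        with pytest.raises(ValueError):
            apply_poisson_noise(np.full((16, 16), -1.0), 5.0, 0)


class TestMeasureSnr:
    scan = np.stack([np.linspace(10, 30, 20), np.full(20, 20.0)], axis=1)

    def test_constant_scan_signals_undefined(self):
        img = np.full((48, 48), 7.0)
        assert measure_snr(img, self.scan) == np.inf

    def test_alternating_values_give_mean_over_std(self):
        img = np.zeros((48, 48))
        img[20, :] = np.resize([8.0, 12.0], 48)
        scan = np.stack([np.arange(10, 30, dtype=float),
                         np.full(20, 20.0)], axis=1)
        assert measure_snr(img, scan) == pytest.approx(5.0)

    def test_poisson_ridge_snr_matches_sqrt_mean(self):
        vals = []
        for seed in range(10):
            img = render_filament(CFG, hline())
            noisy = apply_poisson_noise(img, 5.0, seed)
            vals.append(measure_snr(noisy, self.scan))
        assert np.mean(vals) == pytest.approx(5.0, rel=0.1)

    def test_short_scan_rejected(self):
        with pytest.raises(ValueError):
            measure_snr(np.zeros((48, 48)), self.scan[:5])


class TestTrajectory:
    def test_pure_growth_has_exact_slope(self):
        rng = np.random.default_rng(0)
        t, L, phases, _, _ = simulate_length_trajectory(
            2.0, 20.0, 0.0, 0.0, 50, 1.0, rng)
        assert np.allclose(np.diff(L), 2.0)
        assert set(phases) == {"growth"}

    def test_length_never_negative(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            _, L, _, _, _ = simulate_length_trajectory(
                1.0, 30.0, 0.1, 0.02, 200, 1.0, rng)
            assert (L >= 0).all()

    def test_catastrophe_rate_recovers_input(self):
        rng = np.random.default_rng(0)
        n_cat, exposure = 0, 0.0
        for _ in range(40):
            t, L, phases, ev_t, ev_k = simulate_length_trajectory(
                2.0, 20.0, 0.02, 0.1, 500, 1.0, rng)
            # exposure = total time in the growth state, censored tail incl.
            state, t_prev = "growth", 0.0
            for te, ke in zip(ev_t, ev_k):
                if state == "growth":
                    exposure += te - t_prev
                    n_cat += 1
                    state = "shrink"
                else:
                    state = "growth"
                t_prev = te
            if state == "growth":
                exposure += t[-1] - t_prev
        rate = n_cat / exposure
        assert n_cat > 50
        assert rate == pytest.approx(0.02, abs=2.5 * 0.02 / np.sqrt(n_cat))

    def test_invalid_frame_interval_rejected(self):
        with pytest.raises(ValueError):
            simulate_length_trajectory(1.0, 10.0, 0.0, 0.0, 10, 0.0,
                                       np.random.default_rng(0))
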