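"""Model evaluation, analytic gradients, LM solver, mask fit, contour length.

The heavyweight oracle checks (100 random draws against central finite
differences, the full perturbation-recovery experiment) live in
test_acceptance; here each property is exercised on a few draws.
"""

import numpy as np
import pytest

from mtdyn.detect import line_from_ellipse
from mtdyn.models import (LineSoGModel, PolySoGModel, contour_length,
                          fit_model, fit_model_multiscale,
                          gaussian_mask_refine, lm_minimize)
from mtdyn.mser import EllipseRegion

GRID = np.meshgrid(np.arange(40.0), np.arange(40.0))
X, Y = GRID[0].ravel(), GRID[1].ravel()


def line_model(angle=0.4, sigma=0.6):
    d = np.array([np.cos(angle), np.sin(angle)])
    p0 = np.array([12.0, 14.0])
    p1 = p0 + 15.0 * d
    theta = np.array([*p0, *p1, 0.55, 60.0, 10.0])
    return LineSoGModel(direction=d, sigma=(sigma, sigma)), theta


def poly_model(b=-0.008, i3=2e-4, sigma=0.6):
    model = PolySoGModel(start=(8.0, 15.0), sigma=(sigma, sigma))
    theta = np.array([30.0, 22.0, 0.55, 60.0, 10.0, b, i3])
    return model, theta


class TestModelEvaluation:
    def test_zero_amplitude_gives_pure_background(self):
        m, th = line_model()
        th[5] = 0.0
        assert np.allclose(m.model(th, X, Y), th[6])

    def test_poly_with_zero_curvature_reduces_to_a_straight_chain(self):
        pm, pth = poly_model(b=0.0, i3=0.0)
        pts = pm.chain(pth)
        d = pts[-1] - pts[0]
        d = d / np.linalg.norm(d)
        # collinear centers at uniform arc spacing ds
        offsets = pts - pts[0]
        perp = offsets @ np.array([-d[1], d[0]])
        assert np.abs(perp).max() < 1e-9
        steps = np.linalg.norm(np.diff(pts[:-1], axis=0), axis=1)
        assert np.allclose(steps, pth[2], atol=1e-9)

    @pytest.mark.parametrize("b,i3", [(0.0, 0.0), (-0.01, 0.0),
                                      (0.005, -3e-4)])
    def test_poly_path_passes_through_both_endpoints(self, b, i3):
        pm, pth = poly_model(b=b, i3=i3)
        xe, ye = pth[0], pth[1]
        xs, ys = pm.start
        assert pm.path_y(pth, np.array([xs]))[0] == pytest.approx(ys)
        assert pm.path_y(pth, np.array([xe]))[0] == pytest.approx(ye)

    def test_background_derivative_is_unity(self):
        m, th = line_model()
        _, D = m.jac(th, X, Y)
        assert np.allclose(D[6], 1.0)


@pytest.mark.parametrize("builder,n_params", [(line_model, 7),
                                              (poly_model, 7)])
def test_analytic_gradients_match_finite_differences(builder, n_params):
    model, theta = builder()
    _, D = model.jac(theta, X, Y)
    for k in range(n_params):
        h = 1e-6 * max(1.0, abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        fd = (model.model(tp, X, Y) - model.model(tm, X, Y)) / (2 * h)
        scale = max(np.abs(D[k]).max(), 1e-10)
        assert np.abs(D[k] - fd).max() / scale < 1e-4, f"parameter {k}"


class TestLevenbergMarquardt:
    def test_ground_truth_initialization_is_a_fixed_point(self):
        m, th = line_model()
        img = m.model(th, X, Y).reshape(40, 40)
        res = fit_model(m, th.copy(), img, (0, 0, 40, 40))
        assert res.converged
        assert res.chi2 < 1e-12
        assert res.n_iter <= 2

    def test_chi2_never_increases_over_accepted_steps(self):
        m, th = line_model()
        img = m.model(th, X, Y).reshape(40, 40)
        pert = th.copy()
        pert[:4] += np.array([0.8, -0.5, 0.6, 0.9])
        res = fit_model(m, pert, img, (0, 0, 40, 40))
        assert all(b <= a + 1e-12 for a, b in
                   zip(res.chi2_history, res.chi2_history[1:]))

    def test_singular_direction_is_handled_by_damping(self):
        # duplicate-parameter residual makes J^T J exactly singular
        def fun_jac(theta):
            # residual f = I - F with F = theta0 + theta1, I = 1
            f = np.array([1.0 - theta[0] - theta[1]])
            J = np.array([[1.0], [1.0]])   # dF/dtheta
            return f, J

        res = lm_minimize(fun_jac, np.array([5.0, -2.0]))
        assert res.chi2 < 1e-10


class TestMaskRefine:
    def test_noiseless_tip_is_a_fixed_point(self):
        m, th = line_model()
        img = m.model(th, X, Y).reshape(40, 40) - th[6]
        tip = th[2:4]
        res = gaussian_mask_refine(img, tip, -m.direction, th[4], m.sigma,
                                   model_image=img)
        assert res.refined
        assert np.allclose(res.position, tip, atol=1e-9)

    def test_divergent_start_flagged_unrefined(self):
        img = np.zeros((40, 40))
        res = gaussian_mask_refine(img, np.array([20.0, 20.0]),
                                   np.array([1.0, 0.0]), 0.5, (0.6, 0.6),
                                   model_image=img)
        assert not res.refined


class TestContourLength:
    def test_line_is_euclidean_three_four_five(self):
        assert contour_length((4.0 / 3.0, 0.0), 0.0, 3.0) \
            == pytest.approx(5.0)

    def test_zero_curvature_poly_equals_euclidean(self):
        assert contour_length((0.0, 0.0, 2.0, 1.0), 1.0, 5.0) \
            == pytest.approx(4.0 * np.hypot(1.0, 2.0))

    def test_cubic_matches_dense_polyline_oracle(self):
        i3 = 1.0 / 300.0
        x = np.linspace(0.0, 30.0, 100_001)
        y = i3 * x**3
        oracle = float(np.hypot(np.diff(x), np.diff(y)).sum())
        val = contour_length((i3, 0.0, 0.0, 0.0), 0.0, 30.0)
        assert val == pytest.approx(oracle, rel=1e-3)

    def test_pixel_size_scales_to_nanometers(self):
        assert contour_length((0.0, 5.0), 0.0, 10.0, pixel_size_nm=156.0) \
            == pytest.approx(1560.0)


class TestLineFromEllipse:
    @staticmethod
    def region_with(p, q, r):
        reg = EllipseRegion.__new__(EllipseRegion)
        reg.pixels = np.zeros((1, 2), dtype=int)
        reg.centroid = np.array([5.0, 7.0])
        reg.p, reg.q, reg.r = p, q, r
        return reg

    def test_symmetric_covariance_gives_unit_slope(self):
        reg = self.region_with(p=2.0, q=1.0, r=2.0)
        m, c = line_from_ellipse(reg)
        assert m == pytest.approx(1.0)
        assert c == pytest.approx(7.0 - 5.0 * 1.0)

    def test_axis_aligned_fallback_is_horizontal(self):
        reg = self.region_with(p=4.0, q=0.0, r=1.0)
        m, c = line_from_ellipse(reg)
        assert m == 0.0
        assert c == pytest.approx(7.0)

    def test_slope_recovered_from_rendered_seed_region(self):
        from mtdyn.mser import detect_mser_regions
        from mtdyn.simulate import (GroundTruthFilament, SimImageConfig,
                                    apply_poisson_noise, render_filament)

        cfg = SimImageConfig(width_px=64, height_px=64, rng_seed=0)
        fil = GroundTruthFilament("line", (0.5, 8.0), 10.0, 40.0)
        noisy = apply_poisson_noise(render_filament(cfg, fil), 10.0, 5,
                                    background=cfg.background)
        regions = detect_mser_regions(noisy)
        assert len(regions) == 1
        m, _ = line_from_ellipse(regions[0])
        assert m == pytest.approx(0.5, abs=0.05)
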