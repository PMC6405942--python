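import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtdyn.mser import EllipseRegion, MserConfig, detect_mser_regions
from mtdyn.simulate import (SimImageConfig, apply_poisson_noise,
                            render_filament, GroundTruthFilament)


def test_constant_image_yields_no_regions():
    assert detect_mser_regions(np.full((64, 64), 13.0)) == []


def test_single_seed_region_contains_the_ridge():
    cfg = SimImageConfig(width_px=64, height_px=64, rng_seed=0)
    fil = GroundTruthFilament("line", (0.3, 12.0), 14.0, 44.0)
    noisy = apply_poisson_noise(render_filament(cfg, fil), 10.0, 1,
                                background=cfg.background)
    regions = detect_mser_regions(noisy)
    assert len(regions) == 1
    reg = regions[0]
    pts = np.round(fil.sample_arc(1.0)).astype(int)
    pix = set(map(tuple, reg.pixels))
    frac = np.mean([(x, y) in pix for x, y in pts])
    assert frac > 0.9


def test_region_detection_rotates_with_the_image():
    cfg = SimImageConfig(width_px=64, height_px=64, rng_seed=0)
    fil = GroundTruthFilament("line", (0.5, 10.0), 12.0, 40.0)
    noisy = apply_poisson_noise(render_filament(cfg, fil), 10.0, 3,
                                background=cfg.background)
    r0 = detect_mser_regions(noisy)
    r90 = detect_mser_regions(np.rot90(noisy))
    assert len(r0) == len(r90) == 1
    # rot90 maps (x, y) -> (y, W-1-x)
    c = r0[0].centroid
    expected = np.array([c[1], 64 - 1 - c[0]])
    assert np.allclose(r90[0].centroid, expected, atol=0.5)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_region_moments_form_a_valid_covariance(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(3, 40)
    pix = rng.integers(0, 30, size=(n, 2))
    reg = EllipseRegion(pixels=pix, stability=0.0, level=10)
    assert reg.p > 0 and reg.r > 0
    assert reg.p * reg.r - reg.q**2 >= 0
    assert reg.dr >= 0
    lam1, lam2 = reg.eigenvalues
    assert lam1 >= lam2
    assert np.isclose(np.linalg.norm(reg.major_axis_vector), 1.0)


def test_min_area_filters_small_specks():
    img = np.zeros((64, 64))
    img[10, 10] = 100.0        # single-pixel spike
    img[30:34, 20:40] = 50.0   # proper region
    regions = detect_mser_regions(
        img, MserConfig(min_area=10, smooth_sigma=0.0))
    assert len(regions) == 1
    assert regions[0].area >= 10
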