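"""Seed detection: MSER regions -> line SoG fit -> subpixel endpoints.

Stabilized microtubule seeds are bright, straight ridges in the seed
channel.  Detection proceeds in three stages:

1. MSER finds one stable region per seed (component-tree stability,
   :mod:`mtdyn.mser`).
2. The region's second-moment ellipse initializes a line, and a sum of 2D
   Gaussians placed along that line is fit by Levenberg-Marquardt with
   analytic derivatives (:mod:`mtdyn.models`).
3. Both end points are refined to subpixel precision with the iterative
   two-Gaussian mask fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .mser import EllipseRegion, MserConfig, detect_mser_regions
from .models import (LMConfig, LMResult, LineSoGModel, dense_model_image,
                     fit_model_multiscale, gaussian_mask_refine)
from .simulate import measure_snr

logger = logging.getLogger(__name__)

__all__ = ["DetectConfig", "DetectedSeed", "line_from_ellipse",
           "detect_seeds", "match_seeds_to_regions"]

_VERTICAL_SLOPE = 1e6


@dataclass(frozen=True)
class DetectConfig:
    """Seed-detection parameters; PSF sigma in pixels (sx, sy)."""

    psf_sigma_px: tuple[float, float] = (0.542, 0.542)
    mser: MserConfig = field(default_factory=MserConfig)
    lm: LMConfig = field(default_factory=LMConfig)
    window_dilation_sigmas: float = 3.0
    mask_tol: float = 1e-3
    mask_max_iter: int = 50
    # seeds shorter than this or dimmer than this measured SNR are
    # discarded as noise-born detections
    min_length_px: float = 5.0
    min_snr: float = 1.5
    # width of the mask-fit weight Gaussians relative to the PSF sigma; a
    # wider mask pools more tip signal per update, stiffening the fixed
    # point against pixel-noise wells
    mask_sigma_scale: float = 1.25


@dataclass
class DetectedSeed:
    """One fitted seed: line model parameters and refined endpoints."""

    seed_id: int
    region: EllipseRegion
    direction: np.ndarray            # unit vector start -> end
    endpoints: np.ndarray            # (2, 2) refined [(x,y) start, end]
    endpoints_refined: tuple[bool, bool]
    m: float
    c: float
    A: float
    Bg: float
    ds: float
    snr: float
    lm_result: LMResult | None = None

    @property
    def length_px(self) -> float:
        return float(np.linalg.norm(self.endpoints[1] - self.endpoints[0]))


def line_from_ellipse(region: EllipseRegion) -> tuple[float, float]:
    """Slope/intercept of the region ellipse's major axis.

    m = (r - p + dr) / (2 q) and c = y_c - x_c m, the line through the
    centroid along the leading eigenvector of the pixel covariance.  For
    q = 0 the covariance is axis-aligned: the major axis is horizontal
    (m = 0) when p > r, and vertical otherwise (reported with a sentinel
    slope of 1e6; callers doing geometry should use
    ``region.major_axis_vector`` which handles all orientations
    parametrically).
    """
    xc, yc = region.centroid
    if abs(region.q) < 1e-12:
        if region.p >= region.r:
            return 0.0, float(yc)
        return _VERTICAL_SLOPE, float(yc - xc * _VERTICAL_SLOPE)
    m = (region.r - region.p + region.dr) / (2.0 * region.q)
    return float(m), float(yc - xc * m)


def _initial_endpoints(region: EllipseRegion) -> tuple[np.ndarray, np.ndarray,
                                                       np.ndarray]:
    """Endpoints from extreme projections of region pixels on the axis."""
    d = region.major_axis_vector
    t = (region.pixels.astype(float) - region.centroid) @ d
    return (region.centroid + t.min() * d, region.centroid + t.max() * d, d)


def fit_seed(image: np.ndarray, region: EllipseRegion,
             config: DetectConfig, seed_id: int = 0) -> DetectedSeed | None:
    """Fit the line SoG model in a region and refine both endpoints."""
    sx, sy = config.psf_sigma_px
    p0, p1, d = _initial_endpoints(region)
    x0, y0, x1, y1 = region.bbox
    pad = int(math.ceil(config.window_dilation_sigmas * max(sx, sy))) + 2
    window = (x0 - pad, y0 - pad, x1 + pad, y1 + pad)

    wx0, wy0 = max(window[0], 0), max(window[1], 0)
    wx1 = min(window[2], image.shape[1])
    wy1 = min(window[3], image.shape[0])
    sub = np.asarray(image, dtype=float)[wy0:wy1, wx0:wx1]
    bg0 = float(np.median(sub))
    amp0 = max(float(sub.max()) - bg0, 1e-6)
    ds0 = sx
    # dense chain ridge ~ A sqrt(pi) sigma / ds for the exp(-d^2/s^2) profile
    a0 = amp0 * ds0 / (math.sqrt(math.pi) * sx)

    model = LineSoGModel(direction=d, sigma=(sx, sy))
    theta0 = np.array([p0[0], p0[1], p1[0], p1[1], ds0, a0, bg0])
    try:
        res = fit_model_multiscale(model, theta0, image, window, config.lm)
    except (ValueError, np.linalg.LinAlgError):
        logger.warning("seed %d: fit failed, region dropped", seed_id)
        return None
    if not np.all(np.isfinite(res.theta)):
        logger.warning("seed %d: fit diverged, region dropped", seed_id)
        return None
    xs, ys, xe, ye, ds, A, Bg = res.theta
    # a fit whose endpoints left the window is a runaway, not a seed
    margin = 5.0
    for px, py in ((xs, ys), (xe, ye)):
        if not (window[0] - margin <= px <= window[2] + margin
                and window[1] - margin <= py <= window[3] + margin):
            logger.warning("seed %d: fit left the window, region dropped",
                           seed_id)
            return None

    start = np.array([xs, ys])
    end = np.array([xe, ye])
    u = end - start
    nrm = np.linalg.norm(u)
    if nrm < 1e-9:
        logger.warning("seed %d: degenerate fit, region dropped", seed_id)
        return None
    u = u / nrm

    # continuous-filament rendering of the fit, for bias cancellation
    model_img = dense_model_image(model, res.theta, image.shape,
                                  (wx0, wy0, wx1, wy1))

    refined = []
    flags = []
    msig = (sx * config.mask_sigma_scale, sy * config.mask_sigma_scale)
    for tip, inward in ((start, u), (end, -u)):
        r = gaussian_mask_refine(image, tip, inward, ds, msig,
                                 background=Bg, model_image=model_img,
                                 tol=config.mask_tol,
                                 max_iter=config.mask_max_iter)
        refined.append(r.position)
        flags.append(r.refined)
    endpoints = np.stack(refined)

    mline, cline = line_from_ellipse(region)
    t = np.linspace(0.05, 0.95, 25)
    scan = start[None, :] + t[:, None] * (end - start)[None, :]
    snr = measure_snr(np.asarray(image, float) - Bg, scan)
    return DetectedSeed(
        seed_id=seed_id, region=region, direction=u, endpoints=endpoints,
        endpoints_refined=(flags[0], flags[1]), m=mline, c=cline,
        A=float(A), Bg=float(Bg), ds=float(ds), snr=float(snr),
        lm_result=res)


def detect_seeds(image: np.ndarray,
                 config: DetectConfig | None = None) -> list[DetectedSeed]:
    """Full seed-detection pipeline on one seed-channel frame."""
    if config is None:
        config = DetectConfig()
    regions = detect_mser_regions(image, config.mser)
    seeds: list[DetectedSeed] = []
    for region in regions:
        seed = fit_seed(image, region, config, seed_id=len(seeds))
        if seed is None:
            continue
        if (seed.length_px < config.min_length_px
                or seed.snr < config.min_snr):
            logger.info("seed candidate dropped (length %.1f px, snr %.1f)",
                        seed.length_px, seed.snr)
            continue
        seed.seed_id = len(seeds)
        seeds.append(seed)
    return seeds


def match_seeds_to_regions(filaments, regions, image_shape,
                           sample_spacing: float = 1.0) -> float:
    """One-to-one assignment accuracy (%) of ground truth to regions.

    A ground-truth filament counts as matched when its sampled path hits
    exactly one detected region and no other filament hits that region.
    """
    h, w = image_shape
    lab = np.full((h, w), -1, dtype=int)
    for i, reg in enumerate(regions):
        lab[reg.pixels[:, 1], reg.pixels[:, 0]] = i
    hits: list[set[int]] = []
    for fil in filaments:
        pts = np.round(fil.sample_arc(sample_spacing)).astype(int)
        pts[:, 0] = np.clip(pts[:, 0], 0, w - 1)
        pts[:, 1] = np.clip(pts[:, 1], 0, h - 1)
        labels = set(int(v) for v in lab[pts[:, 1], pts[:, 0]] if v >= 0)
        hits.append(labels)
    matched = 0
    for i, labels in enumerate(hits):
        if len(labels) != 1:
            continue
        label = next(iter(labels))
        if any(label in other for j, other in enumerate(hits) if j != i):
            continue
        matched += 1
    return 100.0 * matched / len(filaments) if filaments else float("nan")
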