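"""Synthetic TIRF image and movie generator with exact ground truth.

Renders fluorescent filaments (stabilized microtubule seeds and dynamic
microtubules) as chains of 2D Gaussians placed densely along a line or a
3rd-order polynomial path, adds a constant background, and draws per-pixel
Poisson counts calibrated so that the measured filament signal-to-noise
ratio (mean over standard deviation of intensities along a line scan of the
background-subtracted image) matches a requested target.

Coordinate convention: pixel centers at integer coordinates, origin (0, 0)
top-left, x rightward (columns), y downward (rows), 0-based.  ``image[y, x]``.

The Gaussian profile convention used throughout the package is
``exp(-dx^2/sx^2 - dy^2/sy^2)`` — the same functional form the fitting
models use — with ``sigma = FWHM / (2 sqrt(2 ln 2))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimImageConfig",
    "simulate_crossing_movie",
    "GroundTruthFilament",
    "GroundTruthTrajectory",
    "SimulatedMovie",
    "fwhm_to_sigma",
    "render_filament",
    "render_filaments",
    "apply_poisson_noise",
    "measure_snr",
    "random_seed_filaments",
    "simulate_movie",
]

# chain spacing for *rendering*, as a fraction of the smaller PSF sigma;
# deliberately finer than the fit-time spacing so rendering discretization
# is negligible against localization error
RENDER_SPACING_FRACTION = 1.0 / 3.0


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a full width at half maximum to the Gaussian sigma."""
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class SimImageConfig:
    """Geometry, optics and intensity settings for one synthetic image.

    Parameters
    ----------
    width_px, height_px :
        Image size in pixels (each at least 16).
    pixel_size_nm :
        Physical pixel size, nm per pixel.
    psf_sigma_px :
        ``(sigma_x, sigma_y)`` of the PSF Gaussian in pixels, in the
        ``exp(-dx^2/sx^2)`` convention.
    background :
        Constant background level (Poisson-mean units after calibration).
    amplitude :
        Ridge intensity of a rendered filament in the noiseless image.
    target_snr :
        Desired measured SNR of the filament ridge after Poisson noise.
    rng_seed :
        Seed for all stochastic draws tied to this configuration.
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_nm: float = 156.0
    psf_sigma_px: tuple[float, float] = (
        fwhm_to_sigma(199.0) / 156.0,
        fwhm_to_sigma(199.0) / 156.0,
    )
    background: float = 20.0
    amplitude: float = 100.0
    target_snr: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 16 or self.height_px < 16:
            raise ValueError("image must be at least 16x16 pixels")
        if min(self.psf_sigma_px) <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if self.target_snr <= 0:
            raise ValueError("target_snr must be positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")


@dataclass
class GroundTruthFilament:
    """A filament path y = f(x) with exact endpoints and contour length.

    ``coefficients`` are ``(m, c)`` for a line (y = m x + c) or
    ``(I, b, m, c)`` for a cubic (y = I x^3 + b x^2 + m x + c), in pixel
    coordinates.  When ``swap_xy`` is true the roles of x and y are
    exchanged (x = f(y)), which lets the generator cover steep orientations
    without ill-conditioned slopes.
    """

    path_kind: str  # {"line", "cubic"}
    coefficients: tuple[float, ...]
    start_x: float
    end_x: float
    swap_xy: bool = False

    def __post_init__(self) -> None:
        if self.path_kind not in ("line", "cubic"):
            raise ValueError(f"unknown path_kind {self.path_kind!r}")
        n = {"line": 2, "cubic": 4}[self.path_kind]
        if len(self.coefficients) != n:
            raise ValueError("coefficient count does not match path_kind")

    # -- path geometry -----------------------------------------------------

    def _poly(self) -> np.polynomial.Polynomial:
        if self.path_kind == "line":
            m, c = self.coefficients
            return np.polynomial.Polynomial([c, m])
        i3, b, m, c = self.coefficients
        return np.polynomial.Polynomial([c, m, b, i3])

    def point(self, x: float | np.ndarray) -> np.ndarray:
        """Path point(s) in image coordinates for parameter value(s) x."""
        y = self._poly()(x)
        pts = np.stack(np.broadcast_arrays(x, y), axis=-1).astype(float)
        if self.swap_xy:
            pts = pts[..., ::-1]
        return pts

    def tangent(self, x: float) -> np.ndarray:
        """Unit tangent at parameter x, oriented from start to end."""
        slope = self._poly().deriv()(x)
        t = np.array([1.0, slope]) / math.hypot(1.0, slope)
        if self.end_x < self.start_x:
            t = -t
        if self.swap_xy:
            t = t[::-1]
        return t

    @property
    def true_endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        return self.point(self.start_x), self.point(self.end_x)

    @property
    def true_contour_length_px(self) -> float:
        from scipy.integrate import quad

        dpoly = self._poly().deriv()
        val, _ = quad(lambda x: math.hypot(1.0, dpoly(x)),
                      min(self.start_x, self.end_x),
                      max(self.start_x, self.end_x), limit=200)
        return val

    def sample_arc(self, spacing: float) -> np.ndarray:
        """Points along the path at (approximately) equal arc spacing.

        Steps the path parameter by ``spacing / sqrt(1 + f'(x)^2)`` so
        successive points are ``spacing`` apart in arc length; always
        includes both endpoints.
        """
        if spacing <= 0:
            raise ValueError("spacing must be positive")
        dpoly = self._poly().deriv()
        sgn = 1.0 if self.end_x >= self.start_x else -1.0
        xs = [self.start_x]
        x = self.start_x
        # cap iterations defensively for pathological spacing
        for _ in range(int(1e6)):
            x = x + sgn * spacing / math.hypot(1.0, dpoly(x))
            if sgn * (x - self.end_x) >= 0:
                break
            xs.append(x)
        xs.append(self.end_x)
        return self.point(np.asarray(xs))

    def truncated(self, arc_length: float) -> "GroundTruthFilament":
        """The sub-filament covering the first ``arc_length`` px of path."""
        if arc_length <= 0:
            return replace(self, end_x=self.start_x)
        dpoly = self._poly().deriv()
        sgn = 1.0 if self.end_x >= self.start_x else -1.0
        x, s = self.start_x, 0.0
        step = 0.05
        while s < arc_length:
            dx = step / math.hypot(1.0, dpoly(x))
            x += sgn * dx
            s += step
        return replace(self, end_x=x)


# ---------------------------------------------------------------------------
# rendering


def _accumulate_gaussians(img: np.ndarray, centers: np.ndarray,
                          sx: float, sy: float) -> None:
    """Add unit-amplitude Gaussians exp(-dx^2/sx^2 - dy^2/sy^2) in place."""
    h, w = img.shape
    rx = max(2, int(math.ceil(4.0 * sx)))
    ry = max(2, int(math.ceil(4.0 * sy)))
    for cx, cy in centers:
        x0, x1 = int(math.floor(cx)) - rx, int(math.floor(cx)) + rx + 1
        y0, y1 = int(math.floor(cy)) - ry, int(math.floor(cy)) + ry + 1
        x0, x1 = max(x0, 0), min(x1, w)
        y0, y1 = max(y0, 0), min(y1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        xg = np.arange(x0, x1, dtype=float)
        yg = np.arange(y0, y1, dtype=float)
        gx = np.exp(-((xg - cx) ** 2) / sx**2)
        gy = np.exp(-((yg - cy) ** 2) / sy**2)
        img[y0:y1, x0:x1] += gy[:, None] * gx[None, :]


def _chain_ridge_value(centers: np.ndarray, sx: float, sy: float) -> float:
    """Continuous-space chain intensity at the mid-chain sample point."""
    mid = centers[len(centers) // 2]
    d = centers - mid
    return float(np.exp(-(d[:, 0] ** 2) / sx**2 - (d[:, 1] ** 2) / sy**2).sum())


def render_filaments(config: SimImageConfig,
                     filaments: list[GroundTruthFilament]) -> np.ndarray:
    """Noiseless image: background plus normalized Gaussian chains.

    Each filament is a chain of PSF-width Gaussians at arc spacing
    ``sigma/3``, scaled so the continuous ridge intensity equals
    ``config.amplitude``.  Raises if any path leaves the image bounds.
    """
    sx, sy = config.psf_sigma_px
    img = np.full((config.height_px, config.width_px), float(config.background))
    spacing = min(sx, sy) * RENDER_SPACING_FRACTION
    for fil in filaments:
        centers = fil.sample_arc(spacing)
        if (centers[:, 0].min() < 0 or centers[:, 1].min() < 0
                or centers[:, 0].max() > config.width_px - 1
                or centers[:, 1].max() > config.height_px - 1):
            raise ValueError("filament path lies outside the image bounds")
        chain = np.zeros_like(img)
        _accumulate_gaussians(chain, centers, sx, sy)
        ridge = _chain_ridge_value(centers, sx, sy)
        img += chain * (config.amplitude / ridge)
    return img


def render_filament(config: SimImageConfig,
                    filament: GroundTruthFilament) -> np.ndarray:
    """Noiseless image of a single filament (see :func:`render_filaments`)."""
    return render_filaments(config, [filament])


# ---------------------------------------------------------------------------
# noise


def apply_poisson_noise(image: np.ndarray, target_snr: float,
                        rng_seed: int, background: float = 0.0) -> np.ndarray:
    """Poisson-noisy realization of ``image`` calibrated to ``target_snr``.

    The whole image (signal + background) is scaled by a single factor k so
    that, with ridge signal R = k * max(image - background) and background
    counts B = k * background, the measured ridge SNR after background
    subtraction, R / sqrt(R + B), equals ``target_snr``.  On zero background
    this reduces to the Poisson identity SNR = sqrt(R), i.e. a ridge mean of
    ``target_snr**2`` counts.  Deterministic for a given ``rng_seed``.
    """
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("image must be non-negative")
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    amp = float(np.max(image - background))
    if amp <= 0:
        raise ValueError("image has no signal above the background")
    k = target_snr**2 * (amp + background) / amp**2
    rng = np.random.default_rng(rng_seed)
    return rng.poisson(k * image).astype(float)


def measure_snr(image: np.ndarray, line_scan: np.ndarray) -> float:
    """SNR = mean / std of intensities sampled along a line scan.

    ``line_scan`` is an (N, 2) array of (x, y) coordinates (N >= 10) on a
    background-subtracted image; samples are bilinearly interpolated.
    Returns ``inf`` when the scan has zero variance (undefined SNR is
    signalled distinctly from failure).
    """
    from scipy.ndimage import map_coordinates

    pts = np.asarray(line_scan, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 10:
        raise ValueError("line_scan must be an (N>=10, 2) array of (x, y)")
    # pixel intensities along the scan (nearest pixel, no interpolation:
    # interpolating would average noise and inflate the measured SNR)
    vals = map_coordinates(np.asarray(image, dtype=float),
                           [pts[:, 1], pts[:, 0]], order=0, mode="nearest")
    sd = float(np.std(vals))
    if sd == 0.0:
        return float("inf")
    return float(np.mean(vals)) / sd


# ---------------------------------------------------------------------------
# random layouts


def _segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between two 2D segments."""

    def pt_seg(p, a, b):
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0, 1))
        return float(np.linalg.norm(p - (a + t * ab)))

    d1, d2 = p2 - p1, q2 - q1
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) > 1e-12:
        r = q1 - p1
        t = (r[0] * d2[1] - r[1] * d2[0]) / denom
        u = (r[0] * d1[1] - r[1] * d1[0]) / denom
        if 0 <= t <= 1 and 0 <= u <= 1:
            return 0.0
    return min(pt_seg(p1, q1, q2), pt_seg(p2, q1, q2),
               pt_seg(q1, p1, p2), pt_seg(q2, p1, p2))


def _line_filament_from_endpoints(p0: np.ndarray,
                                  p1: np.ndarray) -> GroundTruthFilament:
    d = p1 - p0
    swap = abs(d[1]) > abs(d[0])
    if swap:
        p0, p1 = p0[::-1], p1[::-1]
        d = d[::-1]
    m = d[1] / d[0]
    c = p0[1] - m * p0[0]
    return GroundTruthFilament("line", (float(m), float(c)),
                               float(p0[0]), float(p1[0]), swap_xy=swap)


def random_seed_filaments(config: SimImageConfig, n: int,
                          length_range: tuple[float, float] = (20.0, 60.0),
                          min_separation: float = 5.0,
                          margin: float = 8.0,
                          rng: np.random.Generator | None = None,
                          ) -> list[GroundTruthFilament]:
    """Straight seed filaments with random position/orientation/length.

    Rejection-samples segments until all pairwise segment-to-segment
    distances exceed ``min_separation`` (the regime in which one-to-one
    detection is expected to be near perfect).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    placed: list[tuple[np.ndarray, np.ndarray]] = []
    out: list[GroundTruthFilament] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place seeds at requested density")
        length = rng.uniform(*length_range)
        theta = rng.uniform(0, math.pi)
        cx = rng.uniform(margin, config.width_px - 1 - margin)
        cy = rng.uniform(margin, config.height_px - 1 - margin)
        d = np.array([math.cos(theta), math.sin(theta)]) * (length / 2)
        p0, p1 = np.array([cx, cy]) - d, np.array([cx, cy]) + d
        if (min(p0.min(), p1.min()) < margin
                or max(p0[0], p1[0]) > config.width_px - 1 - margin
                or max(p0[1], p1[1]) > config.height_px - 1 - margin):
            continue
        if any(_segment_distance(p0, p1, q0, q1) <= min_separation
               for q0, q1 in placed):
            continue
        placed.append((p0, p1))
        out.append(_line_filament_from_endpoints(p0, p1))
    return out


# ---------------------------------------------------------------------------
# dynamic movies


@dataclass
class GroundTruthTrajectory:
    """Per-frame ground truth for one dynamic filament.

    ``lengths_px`` is the contour length of the dynamic extension beyond the
    seed end; ``phases`` labels the interval *ending* at each frame
    ('growth' or 'shrink'; index 0 repeats the initial phase).  ``tips``
    holds the exact subpixel tip coordinate per frame.
    """

    times: np.ndarray          # s
    lengths_px: np.ndarray
    phases: list[str]
    tips: np.ndarray           # (T, 2) of (x, y)
    event_times: np.ndarray    # s, switching times within the movie
    event_kinds: list[str]     # 'catastrophe' | 'rescue' | 'total_catastrophe'
    true_vg: float             # nm/s
    true_vs: float
    true_fc: float             # 1/s
    true_fr: float
    pixel_size_nm: float = 156.0

    @property
    def lengths_nm(self) -> np.ndarray:
        return self.lengths_px * self.pixel_size_nm


def simulate_length_trajectory(vg: float, vs: float, fc: float, fr: float,
                               n_frames: int, frame_interval: float,
                               rng: np.random.Generator,
                               initial_length: float = 0.0,
                               max_length: float = math.inf,
                               ) -> tuple[np.ndarray, np.ndarray, list[str],
                                          np.ndarray, list[str]]:
    """Two-state telegraph length process sampled at frame times.

    Growth at speed ``vg`` switches to shrinkage with rate ``fc``;
    shrinkage at ``vs`` switches back with rate ``fr``; hitting zero length
    is a total catastrophe that restarts growth.  All speeds/lengths share
    one unit system (px or nm).  Returns (times, lengths, phase-per-frame,
    event_times, event_kinds).
    """
    if vg <= 0 or vs <= 0:
        raise ValueError("vg and vs must be positive")
    if fc < 0 or fr < 0:
        raise ValueError("fc and fr must be non-negative")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    t_end = (n_frames - 1) * frame_interval
    # piecewise-linear segments: (t0, L0, rate)
    seg_t = [0.0]
    seg_len = [initial_length]
    seg_rate = []
    ev_t: list[float] = []
    ev_k: list[str] = []
    t, length, growing = 0.0, initial_length, True
    while t < t_end:
        if growing:
            wait = rng.exponential(1.0 / fc) if fc > 0 else math.inf
            if max_length < math.inf:
                wait = min(wait, (max_length - length) / vg)
            t2 = min(t + wait, t_end)
            length2 = length + vg * (t2 - t)
            seg_rate.append(vg)
            if t2 < t_end:
                ev_t.append(t2)
                ev_k.append("catastrophe")
                growing = False
        else:
            wait = rng.exponential(1.0 / fr) if fr > 0 else math.inf
            t_zero = length / vs
            if t_zero <= wait:  # total catastrophe
                t2 = min(t + t_zero, t_end)
                kind = "total_catastrophe"
            else:
                t2 = min(t + wait, t_end)
                kind = "rescue"
            length2 = max(0.0, length - vs * (t2 - t))
            seg_rate.append(-vs)
            if t2 < t_end:
                ev_t.append(t2)
                ev_k.append(kind)
                growing = True
        t, length = t2, length2
        seg_t.append(t)
        seg_len.append(length)
    times = np.arange(n_frames) * frame_interval
    lengths = np.interp(times, seg_t, seg_len)
    # phase of the interval ending at each frame
    phases = []
    for k, tk in enumerate(times):
        tq = max(tk - frame_interval / 2, 0.0) if k else 0.0
        j = int(np.searchsorted(seg_t, tq, side="right")) - 1
        j = min(max(j, 0), len(seg_rate) - 1)
        phases.append("growth" if seg_rate[j] > 0 else "shrink")
    return times, lengths, phases, np.asarray(ev_t), ev_k


@dataclass
class SimulatedMovie:
    """A seed-channel frame plus dynamic-channel stack with ground truth."""

    config: SimImageConfig
    seed_image: np.ndarray           # noisy seed channel
    seed_image_clean: np.ndarray
    frames: np.ndarray               # (T, H, W) noisy dynamic channel
    frames_clean: np.ndarray
    seed_filaments: list[GroundTruthFilament]
    growth_paths: list[GroundTruthFilament]   # full path each tip follows
    trajectories: list[GroundTruthTrajectory]
    frame_interval_s: float = 1.0


def _growth_path_for_seed(seed: GroundTruthFilament, cfg: SimImageConfig,
                          kind: str, rng: np.random.Generator,
                          max_extent: float) -> GroundTruthFilament:
    """Path the dynamic tip follows, starting at the seed's end point.

    For ``kind='line'`` this is the seed's own line extended; for
    ``kind='cubic'`` a gentle random curvature/inflection is added in the
    seed-aligned frame so the path stays tangent to the seed at its end.
    """
    p_end = seed.point(seed.end_x)
    tang = seed.tangent(seed.end_x)
    if kind == "line":
        p_far = p_end + tang * max_extent
        path = _line_filament_from_endpoints(p_end, p_far)
        return path
    if kind != "cubic":
        raise ValueError(f"unknown growth path kind {kind!r}")
    # build in the (possibly swapped) frame of the seed's parametrization
    swap = abs(tang[1]) > abs(tang[0])
    e, tg = (p_end[::-1], tang[::-1]) if swap else (p_end, tang)
    sgn = 1.0 if tg[0] >= 0 else -1.0
    slope = tg[1] / tg[0]
    b = rng.uniform(-0.004, 0.004)
    i3 = rng.uniform(-6e-5, 6e-5)
    # tangent continuity at the seed end: slope of cubic at e.x equals slope
    m = slope - 2 * b * e[0] - 3 * i3 * e[0] ** 2
    c = e[1] - i3 * e[0] ** 3 - b * e[0] ** 2 - m * e[0]
    return GroundTruthFilament("cubic", (i3, b, m, c), float(e[0]),
                               float(e[0] + sgn * max_extent), swap_xy=swap)


def simulate_movie(config: SimImageConfig, vg: float, vs: float, fc: float,
                   fr: float, n_frames: int, frame_interval: float,
                   n_filaments: int = 1, path_kind: str = "line",
                   seed_length_range: tuple[float, float] = (12.0, 20.0),
                   initial_length_px: float = 3.0,
                   min_separation: float = 12.0) -> SimulatedMovie:
    """Simulate a two-channel experiment: static seeds + dynamic movie.

    ``vg``/``vs`` in nm/s, ``fc``/``fr`` in 1/s, ``frame_interval`` in s.
    Each seed nucleates one dynamic microtubule at its end, whose length
    follows the two-state telegraph process; frames are rendered with the
    same PSF/amplitude settings as the seed channel and Poisson noise at
    ``config.target_snr``.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    rng = np.random.default_rng(config.rng_seed)
    margin = 10.0
    max_extent_px = (vg * frame_interval * n_frames) / config.pixel_size_nm \
        + initial_length_px + 5.0

    # place seeds so that the full growth corridor stays inside the image
    seeds: list[GroundTruthFilament] = []
    paths: list[GroundTruthFilament] = []
    segs: list[tuple[np.ndarray, np.ndarray]] = []
    attempts = 0
    while len(seeds) < n_filaments:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place filaments at this density")
        cand = random_seed_filaments(
            config, 1, length_range=seed_length_range,
            min_separation=0.0, margin=margin, rng=rng)[0]
        path = _growth_path_for_seed(cand, config, path_kind, rng,
                                     max_extent_px)
        pts = path.sample_arc(1.0)
        if (pts[:, 0].min() < margin or pts[:, 1].min() < margin
                or pts[:, 0].max() > config.width_px - 1 - margin
                or pts[:, 1].max() > config.height_px - 1 - margin):
            continue
        a0, a1 = cand.true_endpoints
        corridor = (np.minimum(pts.min(axis=0), np.minimum(a0, a1)),
                    np.maximum(pts.max(axis=0), np.maximum(a0, a1)))
        ok = True
        for b0, b1 in segs:
            # conservative corridor separation via bounding boxes
            gap_x = max(b0[0] - corridor[1][0], corridor[0][0] - b1[0])
            gap_y = max(b0[1] - corridor[1][1], corridor[0][1] - b1[1])
            if max(gap_x, gap_y) <= min_separation:
                ok = False
                break
        if not ok:
            continue
        segs.append(corridor)
        seeds.append(cand)
        paths.append(path)

    seed_clean = render_filaments(config, seeds)
    seed_noisy = apply_poisson_noise(seed_clean, config.target_snr,
                                     int(rng.integers(2**31)),
                                     background=config.background)

    vg_px = vg / config.pixel_size_nm
    vs_px = vs / config.pixel_size_nm
    trajectories = []
    for path in paths:
        times, lengths, phases, ev_t, ev_k = simulate_length_trajectory(
            vg_px, vs_px, fc, fr, n_frames, frame_interval, rng,
            initial_length=initial_length_px,
            max_length=path.true_contour_length_px - 1.0)
        tips = np.array([path.truncated(l).point(
            path.truncated(l).end_x) for l in lengths])
        trajectories.append(GroundTruthTrajectory(
            times=times, lengths_px=lengths, phases=phases, tips=tips,
            event_times=ev_t, event_kinds=ev_k, true_vg=vg, true_vs=vs,
            true_fc=fc, true_fr=fr, pixel_size_nm=config.pixel_size_nm))

    frames_clean = np.empty((n_frames, config.height_px, config.width_px))
    frames_noisy = np.empty_like(frames_clean)
    for k in range(n_frames):
        fils = []
        for path, traj in zip(paths, trajectories):
            L = traj.lengths_px[k]
            if L > 0.5:  # sub-half-pixel stubs are not rendered
                fils.append(path.truncated(L))
        if fils:
            clean = render_filaments(config, fils)
        else:
            clean = np.full((config.height_px, config.width_px),
                            float(config.background))
        frames_clean[k] = clean
        if clean.max() > config.background:
            frames_noisy[k] = apply_poisson_noise(
                clean, config.target_snr, int(rng.integers(2**31)),
                background=config.background)
        else:
            scale = (config.target_snr**2
                     * (config.amplitude + config.background)
                     / config.amplitude**2)
            frames_noisy[k] = np.random.default_rng(
                int(rng.integers(2**31))).poisson(
                    scale * clean).astype(float)
    return SimulatedMovie(
        config=config, seed_image=seed_noisy, seed_image_clean=seed_clean,
        frames=frames_noisy, frames_clean=frames_clean,
        seed_filaments=seeds, growth_paths=paths, trajectories=trajectories,
        frame_interval_s=frame_interval)


def simulate_crossing_movie(config: SimImageConfig, angle_deg: float,
                            vg: float, n_frames: int,
                            frame_interval: float = 1.0,
                            seed_length_px: float = 14.0,
                            initial_length_px: float = 4.0) -> SimulatedMovie:
    """Two straight microtubules growing through a crossing point.

    The two growth paths intersect at the image centre at ``angle_deg``
    (30-90 degrees is the interesting regime); both filaments grow at
    ``vg`` nm/s without catastrophes and pass through the crossing during
    the movie, which exercises the collision-handling logic of a tracker.
    """
    rng = np.random.default_rng(config.rng_seed)
    centre = np.array([config.width_px / 2.0, config.height_px / 2.0])
    base = rng.uniform(0, math.pi)
    total_growth_px = (vg * frame_interval * n_frames) / config.pixel_size_nm \
        + initial_length_px
    reach = total_growth_px * 0.6 + seed_length_px
    seeds, paths, trajectories = [], [], []
    for k, ang in enumerate((base, base + math.radians(angle_deg))):
        u = np.array([math.cos(ang), math.sin(ang)])
        # seed placed so the tip reaches the crossing mid-movie
        seed_far = centre - u * (total_growth_px * 0.5)
        seed_near = seed_far - u * seed_length_px
        seed = _line_filament_from_endpoints(seed_near, seed_far)
        path = _line_filament_from_endpoints(seed_far, seed_far + u * reach)
        pts = path.sample_arc(1.0)
        if (pts.min() < 6 or pts[:, 0].max() > config.width_px - 7
                or pts[:, 1].max() > config.height_px - 7):
            raise ValueError("image too small for this crossing geometry")
        seeds.append(seed)
        paths.append(path)
    vg_px = vg / config.pixel_size_nm
    n = n_frames
    times = np.arange(n) * frame_interval
    for path in paths:
        lengths = initial_length_px + vg_px * times
        tips = np.array([path.truncated(l).point(path.truncated(l).end_x)
                         for l in lengths])
        trajectories.append(GroundTruthTrajectory(
            times=times, lengths_px=lengths, phases=["growth"] * n,
            tips=tips, event_times=np.array([]), event_kinds=[],
            true_vg=vg, true_vs=0.0, true_fc=0.0, true_fr=0.0,
            pixel_size_nm=config.pixel_size_nm))
    seed_clean = render_filaments(config, seeds)
    seed_noisy = apply_poisson_noise(seed_clean, config.target_snr,
                                     int(rng.integers(2**31)),
                                     background=config.background)
    frames_clean = np.empty((n, config.height_px, config.width_px))
    frames_noisy = np.empty_like(frames_clean)
    for k in range(n):
        fils = [path.truncated(traj.lengths_px[k])
                for path, traj in zip(paths, trajectories)]
        frames_clean[k] = render_filaments(config, fils)
        frames_noisy[k] = apply_poisson_noise(
            frames_clean[k], config.target_snr, int(rng.integers(2**31)),
            background=config.background)
    return SimulatedMovie(
        config=config, seed_image=seed_noisy, seed_image_clean=seed_clean,
        frames=frames_noisy, frames_clean=frames_clean,
        seed_filaments=seeds, growth_paths=paths,
        trajectories=trajectories, frame_interval_s=frame_interval)
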