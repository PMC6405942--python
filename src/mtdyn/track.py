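"""Frame-by-frame tracking of dynamic microtubules growing from seeds.

Each tracked seed end owns one track.  Per frame, MSER re-detects bright
regions in the dynamic channel; the track's growth direction (tangent of
the previous polynomial at its tip) is projected from the fixed seed end
to find the candidate region and an end-point guess on its far boundary;
the cubic sum-of-Gaussians model is then fit with the start pinned to the
seed end, the step is validated against sudden direction/shape changes
(collision handling), and the tip is refined with the Gaussian mask fit.
The output is contour length versus time per seed end.

Steep paths (|direction_y| > |direction_x|) are fit in the x<->y swapped
frame, so the cubic y(x) parametrization stays well conditioned at every
orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .mser import EllipseRegion, MserConfig, detect_mser_regions
from .models import (LMConfig, PolySoGModel, contour_length,
                     dense_model_image, fit_model_multiscale,
                     gaussian_mask_refine)

logger = logging.getLogger(__name__)

__all__ = ["TrackConfig", "TrackPoint", "Track", "initialize_guess",
           "resolve_multi_region", "validate_step", "track_movie"]


@dataclass(frozen=True)
class TrackConfig:
    pixel_size_nm: float = 156.0
    frame_interval_s: float = 1.0
    psf_sigma_px: tuple[float, float] = (0.542, 0.542)
    mser: MserConfig = field(default_factory=MserConfig)
    # per-frame fits start close to the optimum (warm-started from the
    # previous frame), so a short cascade and iteration cap suffice
    lm: LMConfig = field(default_factory=lambda: LMConfig(max_iter=40))
    blur_sigmas: tuple[float, ...] = (1.5, 0.0)
    angular_threshold_deg: float = 20.0
    max_gap: int = 5
    intensity_frac: float = 0.5       # boundary-point intensity gate
    poly_jump_sigmas: float = 10.0    # |db|,|dI| vs their running std
    # a dynamic microtubule is anchored at its seed: candidate regions must
    # first intersect the projection ray within this distance of the seed
    # end (distant specks would otherwise blow up the fit window)
    max_first_hit_px: float = 8.0
    window_dilation_sigmas: float = 3.0
    mask_tol: float = 1e-3
    mask_max_iter: int = 50
    # below this filament length the cubic terms are unconstrained and are
    # frozen at zero (straight fit); the tangent then equals the chord
    min_cubic_length_px: float = 10.0


@dataclass
class TrackPoint:
    frame: int
    time_s: float
    x: float
    y: float
    length_nm: float
    ok: bool                      # mask refinement succeeded
    b: float
    curve_I: float
    m: float
    c: float
    direction_deg: float          # tip tangent, image frame
    swap_xy: bool


@dataclass
class Track:
    seed_id: int
    end_label: str                          # "end_A" | "end_B"
    start: np.ndarray                       # fixed seed end (x, y)
    initial_direction: np.ndarray           # outward unit vector
    points: list[TrackPoint] = field(default_factory=list)
    n_gaps: int = 0
    closed: bool = False

    @property
    def last_point(self) -> TrackPoint | None:
        return self.points[-1] if self.points else None


# ---------------------------------------------------------------------------
# per-frame geometry helpers


def _ray_points(start, direction, length, spacing=0.5):
    t = np.arange(0.0, length, spacing)
    return start[None, :] + t[:, None] * direction[None, :]


def initialize_guess(start: np.ndarray, direction: np.ndarray,
                     region: EllipseRegion, image: np.ndarray,
                     intensity_frac: float = 0.5) -> np.ndarray | None:
    """End-point guess: far intersection of the projected ray with a region.

    Samples the ray cast from the fixed seed end along the previous growth
    direction; of the samples falling inside the region whose intensity
    exceeds ``intensity_frac`` of the region's maximum, the farthest one is
    the guess.  Returns None (caller records a gap) when the ray misses the
    region or all ray samples are dimmer than the gate.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    mask = np.zeros((h, w), dtype=bool)
    mask[region.pixels[:, 1], region.pixels[:, 0]] = True
    # robust maximum: where two filaments overlap in one region the few
    # overlap pixels have ~double intensity and would push the 50% gate
    # above the single-filament ridge level
    reg_max = float(np.percentile(
        img[region.pixels[:, 1], region.pixels[:, 0]], 95.0))
    ray = _ray_points(start, direction, length=float(np.hypot(h, w)))
    xi = np.round(ray[:, 0]).astype(int)
    yi = np.round(ray[:, 1]).astype(int)
    ok = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
    ray, xi, yi = ray[ok], xi[ok], yi[ok]
    inside = mask[yi, xi]
    bright = inside & (img[yi, xi] >= intensity_frac * reg_max)
    if not bright.any():
        return None
    # keep only the first contiguous intersection of the ray with the
    # region: when two filaments share one region the ray can re-enter it
    # where it crosses the *other* filament, which must not set the guess
    idx = np.nonzero(bright)[0]
    run_end = idx[0]
    for k in range(1, idx.size):
        if (idx[k] - run_end) * 0.5 > 3.0:   # >3 px of non-filament pixels
            break
        run_end = idx[k]
    return ray[run_end]


def resolve_multi_region(last_endpoint: np.ndarray,
                         fits: list[tuple[np.ndarray, object]]):
    """Among candidate fits, keep the endpoint nearest the last known one."""
    if not fits:
        return None
    return min(fits, key=lambda f: float(np.linalg.norm(f[0] - last_endpoint)))


def validate_step(prev_direction_deg: float, new_direction_deg: float,
                  b_history: list[float], I_history: list[float],
                  b_new: float, I_new: float,
                  angular_threshold_deg: float = 20.0,
                  poly_jump_sigmas: float = 10.0) -> bool:
    """Reject fits that flip direction or jump in shape between frames.

    The angular change of the tip direction must stay below the threshold
    (default 20 degrees); with enough history, the curvature/inflection
    coefficients must stay within ``poly_jump_sigmas`` running standard
    deviations of their track history.
    """
    d = abs(new_direction_deg - prev_direction_deg) % 360.0
    d = min(d, 360.0 - d)
    if d > angular_threshold_deg:
        return False
    if len(b_history) >= 5:
        sb = float(np.std(b_history)) + 1e-4
        sI = float(np.std(I_history)) + 1e-6
        if (abs(b_new - float(np.mean(b_history))) > poly_jump_sigmas * sb
                or abs(I_new - float(np.mean(I_history)))
                > poly_jump_sigmas * sI):
            return False
    return True


# ---------------------------------------------------------------------------
# the per-frame fit (possibly in the swapped frame)


def _fit_in_region(image, track: Track, region: EllipseRegion, guess,
                   prev, config: TrackConfig):
    """Fit the cubic SoG with the start pinned at the seed end.

    Returns (tip_xy, info dict) in image coordinates, or None.
    ``prev`` is the previous accepted TrackPoint (or None on the first
    frame, where the polynomial coefficients start at zero).
    """
    sx, sy = config.psf_sigma_px
    start = track.start
    d_guess = guess - start
    swap = abs(d_guess[1]) > abs(d_guess[0])
    img = np.asarray(image, dtype=float)
    if swap:
        img_f = img.T
        start_f = start[::-1]
        guess_f = guess[::-1]
        sig = (sy, sx)
        reg_pix = region.pixels[:, ::-1]
    else:
        img_f = img
        start_f = start
        guess_f = guess
        sig = (sx, sy)
        reg_pix = region.pixels
    if abs(guess_f[0] - start_f[0]) < 1.0:
        return None   # degenerate even after swapping

    pad = int(math.ceil(config.window_dilation_sigmas * max(sig))) + 2
    xs_all = np.concatenate([reg_pix[:, 0], [start_f[0], guess_f[0]]])
    ys_all = np.concatenate([reg_pix[:, 1], [start_f[1], guess_f[1]]])
    window = (int(xs_all.min()) - pad, int(ys_all.min()) - pad,
              int(xs_all.max()) + pad + 1, int(ys_all.max()) + pad + 1)

    wx0, wy0 = max(window[0], 0), max(window[1], 0)
    wx1, wy1 = min(window[2], img_f.shape[1]), min(window[3], img_f.shape[0])
    sub = img_f[wy0:wy1, wx0:wx1]
    if sub.size < 16:
        return None
    bg0 = float(np.median(sub))
    amp0 = max(float(sub.max()) - bg0, 1e-6)

    if prev is not None and prev.swap_xy == swap:
        b0, i0 = prev.b, prev.curve_I
    else:
        b0, i0 = 0.0, 0.0   # first frame: polynomial coefficients at zero
    ds0 = sig[0]
    a0 = amp0 * ds0 / (math.sqrt(math.pi) * sig[0])
    chord = float(np.hypot(guess_f[0] - start_f[0], guess_f[1] - start_f[1]))
    short = chord < config.min_cubic_length_px
    if short:
        b0, i0 = 0.0, 0.0
    theta0 = np.array([guess_f[0], guess_f[1], ds0, a0, bg0, b0, i0])
    model = PolySoGModel(start=(float(start_f[0]), float(start_f[1])),
                         sigma=sig)
    free = np.ones(7, dtype=bool)
    if short:
        free[5] = free[6] = False
    try:
        res = fit_model_multiscale(model, theta0, img_f, window, config.lm,
                                   blur_sigmas=config.blur_sigmas,
                                   free_mask=free, polish_rounds=2,
                                   scan=(1.5, 0.5))
    except (ValueError, np.linalg.LinAlgError):
        return None
    if not np.all(np.isfinite(res.theta)):
        return None
    xe, ye, ds, A, Bg, b, I3 = res.theta
    m, c = model.m_c(res.theta)

    # tip tangent in the fit frame, oriented outward (start -> tip)
    slope = 3 * I3 * xe**2 + 2 * b * xe + m
    tang_f = np.array([1.0, slope]) / math.hypot(1.0, slope)
    if xe < start_f[0]:
        tang_f = -tang_f
    tip_f = np.array([xe, ye])

    # mask-fit refinement calibrated on the continuous-filament rendering
    model_img = dense_model_image(model, res.theta, img_f.shape,
                                  (wx0, wy0, wx1, wy1))
    mask_res = gaussian_mask_refine(img_f, tip_f, -tang_f, ds, sig,
                                    background=Bg, model_image=model_img,
                                    tol=config.mask_tol,
                                    max_iter=config.mask_max_iter)
    tip_ref_f = mask_res.position

    length_nm = contour_length((I3, b, m, c), float(start_f[0]),
                               float(tip_ref_f[0]), config.pixel_size_nm)
    tip = tip_ref_f[::-1] if swap else tip_ref_f
    tang = tang_f[::-1] if swap else tang_f
    info = dict(b=b, I=I3, m=m, c=c, swap=swap, ok=mask_res.refined,
                length_nm=length_nm, chi2=res.chi2,
                direction_deg=math.degrees(math.atan2(tang[1], tang[0])))
    return tip, info


# ---------------------------------------------------------------------------
# movie loop


def _track_direction(track: Track) -> float | None:
    p = track.last_point
    return p.direction_deg if p is not None else None


def track_movie(frames: np.ndarray, seeds, config: TrackConfig | None = None,
                both_ends: bool = False) -> list[Track]:
    """Track seed ends through a dynamic-channel stack.

    ``seeds`` is a list of :class:`mtdyn.detect.DetectedSeed` (or any
    object with ``seed_id``, ``endpoints`` (2, 2) and ``direction``).
    With ``both_ends`` both seed ends are tracked; otherwise end_B (the
    end toward which ``direction`` points).  Tracks that accumulate more
    than ``max_gap`` consecutive missed frames are closed.
    """
    if config is None:
        config = TrackConfig()
    tracks: list[Track] = []
    for s in seeds:
        ends = [("end_B", np.asarray(s.endpoints[1], float),
                 np.asarray(s.direction, float))]
        if both_ends:
            ends.append(("end_A", np.asarray(s.endpoints[0], float),
                         -np.asarray(s.direction, float)))
        for label, pt, u in ends:
            tracks.append(Track(seed_id=s.seed_id, end_label=label,
                                start=pt, initial_direction=u))

    frames = np.asarray(frames, dtype=float)
    n_frames = frames.shape[0]
    for k in range(n_frames):
        frame = frames[k]
        regions = detect_mser_regions(frame, config.mser)
        h, w = frame.shape
        lab = np.full((h, w), -1, dtype=int)
        for i, reg in enumerate(regions):
            lab[reg.pixels[:, 1], reg.pixels[:, 0]] = i
        t_s = k * config.frame_interval_s

        for track in tracks:
            if track.closed:
                continue
            prev = track.last_point
            if prev is not None:
                ang = math.radians(prev.direction_deg)
                direction = np.array([math.cos(ang), math.sin(ang)])
            else:
                direction = track.initial_direction
            # candidate regions: those the projected ray passes through,
            # anchored near the seed end (first intersection close by)
            ray = _ray_points(track.start, direction, float(np.hypot(h, w)))
            xi = np.round(ray[:, 0]).astype(int)
            yi = np.round(ray[:, 1]).astype(int)
            ok = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
            hits = lab[yi[ok], xi[ok]]
            first_hit: dict[int, float] = {}
            for idx_s in range(hits.size):
                v = int(hits[idx_s])
                if v >= 0 and v not in first_hit:
                    first_hit[v] = idx_s * 0.5
            cand_ids = sorted(v for v, d in first_hit.items()
                              if d <= config.max_first_hit_px)
            fits = []
            for ci in cand_ids:
                guess = initialize_guess(track.start, direction, regions[ci],
                                         frame, config.intensity_frac)
                if guess is None:
                    continue
                out = _fit_in_region(frame, track, regions[ci], guess, prev,
                                     config)
                if out is not None:
                    fits.append(out)
            last_tip = (np.array([prev.x, prev.y]) if prev is not None
                        else track.start)
            chosen = resolve_multi_region(last_tip, fits)
            accepted = False
            if chosen is not None:
                tip, info = chosen
                if prev is None:
                    accepted = True
                else:
                    accepted = validate_step(
                        prev.direction_deg, info["direction_deg"],
                        [p.b for p in track.points if p.swap_xy == info["swap"]],
                        [p.curve_I for p in track.points
                         if p.swap_xy == info["swap"]],
                        info["b"], info["I"],
                        config.angular_threshold_deg,
                        config.poly_jump_sigmas)
            if accepted:
                track.points.append(TrackPoint(
                    frame=k, time_s=t_s, x=float(tip[0]), y=float(tip[1]),
                    length_nm=float(info["length_nm"]), ok=bool(info["ok"]),
                    b=float(info["b"]), curve_I=float(info["I"]),
                    m=float(info["m"]), c=float(info["c"]),
                    direction_deg=float(info["direction_deg"]),
                    swap_xy=bool(info["swap"])))
                track.n_gaps = 0
            else:
                track.n_gaps += 1
                if track.points and track.n_gaps > config.max_gap:
                    track.closed = True
                    logger.info("track %s/%s closed after %d gaps",
                                track.seed_id, track.end_label, track.n_gaps)
    return tracks
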