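"""Dynamic-instability analysis of length-versus-time tracks.

A microtubule track alternates between growth phases (slow, near-linear
polymerization) and much faster shrinkage phases.  Events are segmented by
iterative RANSAC with robust outlier removal: the largest consecutive run
of points consistent with a near-linear (ridge-regularized cubic) growth
model is found, its inliers removed from the sampling set, and the search
repeated until no further growth event remains; shrinkage events are then
found among the leftover points with a line constrained to fast decline.
Each event is finalized by a plain linear fit to its inliers.

From the events the four parameters of dynamic instability follow:

* vg, vs — mean growth / shrinkage speed (nm/s) over events,
* fc — catastrophe frequency: shrinkage events per time spent growing,
* fr — rescue frequency: rescues per time spent shrinking.

Shrinkage that returns all the way to the seed baseline is a *total
catastrophe* (the subsequent regrowth is re-nucleation from the seed, not
a rescue), and is bookkept separately from rescues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "plot_track_events",
    "RansacConfig",
    "Event",
    "DynamicsSummary",
    "estimate_noise",
    "find_growth_events",
    "find_shrink_events",
    "analyze_track",
    "compute_frequencies",
    "classify_transitions",
    "assign_polarity",
    "length_distribution",
]


@dataclass(frozen=True)
class RansacConfig:
    """Event-segmentation parameters.

    ``epsilon_nm`` is the inlier tolerance; when None it is estimated per
    track as 3x the localization noise derived from high-frequency
    residuals (second differences).  ``model_order`` (2 or 3) is the
    polynomial order of the growth model, ridge-regularized toward a line
    with weight ``linear_reg`` in normalized units; reported slopes always
    come from the final plain linear refit.  ``shrink_slope_nm_s`` < 0
    gates shrinkage events; when None it defaults to -2x the track's
    fitted growth speed.
    """

    epsilon_nm: float | None = None
    min_inliers: int = 5
    max_iterations: int = 500
    model_order: int = 3
    linear_reg: float = 1e3
    shrink_slope_nm_s: float | None = None
    min_event_frames: int = 3
    max_inlier_gap: int = 2       # missing frames allowed inside an event
    min_sample_span: int = 5      # frames a minimal sample must cover
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if self.model_order not in (2, 3):
            raise ValueError("model_order must be 2 or 3")
        if self.min_inliers < 2:
            raise ValueError("min_inliers must be at least 2")


@dataclass(eq=False)
class Event:
    kind: str                     # "growth" | "shrink"
    indices: np.ndarray           # time indices of inliers (sorted)
    t_start: float
    t_end: float
    slope: float                  # nm/s from the final linear fit
    intercept: float              # nm
    is_complete: bool = False

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def value_at(self, t: float) -> float:
        return self.intercept + self.slope * t


@dataclass
class DynamicsSummary:
    vg_mean: float
    vg_sd: float
    vs_mean: float
    vs_sd: float
    fc: float                     # 1/s; nan when undefined
    fr: float
    n_growth: int
    n_shrink: int
    n_rescues: int
    n_total_catastrophes: int
    total_growth_time: float
    total_shrink_time: float
    events: list[Event] = field(default_factory=list)


# ---------------------------------------------------------------------------
# noise / epsilon


def estimate_noise(lengths: np.ndarray) -> float:
    """Robust per-point noise from second differences.

    For a piecewise-linear signal with i.i.d. noise sigma, the second
    difference has std sqrt(6) sigma away from breakpoints; the median
    absolute value is robust to the sparse breakpoints.
    """
    d2 = np.diff(np.asarray(lengths, dtype=float), n=2)
    if d2.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d2))) / math.sqrt(6.0)


def _epsilon(lengths: np.ndarray, config: RansacConfig) -> float:
    if config.epsilon_nm is not None:
        return config.epsilon_nm
    eps = 3.0 * estimate_noise(lengths)
    return max(eps, 1e-6)


# ---------------------------------------------------------------------------
# RANSAC cores


def _longest_run(idx: np.ndarray, frames: np.ndarray, max_gap: int
                 ) -> np.ndarray:
    """Longest subsequence of idx whose frame numbers are quasi-consecutive."""
    if idx.size == 0:
        return idx
    runs = []
    start = 0
    for k in range(1, idx.size):
        if frames[idx[k]] - frames[idx[k - 1]] > max_gap + 1:
            runs.append(idx[start:k])
            start = k
    runs.append(idx[start:])
    return max(runs, key=len)


def _fit_regularized_poly(t: np.ndarray, y: np.ndarray, order: int,
                          reg: float) -> np.ndarray:
    """Ridge fit of y(t) penalizing all coefficients above the linear ones.

    Time and length are normalized to unit scale so the penalty weight is
    dimensionless; returns coefficients in the original units (highest
    order last, numpy Polynomial convention).
    """
    t0, ts = t.mean(), max(np.ptp(t), 1e-9)
    y0, ys = y.mean(), max(np.ptp(y), 1e-9)
    tn = (t - t0) / ts
    yn = (y - y0) / ys
    V = np.vander(tn, order + 1, increasing=True)
    pen = np.zeros(order + 1)
    pen[2:] = reg
    A = V.T @ V + np.diag(pen)
    coef_n = np.linalg.solve(A, V.T @ yn)
    # un-normalize: y = y0 + ys * sum c_k ((t - t0)/ts)^k
    p = np.polynomial.Polynomial(coef_n)
    q = p(np.polynomial.Polynomial([-t0 / ts, 1.0 / ts])) * ys + y0
    coef = q.coef
    if coef.size < order + 1:
        coef = np.pad(coef, (0, order + 1 - coef.size))
    return coef


def _ransac_event(times, lengths, frames, avail, config: RansacConfig,
                  rng, kind: str, shrink_thresh: float | None):
    """One RANSAC round: best consecutive inlier run on available points."""
    eps = _epsilon(lengths, config)
    cand = np.nonzero(avail)[0]
    if cand.size < config.min_inliers:
        return None
    n_sample = (config.model_order + 1) if kind == "growth" else 2
    best_run = None
    # sample minimal sets around a random anchor: events are contiguous in
    # time, so local samples are far more likely to be uncontaminated
    window = max(6 * config.min_sample_span, 20)
    for _ in range(config.max_iterations):
        if cand.size < n_sample:
            break
        anchor = rng.choice(cand)
        local = cand[np.abs(frames[cand] - frames[anchor]) <= window]
        if local.size < n_sample:
            continue
        pick = rng.choice(local, size=n_sample, replace=False)
        if np.ptp(frames[pick]) < config.min_sample_span:
            continue
        t_s, y_s = times[pick], lengths[pick]
        if kind == "growth":
            coef = _fit_regularized_poly(t_s, y_s, config.model_order,
                                         config.linear_reg)
            pred = np.polynomial.Polynomial(coef)(times)
        else:
            slope, icpt = np.polyfit(t_s, y_s, 1)
            if shrink_thresh is not None and slope >= shrink_thresh:
                continue
            pred = icpt + slope * times
        resid = np.abs(lengths - pred)
        inl = cand[resid[cand] <= eps]
        run = _longest_run(inl, frames, config.max_inlier_gap)
        if run.size < config.min_inliers:
            continue
        # growth events must actually grow: positive slope and a total
        # rise clearly above the inlier tolerance (rejects flat baselines)
        sl = np.polyfit(times[run], lengths[run], 1)[0]
        if kind == "growth":
            rise = sl * (times[run[-1]] - times[run[0]])
            if sl <= 0 or rise < 2.0 * eps:
                continue
        if kind == "shrink" and shrink_thresh is not None \
                and sl >= shrink_thresh:
            continue
        if best_run is None or run.size > best_run.size:
            best_run = run
    if best_run is None:
        return None
    if np.ptp(frames[best_run]) + 1 < config.min_event_frames:
        return None
    slope, icpt = np.polyfit(times[best_run], lengths[best_run], 1)
    return Event(kind=kind, indices=best_run,
                 t_start=float(times[best_run[0]]),
                 t_end=float(times[best_run[-1]]),
                 slope=float(slope), intercept=float(icpt))


def _merge_adjacent(events: list[Event], times, lengths, frames,
                    config: RansacConfig) -> list[Event]:
    """Merge same-kind events that are two pieces of one phase.

    Two events merge when they are adjacent in time (frame gap within the
    event-internal tolerance) and each one's linear fit predicts the other
    event's near endpoint within the inlier tolerance.
    """
    eps = _epsilon(lengths, config)
    evs = sorted(events, key=lambda e: e.t_start)
    merged = True
    while merged and len(evs) > 1:
        merged = False
        for i in range(len(evs) - 1):
            a, b = evs[i], evs[i + 1]
            if a.kind != b.kind:
                continue
            gap = frames[b.indices[0]] - frames[a.indices[-1]]
            if gap > 3 * (config.max_inlier_gap + 1):
                continue
            ta, tb = times[a.indices[-1]], times[b.indices[0]]
            ya, yb = lengths[a.indices[-1]], lengths[b.indices[0]]
            if (abs(a.value_at(tb) - yb) > 2 * eps
                    or abs(b.value_at(ta) - ya) > 2 * eps):
                continue
            idx = np.sort(np.concatenate([a.indices, b.indices]))
            slope, icpt = np.polyfit(times[idx], lengths[idx], 1)
            evs[i] = Event(kind=a.kind, indices=idx,
                           t_start=float(times[idx[0]]),
                           t_end=float(times[idx[-1]]),
                           slope=float(slope), intercept=float(icpt))
            del evs[i + 1]
            merged = True
            break
    return evs


def find_growth_events(times: np.ndarray, lengths: np.ndarray,
                       config: RansacConfig | None = None,
                       frames: np.ndarray | None = None) -> list[Event]:
    """All growth events by iterative RANSAC with inlier removal.

    Repeatedly finds the largest consecutive near-linear increasing run,
    removes its inliers from the sampling set, and stops when no run with
    at least ``min_inliers`` points remains.  Events are returned in
    detection order (largest first); inlier sets are disjoint.
    """
    if config is None:
        config = RansacConfig()
    times = np.asarray(times, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if frames is None:
        frames = np.arange(times.size)
    rng = np.random.default_rng(config.rng_seed)
    avail = np.ones(times.size, dtype=bool)
    events: list[Event] = []
    while avail.sum() >= config.min_inliers:
        ev = _ransac_event(times, lengths, frames, avail, config, rng,
                           "growth", None)
        if ev is None:
            break
        avail[ev.indices] = False
        events.append(ev)
    return _merge_adjacent(events, times, lengths, frames, config)


def find_shrink_events(times: np.ndarray, lengths: np.ndarray,
                       growth_events: list[Event],
                       config: RansacConfig | None = None,
                       frames: np.ndarray | None = None) -> list[Event]:
    """Shrinkage events among points not claimed by growth events.

    The linear model is constrained to fast decline: slope below
    ``shrink_slope_nm_s`` (default -2x the mean growth slope of this
    track).  Shrink events may have as few as 3 points since shrinkage is
    typically an order of magnitude faster than growth.
    """
    if config is None:
        config = RansacConfig()
    times = np.asarray(times, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if frames is None:
        frames = np.arange(times.size)
    thresh = config.shrink_slope_nm_s
    if thresh is None:
        vg = np.mean([e.slope for e in growth_events]) if growth_events else 0.0
        thresh = -2.0 * max(vg, 1e-9)
    shrink_cfg = RansacConfig(
        epsilon_nm=config.epsilon_nm, min_inliers=3,
        max_iterations=config.max_iterations, model_order=config.model_order,
        linear_reg=config.linear_reg, shrink_slope_nm_s=thresh,
        min_event_frames=config.min_event_frames,
        max_inlier_gap=config.max_inlier_gap, min_sample_span=2,
        rng_seed=config.rng_seed + 1)
    rng = np.random.default_rng(shrink_cfg.rng_seed)
    avail = np.ones(times.size, dtype=bool)
    for ev in growth_events:
        avail[ev.indices] = False
    events: list[Event] = []
    while avail.sum() >= shrink_cfg.min_inliers:
        ev = _ransac_event(times, lengths, frames, avail, shrink_cfg, rng,
                           "shrink", thresh)
        if ev is None:
            break
        avail[ev.indices] = False
        events.append(ev)
    return _merge_adjacent(events, times, lengths, frames, shrink_cfg)


# ---------------------------------------------------------------------------
# event interpretation


def classify_transitions(events: list[Event], baseline_nm: float = 0.0,
                         epsilon_nm: float = 0.0) -> list[str]:
    """Label each shrink event 'total_catastrophe' or 'rescued'.

    A shrink followed by growth starting at or below the seed baseline
    (within epsilon) ended in a total catastrophe; growth resuming above
    the baseline marks a rescue.  A shrink not followed by any growth
    event (track ends mid-shrink) is labelled 'incomplete' and excluded
    from frequency denominators.
    """
    ordered = sorted(events, key=lambda e: e.t_start)
    labels = []
    for i, ev in enumerate(ordered):
        if ev.kind != "shrink":
            continue
        nxt = next((e for e in ordered[i + 1:] if e.kind == "growth"), None)
        if nxt is None:
            labels.append("incomplete")
        elif nxt.value_at(nxt.t_start) <= baseline_nm + epsilon_nm:
            labels.append("total_catastrophe")
        else:
            labels.append("rescued")
    return labels


def _complete_growth_events(events: list[Event]) -> list[Event]:
    """Growth events bounded on both sides by a transition or the baseline.

    A growth event is complete when the next detected event is a shrink
    (its catastrophe was observed); the leading growth event of a track
    counts as bounded at its start by the seed baseline.  A growth phase
    whose terminating shrinkage was too short to resolve is incomplete and
    contributes neither an event nor exposure time, keeping the frequency
    estimator consistent.
    """
    ordered = sorted(events, key=lambda e: e.t_start)
    out = []
    for i, ev in enumerate(ordered):
        if ev.kind != "growth":
            continue
        if i + 1 < len(ordered) and ordered[i + 1].kind == "shrink":
            out.append(ev)
    return out


def compute_frequencies(events: list[Event], baseline_nm: float = 0.0,
                        epsilon_nm: float = 0.0) -> tuple[float, float]:
    """Catastrophe and rescue frequencies from an ordered event list.

    fc = (number of shrink events) / (total duration of complete growth
    events); fr = (number of rescues) / (total duration of shrink events
    with an observed outcome).  Regrowth after a total catastrophe is
    re-nucleation and does not count as a rescue.  A frequency whose
    denominator is zero is returned as nan (undefined, distinct from 0).
    """
    ordered = sorted(events, key=lambda e: e.t_start)
    # catastrophes observed at the end of a resolved growth event
    n_shrink = sum(1 for i, e in enumerate(ordered)
                   if e.kind == "shrink"
                   and i > 0 and ordered[i - 1].kind == "growth")
    growth_time = sum(e.duration for e in _complete_growth_events(ordered))
    labels = classify_transitions(ordered, baseline_nm, epsilon_nm)
    shrinks = [e for e in ordered if e.kind == "shrink"]
    complete_shrink_time = sum(
        e.duration for e, lab in zip(shrinks, labels) if lab != "incomplete")
    n_rescues = sum(1 for lab in labels if lab == "rescued")
    if n_shrink == 0:
        # monotone growth: an observed catastrophe rate of zero, provided
        # any growth was observed at all (else undefined)
        any_growth = sum(e.duration for e in ordered if e.kind == "growth")
        fc = 0.0 if any_growth > 0 else float("nan")
    else:
        fc = n_shrink / growth_time if growth_time > 0 else float("nan")
    fr = (n_rescues / complete_shrink_time if complete_shrink_time > 0
          else float("nan"))
    return fc, fr


def analyze_track(times: np.ndarray, lengths_nm: np.ndarray,
                  config: RansacConfig | None = None,
                  baseline_nm: float = 0.0) -> DynamicsSummary:
    """Full per-track analysis: events, speeds, frequencies, counts."""
    if config is None:
        config = RansacConfig()
    times = np.asarray(times, dtype=float)
    lengths_nm = np.asarray(lengths_nm, dtype=float)
    growth = find_growth_events(times, lengths_nm, config)
    shrink = find_shrink_events(times, lengths_nm, growth, config)
    events = sorted(growth + shrink, key=lambda e: e.t_start)
    eps = _epsilon(lengths_nm, config)
    labels = classify_transitions(events, baseline_nm, eps)
    fc, fr = compute_frequencies(events, baseline_nm, eps)
    for ev in events:
        if ev.kind == "growth":
            ev.is_complete = ev in _complete_growth_events(events)
        else:
            ev.is_complete = True
    g = [e.slope for e in growth]
    s = [e.slope for e in shrink]
    shrinks = [e for e in events if e.kind == "shrink"]
    return DynamicsSummary(
        vg_mean=float(np.mean(g)) if g else float("nan"),
        vg_sd=float(np.std(g)) if g else float("nan"),
        vs_mean=float(np.mean(s)) if s else float("nan"),
        vs_sd=float(np.std(s)) if s else float("nan"),
        fc=fc, fr=fr,
        n_growth=len(growth), n_shrink=len(shrink),
        n_rescues=sum(1 for lab in labels if lab == "rescued"),
        n_total_catastrophes=sum(1 for lab in labels
                                 if lab == "total_catastrophe"),
        total_growth_time=sum(e.duration
                              for e in _complete_growth_events(events)),
        total_shrink_time=sum(e.duration for e, lab in zip(shrinks, labels)
                              if lab != "incomplete"),
        events=events)


def assign_polarity(summary_a: DynamicsSummary, summary_b: DynamicsSummary
                    ) -> tuple[str, str]:
    """Label the faster-growing end 'plus', the other 'minus'.

    Compares mean growth-event slopes; ties break on total length gained
    (sum of slope x duration over growth events), deterministically.
    """
    def gained(s):
        return sum(e.slope * e.duration for e in s.events
                   if e.kind == "growth")

    va = summary_a.vg_mean if math.isfinite(summary_a.vg_mean) else -math.inf
    vb = summary_b.vg_mean if math.isfinite(summary_b.vg_mean) else -math.inf
    if va > vb:
        return "plus", "minus"
    if vb > va:
        return "minus", "plus"
    return (("plus", "minus") if gained(summary_a) >= gained(summary_b)
            else ("minus", "plus"))


# ---------------------------------------------------------------------------
# two-state length distribution


def length_distribution(vg: float, vs: float, fc: float, fr: float,
                        t: float | None = None, l_max: float | None = None,
                        n_bins: int = 400):
    """Microtubule length distribution of the two-state model.

    Integrates the advection equations for the densities of growing and
    shrinking microtubules (upwind scheme, shrinkage flux at the seed
    re-entering growth) up to time ``t``, or — when ``t`` is None — to the
    stationary regime, returning the time-averaged distribution.  In the
    bounded regime (vg fr < vs fc) the stationary distribution is
    exponential with decay rate a = fc/vg - fr/vs.

    Returns (bin_centers, density).  Raises in the unbounded regime
    (vg fr >= vs fc, or fc = 0) when a stationary answer is requested.
    """
    if min(vg, vs) <= 0 or fc < 0 or fr < 0:
        raise ValueError("need vg, vs > 0 and fc, fr >= 0")
    stationary = t is None
    a = fc / vg - fr / vs
    if stationary and (fc == 0 or a <= 0):
        raise ValueError("unbounded growth regime: no stationary "
                         "length distribution")
    if l_max is None:
        l_max = 12.0 / a if stationary else vg * t * 1.2 + 1.0
    dl = l_max / n_bins
    edges = np.arange(n_bins + 1) * dl
    centers = 0.5 * (edges[:-1] + edges[1:])
    pg = np.zeros(n_bins)
    ps = np.zeros(n_bins)
    pg[0] = 1.0 / dl          # all mass starts at the seed, growing
    dt = 0.5 * dl / max(vg, vs)
    # the exponential tail fills at speed ~ a*vg; integrate long enough for
    # the slowest mode to relax before averaging
    t_end = t if t is not None else max(40.0 / (a * vg), 20.0 / fc)
    n_steps = int(math.ceil(t_end / dt))
    avg = np.zeros(n_bins)
    n_avg = 0
    for step in range(n_steps):
        # upwind advection: growth moves right, shrinkage moves left
        flux_g = vg * pg
        flux_s = vs * ps
        dpg = np.zeros(n_bins)
        dps = np.zeros(n_bins)
        dpg[1:] -= (flux_g[1:] - flux_g[:-1]) / dl
        dpg[0] -= flux_g[0] / dl
        dps[:-1] -= (flux_s[:-1] - flux_s[1:]) / dl
        # shrinkage flux through l = 0 re-enters growth at the seed
        dpg[0] += flux_s[0] / dl
        dps[-1] -= flux_s[-1] / dl
        dpg += -fc * pg + fr * ps
        dps += fc * pg - fr * ps
        pg = pg + dt * dpg
        ps = ps + dt * dps
        if stationary and step >= n_steps // 2:
            avg += pg + ps
            n_avg += 1
    if stationary:
        dens = avg / n_avg
    else:
        dens = pg + ps
    total = dens.sum() * dl
    if total > 0:
        dens = dens / total
    return centers, dens


def plot_track_events(times, lengths_nm, events: list[Event], ax=None,
                      baseline_nm: float = 0.0):
    """Annotated length-versus-time plot: data, event fits, transitions.

    Growth events are drawn in green, shrinkage in blue, with the seed
    baseline dashed.  Returns the matplotlib axes (created on demand).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    ax.plot(times, lengths_nm, ".", color="0.6", ms=3, label="track")
    for ev in sorted(events, key=lambda e: e.t_start):
        tt = np.array([ev.t_start, ev.t_end])
        color = "tab:green" if ev.kind == "growth" else "tab:blue"
        ax.plot(tt, ev.value_at(tt), "-", color=color, lw=2)
    ax.axhline(baseline_nm, ls="--", color="tab:red", lw=1,
               label="seed baseline")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("length (nm)")
    ax.legend(loc="upper left", fontsize=8)
    return ax
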