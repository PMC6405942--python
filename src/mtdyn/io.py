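"""File formats and configuration for the pipeline.

TIFF stacks in (via tifffile); CSV/JSON out (via pandas / json).  Every CSV
starts with a schema comment line (``# mtdyn <name> v1``) and is read back
with ``comment='#'``.  Units in all outputs: lengths nm, times s, angles
degrees, coordinates px.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_stack",
    "write_stack",
    "write_seeds_csv",
    "read_seeds_csv",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_events_csv",
    "write_summary_json",
    "write_ground_truth_csv",
]

SCHEMA_VERSION = 1


@dataclasses.dataclass
class PipelineConfig:
    """Physical calibration plus stage parameters, file-round-trippable.

    ``psf_fwhm_nm`` per channel converts to the Gaussian sigma through
    sigma = FWHM / (2 sqrt(2 ln 2)).
    """

    pixel_size_nm: float = 156.0
    frame_interval_s: float = 1.0
    psf_fwhm_nm_seed: float = 199.0
    psf_fwhm_nm_dynamic: float = 199.0
    mser_delta: int = 2
    mser_min_area: int = 10
    mser_max_area_frac: float = 0.10
    mser_max_variation: float = 0.5
    mser_smooth_sigma: float = 1.0
    mser_min_level_sigma: float = 2.0
    angular_threshold_deg: float = 20.0
    max_gap: int = 5
    ransac_epsilon_nm: float | None = None
    ransac_min_inliers: int = 5
    ransac_iterations: int = 500
    rng_seed: int = 42

    def __post_init__(self) -> None:
        for name in ("pixel_size_nm", "frame_interval_s",
                     "psf_fwhm_nm_seed", "psf_fwhm_nm_dynamic"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def psf_sigma_px(self, channel: str = "seed") -> tuple[float, float]:
        fwhm = (self.psf_fwhm_nm_seed if channel == "seed"
                else self.psf_fwhm_nm_dynamic)
        s = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / self.pixel_size_nm
        return (s, s)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh,
                           default_flow_style=False, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def mser_config(self):
        from .mser import MserConfig

        return MserConfig(
            delta=self.mser_delta, min_area=self.mser_min_area,
            max_area_frac=self.mser_max_area_frac,
            max_variation=self.mser_max_variation,
            smooth_sigma=self.mser_smooth_sigma,
            min_level_sigma=self.mser_min_level_sigma)

    def detect_config(self):
        from .detect import DetectConfig

        return DetectConfig(psf_sigma_px=self.psf_sigma_px("seed"),
                            mser=self.mser_config())

    def track_config(self):
        from .track import TrackConfig

        return TrackConfig(
            pixel_size_nm=self.pixel_size_nm,
            frame_interval_s=self.frame_interval_s,
            psf_sigma_px=self.psf_sigma_px("dynamic"),
            mser=self.mser_config(),
            angular_threshold_deg=self.angular_threshold_deg,
            max_gap=self.max_gap)

    def ransac_config(self):
        from .kymo import RansacConfig

        return RansacConfig(
            epsilon_nm=self.ransac_epsilon_nm,
            min_inliers=self.ransac_min_inliers,
            max_iterations=self.ransac_iterations,
            rng_seed=self.rng_seed)


# ---------------------------------------------------------------------------
# TIFF


def read_stack(path) -> np.ndarray:
    """Read a single- or multi-frame TIFF as a (T, H, W) float array.

    Single frames become stacks of length 1.  RGB data is converted to a
    single channel by averaging with a warning (fluorescence stacks should
    be single-channel).
    """
    try:
        arr = tifffile.imread(str(path))
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise OSError(f"could not read TIFF stack {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < arr.shape[-2]:
        warnings.warn(f"{path}: RGB(A) TIFF converted to single channel "
                      "by averaging the color channels")
        arr = arr[..., :3].mean(axis=-1)[None]
    elif arr.ndim == 4 and arr.shape[-1] in (3, 4):
        warnings.warn(f"{path}: RGB(A) TIFF converted to single channel "
                      "by averaging the color channels")
        arr = arr[..., :3].mean(axis=-1)
    elif arr.ndim != 3:
        raise OSError(f"{path}: unsupported TIFF dimensionality {arr.shape}")
    return arr.astype(float)


def write_stack(path, frames: np.ndarray) -> None:
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    tifffile.imwrite(str(path), frames.astype(np.float32))


# ---------------------------------------------------------------------------
# CSV / JSON


def _write_csv(path, df: pd.DataFrame, name: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mtdyn {name} v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_seeds_csv(path, seeds) -> None:
    rows = [{
        "seed_id": s.seed_id,
        "x_start": s.endpoints[0][0], "y_start": s.endpoints[0][1],
        "x_end": s.endpoints[1][0], "y_end": s.endpoints[1][1],
        "m": s.m, "c": s.c, "A": s.A, "Bg": s.Bg, "ds": s.ds,
        "snr": s.snr,
        "refined_start": s.endpoints_refined[0],
        "refined_end": s.endpoints_refined[1],
    } for s in seeds]
    _write_csv(path, pd.DataFrame(rows), "seeds")


def read_seeds_csv(path) -> list:
    """Seeds CSV as lightweight seed records usable by the tracker."""
    import types

    df = _read_csv(path)
    out = []
    for _, r in df.iterrows():
        ep = np.array([[r.x_start, r.y_start], [r.x_end, r.y_end]])
        d = ep[1] - ep[0]
        n = np.linalg.norm(d)
        d = d / n if n > 0 else np.array([1.0, 0.0])
        out.append(types.SimpleNamespace(
            seed_id=int(r.seed_id), endpoints=ep, direction=d,
            m=float(r.m), c=float(r.c), A=float(r.A), Bg=float(r.Bg),
            ds=float(r.ds), snr=float(r.snr)))
    return out


def write_tracks_csv(path, tracks) -> None:
    rows = []
    for tr in tracks:
        for p in tr.points:
            rows.append({
                "seed_id": tr.seed_id, "end": tr.end_label,
                "frame": p.frame, "time_s": p.time_s,
                "x": p.x, "y": p.y, "length_nm": p.length_nm,
                "ok": p.ok,
            })
    _write_csv(path, pd.DataFrame(
        rows, columns=["seed_id", "end", "frame", "time_s", "x", "y",
                       "length_nm", "ok"]), "tracks")


def read_tracks_csv(path) -> pd.DataFrame:
    df = _read_csv(path)
    if not {"time_s", "length_nm"} <= set(df.columns):
        raise ValueError(f"{path}: tracks CSV needs time_s and length_nm")
    if "seed_id" not in df.columns:
        df["seed_id"] = 0
    if "end" not in df.columns:
        df["end"] = "end_B"
    return df


def write_events_csv(path, events_by_track) -> None:
    """``events_by_track``: list of (track_id, end, Event)."""
    rows = [{
        "track_id": tid, "end": end, "kind": ev.kind,
        "t_start": ev.t_start, "t_end": ev.t_end,
        "slope_nm_per_s": ev.slope, "n_inliers": len(ev.indices),
        "complete": ev.is_complete,
    } for tid, end, ev in events_by_track]
    _write_csv(path, pd.DataFrame(
        rows, columns=["track_id", "end", "kind", "t_start", "t_end",
                       "slope_nm_per_s", "n_inliers", "complete"]), "events")


def write_summary_json(path, summaries: dict) -> None:
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, float)):
            v = float(obj)
            return v if np.isfinite(v) else None
        if isinstance(obj, (np.integer, int)):
            return int(obj)
        return obj

    with open(path, "w") as fh:
        json.dump(clean(summaries), fh, indent=2)


def write_ground_truth_csv(path, movie) -> None:
    """Sidecar for a simulated movie: per frame/filament truth."""
    rows = []
    for fi, traj in enumerate(movie.trajectories):
        for k, t in enumerate(traj.times):
            rows.append({
                "filament": fi, "frame": k, "time_s": t,
                "length_px": traj.lengths_px[k],
                "length_nm": traj.lengths_px[k] * traj.pixel_size_nm,
                "tip_x": traj.tips[k][0], "tip_y": traj.tips[k][1],
                "phase": traj.phases[k],
            })
    _write_csv(path, pd.DataFrame(rows), "ground_truth")
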