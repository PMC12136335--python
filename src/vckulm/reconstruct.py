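"""Super-resolved map rendering and image-quality metrics.

Accepted trajectories are accumulated on a grid upsampled by ``sr_factor``:
each trajectory sample (track points plus linearly interpolated inter-frame
samples at super-resolution step) increments the density map and deposits a
signed speed sample (positive toward +y, matching the flow-direction
colouring convention) into its pixel. Image quality is quantified by

    CNR   = (E_V − E_N) / σ_N                      (density contrast-to-noise)
    nRMSE = √(Σ|Vᵢ − V_mean|²/N) / |V_mean|        (per-pixel velocity spread)

with the image-level nRMSE the unweighted mean over pixels holding ≥ 2
velocity samples with nonzero mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FrameStack
from .localize import LocalizationConfig, localize_stack
from .tracking import Track, TrackerConfig, track_stack, track_stack_nn
from .trajectory import filter_tracks


@dataclass
class ULMMaps:
    sr_factor: int
    density: np.ndarray                 # counts per SR pixel
    velocity: np.ndarray                # signed px/frame, NaN where empty
    velocity_samples: dict[tuple[int, int], list[float]] = field(default_factory=dict)


@dataclass
class MetricsReport:
    cnr: float
    nrmse: float
    mean_trace_length: float            # detections / track
    mean_trace_duration_s: float
    mean_flow_speed: float              # px/s (frame-rate normalized)
    n_tracks: int = 0
    n_nrmse_pixels: int = 0
    n_zero_mean_excluded: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("cnr", "nrmse", "mean_trace_length", "mean_trace_duration_s",
                 "mean_flow_speed", "n_tracks", "n_nrmse_pixels",
                 "n_zero_mean_excluded")}


def _signed_speed(dx: float, dy: float, dt: float) -> float:
    speed = float(np.hypot(dx, dy)) / dt
    if abs(dy) > 1e-12:
        return speed if dy > 0 else -speed
    if abs(dx) > 1e-12:
        return speed if dx > 0 else -speed
    return 0.0


def render_maps(tracks: list[Track], grid_shape: tuple[int, int],
                sr_factor: int = 8) -> ULMMaps:
    """Accumulate tracks into density and signed-velocity maps.

    Each consecutive point pair contributes samples spaced at most one SR
    pixel apart along the segment (segment start inclusive, end exclusive;
    the track's final point is deposited once at the end), so the total
    density equals the exact number of deposited samples.
    """
    rows, cols = grid_shape
    density = np.zeros((rows * sr_factor, cols * sr_factor), dtype=np.int64)
    samples: dict[tuple[int, int], list[float]] = {}

    def deposit(x: float, y: float, v: float, seen: set) -> None:
        c = int(round(x * sr_factor))
        r = int(round(y * sr_factor))
        if (r, c) in seen:
            return        # one sample per pixel per segment pass
        seen.add((r, c))
        if 0 <= r < density.shape[0] and 0 <= c < density.shape[1]:
            density[r, c] += 1
            samples.setdefault((r, c), []).append(v)

    for tr in tracks:
        pts = tr.points
        if len(pts) < 2:
            continue
        for (f0, x0, y0, _), (f1, x1, y1, _) in zip(pts[:-1], pts[1:]):
            dt = f1 - f0
            v = _signed_speed(x1 - x0, y1 - y0, dt)
            seg_len = np.hypot(x1 - x0, y1 - y0) * sr_factor
            n_steps = max(1, int(np.ceil(seg_len)))
            seen: set = set()
            for j in range(n_steps):
                t = j / n_steps
                deposit(x0 + t * (x1 - x0), y0 + t * (y1 - y0), v, seen)
        f0, x0, y0, _ = pts[-2]
        f1, x1, y1, _ = pts[-1]
        deposit(x1, y1, _signed_speed(x1 - x0, y1 - y0, f1 - f0), set())

    velocity = np.full(density.shape, np.nan)
    for (r, c), vals in samples.items():
        velocity[r, c] = float(np.mean(vals))
    return ULMMaps(sr_factor=sr_factor, density=density, velocity=velocity,
                   velocity_samples=samples)


def cnr(image: np.ndarray, vessel_region: np.ndarray,
        noise_region: np.ndarray) -> float:
    """Contrast-to-noise ratio (E_V − E_N)/σ_N between two disjoint regions.

    Regions are boolean masks on ``image``. Invariant under multiplicative
    rescaling of the image.
    """
    vessel_region = np.asarray(vessel_region, dtype=bool)
    noise_region = np.asarray(noise_region, dtype=bool)
    if not vessel_region.any() or not noise_region.any():
        raise ValueError("regions must be non-empty")
    if (vessel_region & noise_region).any():
        raise ValueError("regions must be disjoint")
    img = np.asarray(image, dtype=np.float64)
    e_v = img[vessel_region].mean()
    noise = img[noise_region]
    sigma_n = noise.std()
    if sigma_n == 0:
        raise ValueError("noise region has zero standard deviation")
    return float((e_v - noise.mean()) / sigma_n)


def nrmse(velocity_samples: dict[tuple[int, int], list[float]],
          weighted: bool = False,
          region: np.ndarray | None = None) -> tuple[float, int, int]:
    """Image-level velocity nRMSE.

    Per pixel with ≥ 2 samples and nonzero mean:
    √(Σ(Vᵢ − V_mean)²/N)/|V_mean|; the image value is the unweighted mean
    over valid pixels (density-weighted when ``weighted``). When ``region``
    (a boolean SR-grid mask, typically the vessel area) is given, only
    pixels inside it contribute — steady flow through a vessel pixel is the
    premise of the per-pixel normalization, so pixels outside the vessel
    are not meaningful samples of tracking consistency. Returns
    (value, n_valid_pixels, n_zero_mean_excluded); the value is NaN when no
    pixel qualifies. Scale-invariant in the samples.
    """
    vals, weights = [], []
    n_zero = 0
    for pix, samples in velocity_samples.items():
        if len(samples) < 2:
            continue
        if region is not None and not region[pix]:
            continue
        arr = np.asarray(samples, dtype=np.float64)
        mean = arr.mean()
        if mean == 0.0:
            n_zero += 1
            continue
        vals.append(float(np.sqrt(np.mean((arr - mean) ** 2)) / abs(mean)))
        weights.append(len(samples))
    if not vals:
        return float("nan"), 0, n_zero
    if weighted:
        return float(np.average(vals, weights=weights)), len(vals), n_zero
    return float(np.mean(vals)), len(vals), n_zero


def save_map_pngs(maps: ULMMaps, out_dir, log_density: bool = True) -> None:
    """Write density.png and velocity.png renders of the maps.

    Density uses a hot colormap (log-compressed by default); velocity uses
    a diverging colormap with warm colors for flow toward +y.
    """
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dens = maps.density.astype(np.float64)
    if log_density:
        dens = np.log1p(dens)
    plt.imsave(out / "density.png", dens, cmap="hot")
    vel = maps.velocity
    vmax = np.nanmax(np.abs(vel)) if np.isfinite(vel).any() else 1.0
    plt.imsave(out / "velocity.png", np.nan_to_num(vel), cmap="RdBu_r",
               vmin=-vmax, vmax=vmax)


def track_summary(tracks: list[Track], frame_rate: float) -> dict:
    """Mean trace length (detections), duration (s) and flow speed (px/s)."""
    if not tracks:
        return {"mean_trace_length": 0.0, "mean_trace_duration_s": 0.0,
                "mean_flow_speed": 0.0, "n_tracks": 0}
    lengths, durations, speeds = [], [], []
    for tr in tracks:
        pts = tr.points
        lengths.append(len(pts))
        durations.append((pts[-1][0] - pts[0][0]) / frame_rate)
        step_speeds = [np.hypot(x1 - x0, y1 - y0) / (f1 - f0)
                       for (f0, x0, y0, _), (f1, x1, y1, _)
                       in zip(pts[:-1], pts[1:])]
        speeds.append(float(np.mean(step_speeds)) * frame_rate)
    return {"mean_trace_length": float(np.mean(lengths)),
            "mean_trace_duration_s": float(np.mean(durations)),
            "mean_flow_speed": float(np.mean(speeds)),
            "n_tracks": len(tracks)}


def compute_metrics(maps: ULMMaps, tracks: list[Track], frame_rate: float,
                    vessel_region: np.ndarray | None = None,
                    noise_region: np.ndarray | None = None) -> MetricsReport:
    c = float("nan")
    if vessel_region is not None and noise_region is not None:
        c = cnr(maps.density, vessel_region, noise_region)
    v, n_valid, n_zero = nrmse(maps.velocity_samples, region=vessel_region)
    s = track_summary(tracks, frame_rate)
    return MetricsReport(cnr=c, nrmse=v,
                         mean_trace_length=s["mean_trace_length"],
                         mean_trace_duration_s=s["mean_trace_duration_s"],
                         mean_flow_speed=s["mean_flow_speed"],
                         n_tracks=s["n_tracks"], n_nrmse_pixels=n_valid,
                         n_zero_mean_excluded=n_zero)


def framerate_sweep(stack: FrameStack, strides: list[int] = (1, 2, 3),
                    loc_config: LocalizationConfig | None = None,
                    tracker_config: TrackerConfig | None = None,
                    vd_max: float = 2.0) -> pd.DataFrame:
    """Frame-rate dependence experiment.

    Runs localization → tracking → VD filtering on the stack subsampled at
    each stride, once with the velocity-constrained Kalman tracker and once
    with the nearest-neighbour baseline (no prediction, no brightness, no
    VD), and reports mean trace length/duration and mean flow speed (px/s)
    plus their relative change versus stride 1. Trace duration and px/s
    speed are the stride-invariant quantities under perfect tracking, so
    their degradation isolates matching failures.
    """
    from .phantom import subsample_frame_rate

    loc_config = loc_config or LocalizationConfig()
    tracker_config = tracker_config or TrackerConfig()
    rows = []
    for stride in strides:
        sub = subsample_frame_rate(stack, stride) if stride > 1 else stack
        dets = localize_stack(sub, loc_config)
        vck = track_stack(dets, tracker_config)
        vck, _ = filter_tracks(vck, vd_max=vd_max)
        base = track_stack_nn(dets, gate_radius=tracker_config.gate_radius,
                              min_track_length=tracker_config.min_track_length)
        for method, tracks in (("vc_kalman", vck), ("baseline_nn", base)):
            s = track_summary(tracks, sub.frame_rate)
            rows.append({"stride": stride, "frame_rate": sub.frame_rate,
                         "method": method, **s})
    df = pd.DataFrame(rows)
    for col in ("mean_trace_length", "mean_trace_duration_s", "mean_flow_speed"):
        ref = df[df.stride == min(strides)].set_index("method")[col]
        df[f"rel_change_{col}"] = [
            (r[col] - ref[r["method"]]) / ref[r["method"]] if ref[r["method"]] else np.nan
            for _, r in df.iterrows()]
    return df
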