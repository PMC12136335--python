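"""Synthetic flow-phantom generator with exact ground truth.

Emulates contrast-enhanced ultrafast ultrasound movies at desk scale:
sparse microbubbles advected along vessel centerlines and convolved with a
Gaussian PSF, additive low-rank slowly-varying tissue clutter, additive
Gaussian noise, and a smooth global tissue-motion trajectory
(respiration/heartbeat-like sinusoid) applied to the whole scene.

Every stochastic choice is driven by the config seed, so identical configs
produce bit-identical stacks and ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import FrameStack
from .tracking import Track


@dataclass
class VesselSpec:
    """A vessel as a polyline centerline with constant plug flow.

    centerline : list of (x, y) control points in pixels, ≥ 2 points.
    radius : vessel half-width in pixels.
    flow_speed : bubble speed along the centerline, pixels/frame.
    direction_sign : +1 to traverse the centerline as given, −1 reversed.
    """

    centerline: list[tuple[float, float]]
    radius: float
    flow_speed: float
    direction_sign: int = 1

    def __post_init__(self) -> None:
        if len(self.centerline) < 2:
            raise ValueError("centerline needs at least 2 control points")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.flow_speed < 0:
            raise ValueError("flow_speed must be nonnegative")
        if self.direction_sign not in (1, -1):
            raise ValueError("direction_sign must be +1 or -1")

    def path(self) -> np.ndarray:
        pts = np.asarray(self.centerline, dtype=np.float64)
        return pts if self.direction_sign == 1 else pts[::-1]


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int] = (128, 128)      # (rows, cols)
    n_frames: int = 200
    frame_rate: float = 440.0                      # Hz
    vessels: list[VesselSpec] = field(default_factory=list)
    bubble_rate: float = 0.5        # Poisson mean spawns / frame / vessel
    psf_sigma: float = 1.2          # pixels
    brightness_range: tuple[float, float] = (8.0, 12.0)
    clutter_amplitude: float = 0.0
    clutter_rank: int = 2
    noise_sigma: float = 0.0
    motion_amplitude: tuple[float, float] = (0.0, 0.0)   # (ax, ay) pixels
    motion_period: float = 50.0     # frames
    pixel_size_um: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 32:
            raise ValueError("grid_shape components must be >= 32")
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")
        for name in ("bubble_rate", "clutter_amplitude", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if min(self.motion_amplitude) < 0:
            raise ValueError("motion amplitudes must be nonnegative")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_tracks: list[Track]
    true_displacements: np.ndarray          # (n_frames, 2) global (dx, dy)
    vessel_mask: np.ndarray                 # binary, super-resolved grid
    sr_factor: int = 8
    layers: dict[str, np.ndarray] = field(default_factory=dict)


def _arc_param(path: np.ndarray) -> tuple[np.ndarray, float]:
    seg = np.diff(path, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    return cum, float(cum[-1])


def _point_at_arclength(path: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    """Position at arc length s; extrapolates along the last segment."""
    total = cum[-1]
    if s <= total:
        i = int(np.searchsorted(cum, s, side="right")) - 1
        i = min(max(i, 0), len(path) - 2)
        seg = path[i + 1] - path[i]
        seglen = np.hypot(*seg)
        t = 0.0 if seglen == 0 else (s - cum[i]) / seglen
        return path[i] + t * seg
    seg = path[-1] - path[-2]
    seglen = np.hypot(*seg)
    direction = seg / seglen if seglen > 0 else np.array([0.0, 1.0])
    return path[-1] + (s - total) * direction


def _tangent_at_arclength(path: np.ndarray, cum: np.ndarray, s: float) -> np.ndarray:
    total = cum[-1]
    i = int(np.searchsorted(cum, min(s, total), side="right")) - 1
    i = min(max(i, 0), len(path) - 2)
    seg = path[i + 1] - path[i]
    n = np.hypot(*seg)
    return seg / n if n > 0 else np.array([0.0, 1.0])


def _render_gaussians(frame: np.ndarray, positions: np.ndarray,
                      brightness: np.ndarray, sigma: float) -> None:
    """Add Gaussian PSFs at subpixel positions, in place."""
    rows, cols = frame.shape
    half = max(2, int(np.ceil(4 * sigma)))
    for (x, y), b in zip(positions, brightness):
        c0, c1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
        r0, r1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
        c0, c1 = max(c0, 0), min(c1, cols)
        r0, r1 = max(r0, 0), min(r1, rows)
        if c0 >= c1 or r0 >= r1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        frame[r0:r1, c0:c1] += b * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma**2))


def _make_clutter(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Low-rank clutter: separable smooth spatial patterns, each modulated
    by a slow temporal sinusoid. Casorati rank ≤ clutter_rank by construction."""
    rows, cols = cfg.grid_shape
    n = cfg.n_frames
    out = np.zeros((n, rows, cols))
    t = np.arange(n)
    y = np.arange(rows)[:, None]
    x = np.arange(cols)[None, :]
    for k in range(cfg.clutter_rank):
        # a few cycles across the grid: smooth at pixel scale yet textured
        # enough that block matching sees a well-defined correlation peak
        fy = rng.uniform(2.0, 6.0)
        fx = rng.uniform(2.0, 6.0)
        phy, phx, pht = rng.uniform(0, 2 * np.pi, 3)
        spatial = (1.1 + np.cos(2 * np.pi * fy * y / rows + phy)) * \
                  (1.1 + np.cos(2 * np.pi * fx * x / cols + phx))
        period = rng.uniform(3.0, 6.0) * n    # slow vs the movie length
        temporal = 1.0 + 0.15 * np.sin(2 * np.pi * t / period + pht)
        out += cfg.clutter_amplitude / max(cfg.clutter_rank, 1) * \
            temporal[:, None, None] * spatial[None]
    return out


def _vessel_mask(cfg: PhantomConfig, sr_factor: int) -> np.ndarray:
    rows, cols = cfg.grid_shape
    mask = np.zeros((rows * sr_factor, cols * sr_factor), dtype=bool)
    yy, xx = np.mgrid[0:rows * sr_factor, 0:cols * sr_factor]
    for vessel in cfg.vessels:
        path = vessel.path()
        cum, total = _arc_param(path)
        n_samples = max(int(np.ceil(total * sr_factor)) + 1, 2)
        for s in np.linspace(0, total, n_samples):
            px, py = _point_at_arclength(path, cum, s)
            r = vessel.radius * sr_factor
            cx, cy = px * sr_factor, py * sr_factor
            r0 = max(int(cy - r) - 1, 0)
            r1 = min(int(cy + r) + 2, rows * sr_factor)
            c0 = max(int(cx - r) - 1, 0)
            c1 = min(int(cx + r) + 2, cols * sr_factor)
            if r0 >= r1 or c0 >= c1:
                continue
            sub = (yy[r0:r1, c0:c1] - cy) ** 2 + (xx[r0:r1, c0:c1] - cx) ** 2
            mask[r0:r1, c0:c1] |= sub <= r * r
    return mask


def generate_phantom(config: PhantomConfig, sr_factor: int = 8) -> tuple[FrameStack, GroundTruth]:
    """Simulate a movie and its exact ground truth.

    The stack is clutter + bubbles (both shifted per frame by the global
    motion trajectory) + i.i.d. Gaussian noise. The ground truth records
    pre-motion bubble tracks, the applied per-frame shifts, a super-resolved
    vessel mask and the three post-motion scene layers separately (keys
    ``clutter``, ``bubbles``, ``noise``) for component-wise bookkeeping.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_shape
    n = config.n_frames

    # --- spawn and advect bubbles (pre-motion coordinates) ---
    tracks: list[Track] = []
    track_id = 0
    for vessel in config.vessels:
        path = vessel.path()
        cum, total = _arc_param(path)
        for t0 in range(n):
            for _ in range(rng.poisson(config.bubble_rate)):
                offset_mag = rng.uniform(-vessel.radius * 0.8, vessel.radius * 0.8)
                brightness = rng.uniform(*config.brightness_range)
                pts = []
                for t in range(t0, n):
                    s = vessel.flow_speed * (t - t0)
                    p = _point_at_arclength(path, cum, s)
                    tx, ty = _tangent_at_arclength(path, cum, s)
                    pos = p + offset_mag * np.array([-ty, tx])
                    if not (0 <= pos[0] < cols and 0 <= pos[1] < rows):
                        break
                    pts.append((t, float(pos[0]), float(pos[1]), brightness))
                if pts:
                    tracks.append(Track(track_id=track_id, points=pts))
                    track_id += 1

    # density sanity check: localization assumes separable bubbles
    per_frame: dict[int, list[tuple[float, float]]] = {}
    for tr in tracks:
        for (t, x, y, _) in tr.points:
            per_frame.setdefault(t, []).append((x, y))
    min_spacings = []
    for pts in per_frame.values():
        if len(pts) >= 2:
            arr = np.asarray(pts)
            d2 = ((arr[:, None] - arr[None]) ** 2).sum(-1)
            np.fill_diagonal(d2, np.inf)
            min_spacings.append(np.sqrt(d2.min(axis=1)).mean())
    if min_spacings and np.mean(min_spacings) < 2 * config.psf_sigma:
        warnings.warn("bubble density violates localization assumptions: "
                      "mean nearest-neighbour spacing < 2*psf_sigma",
                      stacklevel=2)

    # --- render layers ---
    bubbles = np.zeros((n, rows, cols))
    for tr in tracks:
        for (t, x, y, b) in tr.points:
            _render_gaussians(bubbles[t], np.array([[x, y]]), np.array([b]),
                              config.psf_sigma)

    clutter = (_make_clutter(config, rng) if config.clutter_amplitude > 0
               else np.zeros((n, rows, cols)))

    # --- global smooth motion, applied to the whole scene ---
    t = np.arange(n, dtype=np.float64)
    ax, ay = config.motion_amplitude
    dx = ax * np.sin(2 * np.pi * t / config.motion_period)
    dy = ay * np.sin(2 * np.pi * t / config.motion_period)
    displacements = np.stack([dx, dy], axis=1)
    if ax > 0 or ay > 0:
        for k in range(n):
            # positive (dx, dy) moves scene content toward +x, +y
            bubbles[k] = ndimage.shift(bubbles[k], (dy[k], dx[k]), order=1,
                                       mode="constant", cval=0.0)
            clutter[k] = ndimage.shift(clutter[k], (dy[k], dx[k]), order=1,
                                       mode="constant", cval=0.0)

    noise = (rng.normal(0.0, config.noise_sigma, size=(n, rows, cols))
             if config.noise_sigma > 0 else np.zeros((n, rows, cols)))

    stack = FrameStack(frames=bubbles + clutter + noise,
                       frame_rate=config.frame_rate,
                       pixel_size_um=config.pixel_size_um)
    gt = GroundTruth(
        true_tracks=tracks,
        true_displacements=displacements,
        vessel_mask=_vessel_mask(config, sr_factor),
        sr_factor=sr_factor,
        layers={"clutter": clutter.astype(np.float32),
                "bubbles": bubbles.astype(np.float32),
                "noise": noise.astype(np.float32)},
    )
    return stack, gt


def subsample_frame_rate(stack: FrameStack, stride: int) -> FrameStack:
    """Keep frames 0, stride, 2·stride, …; frame rate divided by stride.

    Emulates acquisition at a lower rate (e.g. stride 3 turns a 440 Hz
    movie into a 146.7 Hz one).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride >= stack.n_frames:
        raise ValueError("stride must be smaller than the number of frames")
    return stack.copy_with(frames=stack.frames[::stride],
                           frame_rate=stack.frame_rate / stride)


def subsample_ground_truth(gt: GroundTruth, stride: int) -> GroundTruth:
    """Ground truth matching :func:`subsample_frame_rate` (frame indices
    renumbered to the subsampled stack)."""
    new_tracks = []
    for tr in gt.true_tracks:
        pts = [(t // stride, x, y, b) for (t, x, y, b) in tr.points
               if t % stride == 0]
        if len(pts) >= 2:
            new_tracks.append(Track(track_id=tr.track_id, points=pts))
    return GroundTruth(true_tracks=new_tracks,
                       true_displacements=gt.true_displacements[::stride],
                       vessel_mask=gt.vessel_mask, sr_factor=gt.sr_factor)
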