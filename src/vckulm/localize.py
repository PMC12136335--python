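"""Per-frame bubble detection and cosine-fit subpixel localization.

Detection refines each integer-pixel intensity peak to subpixel precision by
fitting a cosine I(u) = A·cos(α(u − ξ)) through the peak sample and its two
axial neighbours, independently along x and y. For a true cosine profile the
estimator is exact:

    α = arccos((I(−1) + I(1)) / (2·I(0)))
    β = arctan((I(−1) − I(1)) / (2·I(0)·sin α))
    ξ = −β / α,  ξ ∈ [−0.5, 0.5]

The arctan form of β is the exact inverse of the cosine model (it reduces to
β = 0 for symmetric profiles); an alternative arccos form of β is available
behind ``beta_form="arccos"`` for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class Detection:
    """One localized bubble: frame index, subpixel (x, y), peak brightness."""

    frame: int
    x: float
    y: float
    brightness: float


@dataclass
class LocalizationConfig:
    gaussian_sigma: float = 1.0       # px, pre-detection smoothing
    min_peak_intensity: float = 0.0   # intensity floor for candidate peaks
    min_peak_separation: float = 3.0  # px, closer peaks merged (brighter kept)
    beta_form: str = "arctan"         # "arctan" (exact) | "arccos" (legacy)

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0 or self.min_peak_intensity < 0 \
                or self.min_peak_separation < 0:
            raise ValueError("localization parameters must be nonnegative")
        if self.beta_form not in ("arctan", "arccos"):
            raise ValueError("beta_form must be 'arctan' or 'arccos'")


def detect_peaks(frame: np.ndarray, config: LocalizationConfig
                 ) -> list[tuple[int, int, float]]:
    """Integer-pixel candidate peaks of the Gaussian-smoothed frame.

    Returns (row, col, smoothed intensity) for every strict local maximum at
    or above ``min_peak_intensity``; peaks closer than ``min_peak_separation``
    are merged greedily by descending intensity, keeping the brighter one.
    """
    frame = np.asarray(frame, dtype=np.float64)
    smoothed = (ndimage.gaussian_filter(frame, config.gaussian_sigma)
                if config.gaussian_sigma > 0 else frame)
    # strict local maxima over the 8-neighbourhood (interior pixels only)
    m = smoothed[1:-1, 1:-1]
    strict = np.ones_like(m, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            strict &= m > smoothed[1 + dr:smoothed.shape[0] - 1 + dr,
                                   1 + dc:smoothed.shape[1] - 1 + dc]
    rr, cc = np.nonzero(strict & (m >= config.min_peak_intensity))
    rr, cc = rr + 1, cc + 1
    vals = smoothed[rr, cc]
    order = np.argsort(-vals)
    kept: list[tuple[int, int, float]] = []
    min_sep2 = config.min_peak_separation**2
    for idx in order:
        r, c, v = int(rr[idx]), int(cc[idx]), float(vals[idx])
        if all((r - kr) ** 2 + (c - kc) ** 2 >= min_sep2 for kr, kc, _ in kept):
            kept.append((r, c, v))
    return kept


def cosine_subpixel_offset(i_m1: float, i_0: float, i_p1: float,
                           beta_form: str = "arctan") -> tuple[float, bool]:
    """Subpixel offset ξ of a peak from three axial samples.

    Returns (ξ, degenerate). Requires a strict peak I(0) > max(I(−1), I(1)) > 0;
    degenerate arithmetic (arccos argument outside [−1, 1] beyond a 1e−12
    tolerance, or sin α = 0) yields ξ = 0 with the flag set.
    """
    if not (i_0 > max(i_m1, i_p1) and max(i_m1, i_p1) > 0):
        return 0.0, True
    arg = (i_m1 + i_p1) / (2.0 * i_0)
    if arg > 1.0 + 1e-12 or arg < -1.0 - 1e-12:
        return 0.0, True
    alpha = np.arccos(np.clip(arg, -1.0, 1.0))
    s = np.sin(alpha)
    if s == 0.0:
        return 0.0, True
    ratio = (i_m1 - i_p1) / (2.0 * i_0 * s)
    if beta_form == "arctan":
        beta = np.arctan(ratio)
    else:
        if abs(ratio) > 1.0 + 1e-12:
            return 0.0, True
        beta = np.arccos(np.clip(ratio, -1.0, 1.0))
    xi = float(np.clip(-beta / alpha, -0.5, 0.5))
    return xi, False


def localize_frame(frame: np.ndarray, config: LocalizationConfig | None = None,
                   frame_index: int = 0) -> list[Detection]:
    """Detect peaks and refine each to subpixel (x, y).

    The cosine fit is applied independently along columns (x) and rows (y)
    around each integer peak of the smoothed frame; brightness is the
    smoothed intensity at the integer peak. Degenerate fits fall back to the
    integer position.
    """
    config = config or LocalizationConfig()
    frame = np.asarray(frame, dtype=np.float64)
    smoothed = (ndimage.gaussian_filter(frame, config.gaussian_sigma)
                if config.gaussian_sigma > 0 else frame)
    out = []
    for r, c, v in detect_peaks(frame, config):
        xi_x, _ = cosine_subpixel_offset(
            smoothed[r, c - 1], v, smoothed[r, c + 1], config.beta_form)
        xi_y, _ = cosine_subpixel_offset(
            smoothed[r - 1, c], v, smoothed[r + 1, c], config.beta_form)
        out.append(Detection(frame=frame_index, x=c + xi_x, y=r + xi_y,
                             brightness=v))
    return out


def localize_stack(stack, config: LocalizationConfig | None = None) -> list[Detection]:
    """Localize every frame of a stack; detections carry their frame index."""
    config = config or LocalizationConfig()
    dets: list[Detection] = []
    for k in range(stack.n_frames):
        dets.extend(localize_frame(stack.frames[k], config, frame_index=k))
    return dets
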