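"""Velocity-difference (VD) trajectory rejection.

Intravascular flow is smooth: along a genuine bubble path the per-frame
step vectors point in a consistent direction, so the sum of their
magnitudes barely exceeds the magnitude of their vector sum. The VD
coefficient

    VD = Σ|vᵢ| / |Σ vᵢ|,   vᵢ = p(xᵢ₊₁, yᵢ₊₁) − p(xᵢ, yᵢ)

is 1 for perfectly straight same-direction motion (triangle-inequality
equality case) and grows as the path becomes erratic; VD > vd_max (default
2, i.e. the summed step lengths deviate by more than 100% from the net
displacement) marks a trajectory as spurious. A vanishing vector sum
(perfect back-tracking) gives VD = +∞ and is always rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracking import Track


@dataclass
class VDResult:
    track_id: int
    vd: float
    accepted: bool


def vd_coefficient(positions) -> float:
    """VD of an ordered (x, y) position sequence (≥ 3 positions required)."""
    pos = np.asarray(positions, dtype=np.float64)
    if pos.ndim != 2 or pos.shape[0] < 3 or pos.shape[1] != 2:
        raise ValueError("need at least 3 (x, y) positions")
    v = np.diff(pos, axis=0)
    total = float(np.hypot(v[:, 0], v[:, 1]).sum())
    net = float(np.hypot(*v.sum(axis=0)))
    if net == 0.0:
        return np.inf
    return total / net


def filter_tracks(tracks: list[Track], vd_max: float = 2.0,
                  window: int | str = "full"
                  ) -> tuple[list[Track], list[VDResult]]:
    """Accept tracks whose VD stays within vd_max.

    window="full" evaluates one VD per track over all its points;
    an integer window w rejects a track if ANY sliding window of w
    consecutive points violates vd ≤ vd_max. Tracks with fewer than
    3 points are rejected (VD undefined).
    """
    if window != "full" and (not isinstance(window, int) or window < 3):
        raise ValueError("window must be 'full' or an integer >= 3")
    accepted, results = [], []
    for tr in tracks:
        pos = tr.positions()
        if len(pos) < 3:
            results.append(VDResult(tr.track_id, np.inf, False))
            continue
        if window == "full":
            vd = vd_coefficient(pos)
        else:
            w = min(window, len(pos))
            vd = max(vd_coefficient(pos[i:i + w])
                     for i in range(len(pos) - w + 1))
        ok = vd <= vd_max
        tr.vd = vd
        results.append(VDResult(tr.track_id, vd, ok))
        if ok:
            accepted.append(tr)
    return accepted, results
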