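"""Multi-target microbubble tracking.

The tracker links per-frame detections into trajectories with a
multidimensional Kalman filter whose state augments position and velocity
with bubble brightness, S = [x, y, I, dx, dy]:

* prediction uses a constant-velocity, constant-brightness model;
* the measurement observes (x, y, I);
* frame-to-frame association is a gated minimum-cost linear assignment whose
  cost blends normalized distance with a brightness mismatch term, so two
  nearby bubbles with distinct echogenicity are not confused;
* young tracks (and tracks whose prediction failed) fall back to a
  statistical velocity — the mean of the last up-to-3 observed
  displacements — to seed the state.

A deliberately naive nearest-neighbour tracker (no prediction, no brightness)
is provided as the comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .localize import Detection

# state layout: [x, y, I, dx, dy]
_F = np.array([
    [1, 0, 0, 1, 0],
    [0, 1, 0, 0, 1],
    [0, 0, 1, 0, 0],
    [0, 0, 0, 1, 0],
    [0, 0, 0, 0, 1],
], dtype=np.float64)

_H = np.array([
    [1, 0, 0, 0, 0],
    [0, 1, 0, 0, 0],
    [0, 0, 1, 0, 0],
], dtype=np.float64)


@dataclass
class TrackerConfig:
    gate_radius: float = 5.0          # px; max plausible inter-frame move
    brightness_weight: float = 0.5    # λ in the match cost
    brightness_scale: float | None = None  # None → median detection brightness
    q_pos: float = 0.05
    q_vel: float = 0.05
    q_i: float = 0.5
    r_pos: float = 0.05
    r_i: float = 1.0
    max_coast: int = 1                # frames a track may go unmatched
    min_track_length: int = 5         # detections required to keep a track
    init_vel_var: float = 25.0        # variance for the unknown initial velocity

    def __post_init__(self) -> None:
        if self.gate_radius <= 0:
            raise ValueError("gate_radius must be positive")
        if self.brightness_weight < 0:
            raise ValueError("brightness_weight must be nonnegative")
        for name in ("q_pos", "q_vel", "q_i", "r_pos", "r_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_coast < 0:
            raise ValueError("max_coast must be nonnegative")
        if self.min_track_length < 2:
            raise ValueError("min_track_length must be >= 2")

    def Q(self) -> np.ndarray:
        return np.diag([self.q_pos, self.q_pos, self.q_i,
                        self.q_vel, self.q_vel])

    def R(self) -> np.ndarray:
        return np.diag([self.r_pos, self.r_pos, self.r_i])


@dataclass
class TrackState:
    """Kalman state S = [x, y, I, dx, dy] with covariance P."""

    S: np.ndarray
    P: np.ndarray
    age: int = 1
    misses: int = 0

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64).reshape(5)
        self.P = np.asarray(self.P, dtype=np.float64).reshape(5, 5)

    @property
    def position(self) -> np.ndarray:
        return self.S[:2]

    @property
    def brightness(self) -> float:
        return float(self.S[2])


@dataclass
class Track:
    track_id: int
    points: list[tuple[int, float, float, float]] = field(default_factory=list)
    status: str = "active"            # active | coasting | terminated
    state: TrackState | None = None
    vd: float | None = None

    def __len__(self) -> int:
        return len(self.points)

    def last_frame(self) -> int:
        return self.points[-1][0]

    def positions(self) -> np.ndarray:
        return np.array([(x, y) for (_, x, y, _) in self.points])


def kalman_predict(state: TrackState, config: TrackerConfig) -> TrackState:
    """Constant-velocity / constant-brightness time update."""
    S = _F @ state.S
    P = _F @ state.P @ _F.T + config.Q()
    return TrackState(S=S, P=P, age=state.age, misses=state.misses)


def kalman_update(state: TrackState, z, config: TrackerConfig) -> TrackState:
    """Measurement update with z = (x, y, I).

    K = P·Hᵀ(H·P·Hᵀ + R)⁻¹; when the measurement noise dominates K → 0 and
    the estimate stays at the prediction; when the prior uncertainty
    dominates K → identity on the observed components and the estimate
    follows the measurement.
    """
    z = np.asarray(z, dtype=np.float64).reshape(3)
    P = state.P
    innov_cov = _H @ P @ _H.T + config.R()
    K = P @ _H.T @ np.linalg.inv(innov_cov)
    S = state.S + K @ (z - _H @ state.S)
    P_new = (np.eye(5) - K @ _H) @ P
    P_new = 0.5 * (P_new + P_new.T)   # keep symmetric despite round-off
    return TrackState(S=S, P=P_new, age=state.age, misses=state.misses)


def statistical_velocity(track: Track) -> tuple[float, float]:
    """Mean of the up-to-3 most recent observed per-frame displacements.

    Used to seed velocity for young tracks and re-seed after failed
    predictions. Single-point tracks return (0, 0). Gaps bridged by
    coasting are accounted for by dividing by the frame difference.
    """
    pts = track.points
    if len(pts) < 2:
        return (0.0, 0.0)
    window = pts[-4:]
    disps = []
    for (f0, x0, y0, _), (f1, x1, y1, _) in zip(window[:-1], window[1:]):
        dt = f1 - f0
        disps.append(((x1 - x0) / dt, (y1 - y0) / dt))
    arr = np.asarray(disps[-3:])
    return (float(arr[:, 0].mean()), float(arr[:, 1].mean()))


def match_cost(predicted: TrackState, det: Detection,
               config: TrackerConfig, brightness_scale: float) -> float:
    """Gated position+brightness cost; inf when outside the gate."""
    d = float(np.hypot(predicted.S[0] - det.x, predicted.S[1] - det.y))
    if d > config.gate_radius:
        return np.inf
    cost = d / config.gate_radius
    if config.brightness_weight > 0:
        cost += config.brightness_weight * \
            abs(predicted.brightness - det.brightness) / brightness_scale
    return cost


def match_frame(tracks: list[Track], detections: list[Detection],
                config: TrackerConfig, brightness_scale: float
                ) -> tuple[list[tuple[Track, Detection]], list[Track], list[Detection]]:
    """Minimum-total-cost one-to-one assignment over in-gate pairs.

    Solved globally per frame (not greedy nearest-first). Returns
    (matched pairs, unmatched tracks, unmatched detections).
    """
    if not tracks or not detections:
        return [], list(tracks), list(detections)
    n, m = len(tracks), len(detections)
    cost = np.full((n, m), np.inf)
    for i, tr in enumerate(tracks):
        for j, det in enumerate(detections):
            cost[i, j] = match_cost(tr.state, det, config, brightness_scale)
    # infeasible pairs forbidden: large finite placeholder, then re-checked
    BIG = 1e9
    finite = np.where(np.isinf(cost), BIG, cost)
    rows, cols = linear_sum_assignment(finite)
    matched, used_t, used_d = [], set(), set()
    for i, j in zip(rows, cols):
        if np.isfinite(cost[i, j]):
            matched.append((tracks[i], detections[j]))
            used_t.add(i)
            used_d.add(j)
    unmatched_tracks = [t for i, t in enumerate(tracks) if i not in used_t]
    unmatched_dets = [d for j, d in enumerate(detections) if j not in used_d]
    return matched, unmatched_tracks, unmatched_dets


def _new_track(track_id: int, det: Detection, config: TrackerConfig) -> Track:
    S = np.array([det.x, det.y, det.brightness, 0.0, 0.0])
    P = np.diag([config.r_pos, config.r_pos, config.r_i,
                 config.init_vel_var, config.init_vel_var])
    return Track(track_id=track_id, points=[(det.frame, det.x, det.y, det.brightness)],
                 state=TrackState(S=S, P=P))


def track_stack(detections: list[Detection], config: TrackerConfig | None = None
                ) -> list[Track]:
    """Full predict → match → update loop over all frames.

    Unmatched tracks coast on their prediction for up to ``max_coast``
    frames, then terminate; unmatched detections seed new tracks. Tracks
    shorter than ``min_track_length`` detections are dropped. Every
    detection belongs to at most one track.
    """
    config = config or TrackerConfig()
    if not detections:
        return []
    bscale = config.brightness_scale
    if bscale is None:
        bscale = float(np.median([d.brightness for d in detections])) or 1.0

    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)

    active: list[Track] = []
    finished: list[Track] = []
    next_id = 0
    last_frame = None
    for f in range(min(by_frame), max(by_frame) + 1):
        dets = by_frame.get(f, [])
        # predict every active track to frame f
        if last_frame is not None:
            for tr in active:
                tr.state = kalman_predict(tr.state, config)
        matched, un_tracks, un_dets = match_frame(active, dets, config, bscale)

        for tr, det in matched:
            tr.state = kalman_update(tr.state, (det.x, det.y, det.brightness), config)
            tr.state.age += 1
            tr.state.misses = 0
            tr.points.append((f, det.x, det.y, det.brightness))
            tr.status = "active"
            if len(tr.points) == 2:
                # velocity now observable: seed from the statistics
                vx, vy = statistical_velocity(tr)
                tr.state.S[3], tr.state.S[4] = vx, vy

        survivors = list(matched_tracks(matched))
        for tr in un_tracks:
            tr.state.misses += 1
            if tr.state.misses > config.max_coast or len(tr.points) == 0:
                tr.status = "terminated"
                finished.append(tr)
            else:
                # failed prediction: re-seed velocity from observed history
                vx, vy = statistical_velocity(tr)
                tr.state.S[3], tr.state.S[4] = vx, vy
                tr.status = "coasting"
                survivors.append(tr)

        for det in un_dets:
            tr = _new_track(next_id, det, config)
            next_id += 1
            survivors.append(tr)
        active = survivors
        last_frame = f

    finished.extend(active)
    for tr in finished:
        tr.status = "terminated"
    return [t for t in finished if len(t.points) >= config.min_track_length]


def matched_tracks(matched: list[tuple[Track, Detection]]) -> list[Track]:
    return [tr for tr, _ in matched]


def track_stack_nn(detections: list[Detection], gate_radius: float = 5.0,
                   min_track_length: int = 5) -> list[Track]:
    """Nearest-neighbour baseline: greedy nearest-first matching from the
    last observed position, no prediction, no brightness, no coasting."""
    if not detections:
        return []
    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    frames = sorted(by_frame)

    active: list[Track] = []
    finished: list[Track] = []
    next_id = 0
    for f in frames:
        dets = list(by_frame[f])
        survivors = []
        # greedy: process candidate pairs by increasing distance
        pairs = []
        for i, tr in enumerate(active):
            last_f, x0, y0, _ = tr.points[-1]
            if f - last_f != 1:
                continue
            for j, det in enumerate(dets):
                d = float(np.hypot(det.x - x0, det.y - y0))
                if d <= gate_radius:
                    pairs.append((d, i, j))
        pairs.sort()
        used_t, used_d = set(), set()
        for d, i, j in pairs:
            if i in used_t or j in used_d:
                continue
            used_t.add(i)
            used_d.add(j)
            det = dets[j]
            active[i].points.append((f, det.x, det.y, det.brightness))
            survivors.append(active[i])
        for i, tr in enumerate(active):
            if i not in used_t:
                finished.append(tr)   # no coasting in the baseline
        for j, det in enumerate(dets):
            if j not in used_d:
                tr = Track(track_id=next_id,
                           points=[(f, det.x, det.y, det.brightness)])
                next_id += 1
                survivors.append(tr)
        active = survivors
    finished.extend(active)
    return [t for t in finished if len(t.points) >= min_track_length]
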