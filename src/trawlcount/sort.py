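"""From-scratch SORT: Kalman prediction, IoU assignment, track lifecycle.

Each track carries a constant-velocity Kalman filter over the state
``[u, v, s, r, du, dv, ds]`` — box center (u, v), area s, aspect ratio
r = w/h, and the per-step velocities of the first three. The aspect ratio is
assumed constant, following the original SORT formulation. The tracker's
clock ticks once per *processed* frame: frames skipped by the scheduler are
invisible to it unless ``predict_through_skips`` is enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import BoundingBox, FrameDetections, iou

_DIM_X = 7  # state dimension
_DIM_Z = 4  # measurement dimension (u, v, s, r)


def box_to_z(box: BoundingBox) -> np.ndarray:
    """Box -> measurement vector [u, v, s, r]."""
    return np.array(
        [box.center_x(), box.center_y(), box.area(), box.width / box.height]
    )


def z_to_box(z: np.ndarray, confidence: float = 1.0) -> BoundingBox:
    """Measurement vector [u, v, s, r] -> box. Exact inverse of box_to_z."""
    u, v, s, r = z[:4]
    w = float(np.sqrt(max(s, 1.0) * max(r, 1e-6)))
    h = float(max(s, 1.0) / w)
    return BoundingBox(u - w / 2.0, v - h / 2.0, w, h, confidence)


@dataclass
class TrackerConfig:
    """SORT hyperparameters.

    The defaults (iou_min 0.3, min_hits 3, max_age 3) are conventional SORT
    values except max_age, raised from 1 to 3 to tolerate detector dropouts
    and skipped frames. ``process_noise_scale`` / ``measurement_noise_scale``
    multiply the SORT reference noise matrices; setting both near zero turns
    the filter into an (asymptotically) exact least-squares line fit, which
    the tests exploit.
    """

    iou_min: float = 0.3
    max_age: int = 3
    min_hits: int = 3
    predict_through_skips: bool = False
    process_noise_scale: float = 1.0
    measurement_noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.iou_min < 1.0:
            raise ValueError("iou_min must lie in (0, 1)")
        if self.max_age < 1 or self.min_hits < 1:
            raise ValueError("max_age and min_hits must be >= 1")


def _make_matrices(cfg: TrackerConfig):
    """Constant-velocity transition and SORT reference noise matrices."""
    F = np.eye(_DIM_X)
    F[0, 4] = F[1, 5] = F[2, 6] = 1.0
    H = np.zeros((_DIM_Z, _DIM_X))
    H[0, 0] = H[1, 1] = H[2, 2] = H[3, 3] = 1.0
    R = np.diag([1.0, 1.0, 10.0, 10.0]) * max(cfg.measurement_noise_scale, 1e-12)
    Q = np.eye(_DIM_X)
    Q[-1, -1] *= 0.01
    Q[4:, 4:] *= 0.01
    Q *= max(cfg.process_noise_scale, 1e-12)
    P0 = np.eye(_DIM_X) * 10.0
    P0[4:, 4:] *= 1000.0  # unobservable initial velocities: high variance
    return F, H, R, Q, P0


@dataclass
class KalmanState:
    """State estimate and covariance of one track's Kalman filter."""

    x: np.ndarray  # shape (7,)
    P: np.ndarray  # shape (7, 7)

    @property
    def u(self) -> float:
        return float(self.x[0])

    @property
    def v(self) -> float:
        return float(self.x[1])

    @property
    def s(self) -> float:
        return float(self.x[2])

    @property
    def r(self) -> float:
        return float(self.x[3])

    def to_box(self, confidence: float = 1.0) -> BoundingBox:
        return z_to_box(self.x, confidence)


@dataclass
class Track:
    """One identity hypothesis with Kalman state and lifecycle counters."""

    track_id: int
    state: KalmanState
    hits: int = 1
    time_since_update: int = 0
    confirmed: bool = False
    history: list[tuple[int, BoundingBox]] = field(default_factory=list)

    def last_box(self) -> BoundingBox:
        """Most recently associated observation."""
        return self.history[-1][1]


class SortTracker:
    """Online tracker stepped once per processed frame.

    ``step`` runs predict -> associate -> update/birth/kill and returns the
    currently confirmed tracks. Deterministic given inputs and config.
    """

    def __init__(self, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame_index: int | None = None
        self._F, self._H, self._R, self._Q, self._P0 = _make_matrices(self.config)

    # -- lifecycle primitives -------------------------------------------

    def init_track(self, det: BoundingBox, frame_index: int = 0) -> Track:
        """Birth a track from an unmatched detection: zero velocities."""
        x = np.zeros(_DIM_X)
        x[:4] = box_to_z(det)
        state = KalmanState(x=x, P=self._P0.copy())
        track = Track(self._next_id, state, hits=1, time_since_update=0)
        track.history.append((frame_index, det))
        if self.config.min_hits <= 1:
            track.confirmed = True
        self._next_id += 1
        return track

    def predict(self, track: Track) -> BoundingBox:
        """Advance one constant-velocity step; returns the predicted box.

        If the area velocity would drive the predicted area non-positive it
        is clamped to zero so the state always converts to a valid box.
        """
        x, P = track.state.x, track.state.P
        if x[2] + x[6] <= 1.0:  # keep area >= 1 px^2
            x[6] = 0.0
        x = self._F @ x
        P = self._F @ P @ self._F.T + self._Q
        track.state.x, track.state.P = x, P
        track.time_since_update += 1
        return track.state.to_box()

    def _update(self, track: Track, det: BoundingBox, frame_index: int) -> None:
        """Standard Kalman measurement update with the associated box."""
        x, P = track.state.x, track.state.P
        z = box_to_z(det)
        y = z - self._H @ x
        S = self._H @ P @ self._H.T + self._R
        K = P @ self._H.T @ np.linalg.inv(S)
        track.state.x = x + K @ y
        track.state.P = (np.eye(_DIM_X) - K @ self._H) @ P
        track.hits += 1
        track.time_since_update = 0
        track.history.append((frame_index, det))
        if track.hits >= self.config.min_hits:
            track.confirmed = True

    # -- stepping -------------------------------------------------------

    def step(self, frame: FrameDetections) -> list[Track]:
        """Process one frame of detections; returns confirmed tracks."""
        if (
            self._last_frame_index is not None
            and frame.frame_index <= self._last_frame_index
        ):
            raise ValueError(
                f"frames must arrive in increasing order: got frame "
                f"{frame.frame_index} after {self._last_frame_index}"
            )
        if self.config.predict_through_skips and self._last_frame_index is not None:
            extra = frame.frame_index - self._last_frame_index - 1
            for _ in range(extra):
                for t in self.tracks:
                    self.predict(t)
        self._last_frame_index = frame.frame_index

        predicted = [(t.track_id, self.predict(t)) for t in self.tracks]
        matches, unmatched_dets, _ = associate(
            predicted, frame.detections, self.config.iou_min
        )
        by_id = {t.track_id: t for t in self.tracks}
        for track_id, det_idx in matches:
            self._update(by_id[track_id], frame.detections[det_idx], frame.frame_index)
        for det_idx in unmatched_dets:
            self.tracks.append(
                self.init_track(frame.detections[det_idx], frame.frame_index)
            )
        self.tracks = [
            t for t in self.tracks if t.time_since_update <= self.config.max_age
        ]
        return [t for t in self.tracks if t.confirmed]


def associate(
    predicted: list[tuple[int, BoundingBox]],
    dets: list[BoundingBox],
    iou_min: float = 0.3,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """IoU-optimal one-to-one assignment of detections to predicted boxes.

    Maximizes total IoU (Hungarian algorithm); pairs below ``iou_min`` are
    rejected. Returns ``(matches, unmatched_det_indices,
    unmatched_track_ids)``; the three outputs partition the inputs.
    """
    if not predicted or not dets:
        return [], list(range(len(dets))), [tid for tid, _ in predicted]
    iou_matrix = np.array(
        [[iou(box, det) for det in dets] for _, box in predicted]
    )
    # pairs below iou_min contribute nothing either way; zeroing them
    # before solving makes the thresholded total-IoU objective optimal
    gain = np.where(iou_matrix >= iou_min, iou_matrix, 0.0)
    rows, cols = linear_sum_assignment(-gain)
    matches = []
    matched_rows: set[int] = set()
    matched_cols: set[int] = set()
    for r, c in zip(rows, cols):
        if iou_matrix[r, c] >= iou_min:
            matches.append((predicted[r][0], int(c)))
            matched_rows.add(int(r))
            matched_cols.add(int(c))
    unmatched_dets = [j for j in range(len(dets)) if j not in matched_cols]
    unmatched_tracks = [
        tid for i, (tid, _) in enumerate(predicted) if i not in matched_rows
    ]
    return matches, unmatched_dets, unmatched_tracks
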