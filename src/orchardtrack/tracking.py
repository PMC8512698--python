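"""Appearance-based tracking-by-detection for fruit counting.

The tracker links per-frame detections into identities using, in order:

1. a constant-velocity Kalman filter predicting each track's box;
2. one-to-one assignment between tracks and detections minimising the
   cosine distance between appearance vectors (minimum over the track's
   gallery), gated at ``max_cosine_distance``;
3. a greedy IoU fallback between still-unmatched tracks' predicted boxes
   and still-unmatched detections, for frames where appearance briefly
   fails (motion blur, partial occlusion);
4. track lifecycle management: new tracks start TENTATIVE and are counted
   toward the yield exactly once, when they reach ``confirm_hits``
   associations and become CONFIRMED; tracks unseen for more than
   ``max_age`` frames are DELETED and never revisited.

Motion (Mahalanobis) gating is deliberately absent: association is purely
appearance-driven, and the Kalman filter exists to supply predicted boxes
for the IoU fallback and smoothed positions for reporting.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection_io import Detection, to_corner_form

#: Sentinel cost marking a gated (infeasible) track/detection pair. Strictly
#: larger than any feasible cosine distance (which is at most 2).
INFEASIBLE_COST = 1e5


# ---------------------------------------------------------------------------
# Appearance features


def normalize(v: np.ndarray) -> np.ndarray:
    """Scale a feature vector to unit Euclidean norm."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def cosine_distance(t: np.ndarray, e: np.ndarray) -> float:
    """1 - cos(t, e); 0 iff the vectors are positive scalar multiples.

    Lies in [0, 2]: 0 means identical appearance direction, 1 orthogonal,
    2 opposite.
    """
    t = np.asarray(t, dtype=float)
    e = np.asarray(e, dtype=float)
    if t.shape != e.shape:
        raise ValueError(f"dimension mismatch: {t.shape} vs {e.shape}")
    nt, ne = np.linalg.norm(t), np.linalg.norm(e)
    if nt == 0 or ne == 0:
        raise ValueError("cosine distance undefined for zero-norm vectors")
    return float(1.0 - np.dot(t, e) / (nt * ne))


# ---------------------------------------------------------------------------
# Geometry


def iou(box_a: Sequence[float], box_b: Sequence[float]) -> float:
    """Intersection-over-union of two corner-form boxes (l, t, r, b)."""
    la, ta, ra, ba = box_a
    lb, tb, rb, bb = box_b
    if not (ra > la and ba > ta and rb > lb and bb > tb):
        raise ValueError("boxes must satisfy right > left and bottom > top")
    iw = min(ra, rb) - max(la, lb)
    ih = min(ba, bb) - max(ta, tb)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ra - la) * (ba - ta) + (rb - lb) * (bb - tb) - inter
    return inter / union


# ---------------------------------------------------------------------------
# Kalman filter over (x, y, a, h) and velocities


class KalmanFilter:
    """Constant-velocity linear Kalman filter on the 8-dim box state.

    State: (x, y, a, h, vx, vy, va, vh) — box center, aspect ratio a = w/h,
    height, and their per-frame velocities. Measurement: (x, y, a, h).
    Noise standard deviations scale with the box height: position terms
    ``std_weight_position * h``, velocity terms ``std_weight_velocity * h``
    (the aspect ratio, being dimensionless, uses small fixed terms).
    """

    _F = np.eye(8)
    _F[:4, 4:] = np.eye(4)
    _H = np.eye(4, 8)

    def __init__(self, std_weight_position: float = 1.0 / 20,
                 std_weight_velocity: float = 1.0 / 160) -> None:
        self._wp = std_weight_position
        self._wv = std_weight_velocity

    def initiate(self, measurement: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
        """State from a first measurement: positions set, velocities zero.

        The initial velocity variance is 10x the position variance so early
        predictions stay permissive about motion.
        """
        x, y, a, h = measurement
        if h <= 0 or a <= 0:
            raise ValueError(f"aspect ratio and height must be positive, got a={a}, h={h}")
        mean = np.array([x, y, a, h, 0.0, 0.0, 0.0, 0.0])
        pos = 2.0 * self._wp * h
        std = np.array([
            pos, pos, 1e-2, pos,
            math.sqrt(10.0) * pos, math.sqrt(10.0) * pos,
            math.sqrt(10.0) * 1e-2, math.sqrt(10.0) * pos,
        ])
        return mean, np.diag(std**2)

    def predict(self, mean: np.ndarray, cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """One constant-velocity step plus process noise."""
        h = mean[3]
        q_std = np.array([
            self._wp * h, self._wp * h, 1e-2, self._wp * h,
            self._wv * h, self._wv * h, 1e-5, self._wv * h,
        ])
        mean = self._F @ mean
        cov = self._F @ cov @ self._F.T + np.diag(q_std**2)
        return mean, cov

    def update(
        self, mean: np.ndarray, cov: np.ndarray, measurement: Sequence[float]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Standard linear measurement update with (x, y, a, h)."""
        h = mean[3]
        r_std = np.array([self._wp * h, self._wp * h, 1e-1, self._wp * h])
        R = np.diag(r_std**2)
        z = np.asarray(measurement, dtype=float)
        S = self._H @ cov @ self._H.T + R
        K = np.linalg.solve(S.T, (cov @ self._H.T).T).T  # cov H^T S^-1
        innovation = z - self._H @ mean
        mean = mean + K @ innovation
        cov = cov - K @ S @ K.T
        cov = (cov + cov.T) / 2.0  # keep symmetric
        return mean, cov


def measurement_from_detection(d: Detection) -> tuple[float, float, float, float]:
    """(x, y, a, h) measurement for the Kalman filter from a detection box."""
    return (d.cx, d.cy, d.w / d.h, d.h)


def state_to_corner_box(mean: np.ndarray) -> tuple[float, float, float, float]:
    """Corner-form box from a Kalman state mean (w = a * h)."""
    x, y, a, h = mean[:4]
    w = a * h
    return (x - w / 2.0, y - h / 2.0, x + w / 2.0, y + h / 2.0)


# ---------------------------------------------------------------------------
# Tracks


class TrackState(enum.Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


@dataclass(frozen=True)
class TrackerConfig:
    """Tracker thresholds. Defaults match the field-tested configuration:

    - ``max_cosine_distance`` 0.15 — appearance matches above this are gated;
    - ``max_age`` 30 frames — 1 s at 30 fps before a lost track is discarded;
    - ``confirm_hits`` 3 — a track is confirmed (and counted) once it has
      more than 2 successful associations;
    - ``iou_threshold`` 0.3 — minimum overlap for the IoU fallback;
    - ``gallery_size`` 100 — most recent appearance vectors kept per track.

    ``iou_fallback_scope`` chooses whether the fallback may rescue all
    unmatched non-deleted tracks (``"all"``) or only tentative ones
    (``"tentative"``). ``spawn_suppression_iou`` stops an unmatched
    detection from spawning a new track when it overlaps a detection already
    claimed this frame at or above the given IoU (a stand-in for detector
    non-maximum suppression); set to ``None`` to disable.
    """

    max_cosine_distance: float = 0.15
    max_age: int = 30
    confirm_hits: int = 3
    iou_threshold: float = 0.3
    gallery_size: int = 100
    feature_dim: int = 512
    std_weight_position: float = 1.0 / 20
    std_weight_velocity: float = 1.0 / 160
    iou_fallback_scope: str = "all"
    spawn_suppression_iou: float | None = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.max_cosine_distance <= 2.0):
            raise ValueError("max_cosine_distance must be in (0, 2]")
        if self.max_age < 1:
            raise ValueError("max_age must be >= 1")
        if self.confirm_hits < 1:
            raise ValueError("confirm_hits must be >= 1")
        if not (0.0 <= self.iou_threshold <= 1.0):
            raise ValueError("iou_threshold must be in [0, 1]")
        if self.iou_fallback_scope not in ("all", "tentative"):
            raise ValueError("iou_fallback_scope must be 'all' or 'tentative'")


@dataclass
class Track:
    """One tracked fruit identity."""

    track_id: int
    mean: np.ndarray
    covariance: np.ndarray
    hits: int = 1
    age: int = 1
    time_since_update: int = 0
    state: TrackState = TrackState.TENTATIVE
    gallery: list[np.ndarray] = field(default_factory=list)

    def add_feature(self, feat: np.ndarray, gallery_size: int) -> None:
        self.gallery.append(np.asarray(feat, dtype=float))
        if len(self.gallery) > gallery_size:
            del self.gallery[0]

    @property
    def predicted_box(self) -> tuple[float, float, float, float]:
        return state_to_corner_box(self.mean)


# ---------------------------------------------------------------------------
# Association


def build_cost_matrix(
    tracks: Sequence[Track],
    feats: np.ndarray | Sequence[np.ndarray],
    cfg: TrackerConfig | None = None,
) -> np.ndarray:
    """|tracks| x |feats| appearance cost matrix.

    Entry (i, j) is the minimum cosine distance between detection feature j
    and every vector in track i's gallery; entries exceeding the gate are
    replaced by :data:`INFEASIBLE_COST`.
    """
    cfg = cfg or TrackerConfig()
    feats = np.atleast_2d(np.asarray(feats, dtype=float))
    n_tracks, n_dets = len(tracks), feats.shape[0]
    if n_tracks == 0 or n_dets == 0:
        return np.zeros((n_tracks, n_dets))
    for t in tracks:
        if not t.gallery:
            raise RuntimeError(f"track {t.track_id} has an empty gallery")
    # One stacked matmul over every gallery vector, then a per-track min.
    gallery = np.vstack([np.vstack(t.gallery) for t in tracks])
    gallery = gallery / np.linalg.norm(gallery, axis=1, keepdims=True)
    fnorm = feats / np.linalg.norm(feats, axis=1, keepdims=True)
    dists = 1.0 - gallery @ fnorm.T
    cost = np.empty((n_tracks, n_dets))
    start = 0
    for i, t in enumerate(tracks):
        stop = start + len(t.gallery)
        cost[i] = dists[start:stop].min(axis=0)
        start = stop
    cost[cost > cfg.max_cosine_distance] = INFEASIBLE_COST
    return cost


def hungarian_solve(
    cost: np.ndarray, infeasible: float = INFEASIBLE_COST
) -> set[tuple[int, int]]:
    """Minimum-cost one-to-one assignment; gated pairs are dropped.

    Non-square matrices are padded with a constant at least as large as the
    sentinel so padding never displaces a feasible pair; assignments landing
    on padded rows/columns, or on sentinel entries, are discarded.
    """
    cost = np.atleast_2d(np.asarray(cost, dtype=float))
    r, c = cost.shape
    if r == 0 or c == 0:
        return set()
    n = max(r, c)
    padded = np.full((n, n), infeasible)
    padded[:r, :c] = cost
    rows, cols = linear_sum_assignment(padded)
    return {
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < r and j < c and cost[i, j] < infeasible
    }


# ---------------------------------------------------------------------------
# Tracker


@dataclass
class FrameReport:
    """What happened in one tracker step."""

    frame_index: int
    matches: list[tuple[int, int]]  # (track_id, detection ordinal)
    new_track_ids: list[int]
    confirmed_track_ids: list[int]
    deleted_track_ids: list[int]
    cumulative_count: int


@dataclass
class TrackingResult:
    count: int
    reports: list[FrameReport]
    mot_rows: list[tuple]  # (frame, track_id, left, top, w, h, confidence)
    confirmation_events: list[tuple[int, int]]  # (track_id, frame_confirmed)

    @property
    def per_frame_new_confirmations(self) -> list[int]:
        return [len(r.confirmed_track_ids) for r in self.reports]


class Tracker:
    """Stateful multi-object tracker accumulating a yield count."""

    def __init__(self, cfg: TrackerConfig | None = None) -> None:
        self.cfg = cfg or TrackerConfig()
        self.kf = KalmanFilter(self.cfg.std_weight_position, self.cfg.std_weight_velocity)
        self.tracks: list[Track] = []
        self.count = 0
        self._next_id = 1
        self._frame = 0

    # -- internals --------------------------------------------------------

    def _new_track(self, det: Detection, feat: np.ndarray | None) -> Track:
        mean, cov = self.kf.initiate(measurement_from_detection(det))
        t = Track(track_id=self._next_id, mean=mean, covariance=cov)
        self._next_id += 1
        if feat is not None:
            t.add_feature(feat, self.cfg.gallery_size)
        self.tracks.append(t)
        return t

    # -- public API -------------------------------------------------------

    def step(
        self,
        detections: Sequence[Detection],
        features: np.ndarray | Sequence[np.ndarray] | None,
    ) -> FrameReport:
        """Advance one frame. ``features`` rows align with ``detections``;
        pass ``None`` to run in IoU-only mode (no appearance stage)."""
        cfg = self.cfg
        if features is not None:
            features = np.atleast_2d(np.asarray(features, dtype=float))
            if features.shape[0] != len(detections) and len(detections) > 0:
                raise ValueError(
                    f"{features.shape[0]} feature rows for {len(detections)} detections"
                )

        live = [t for t in self.tracks if t.state is not TrackState.DELETED]
        pre_existing = set(id(t) for t in live)

        # (1) predict
        for t in live:
            t.mean, t.covariance = self.kf.predict(t.mean, t.covariance)

        matched_tracks: set[int] = set()   # indices into `live`
        matched_dets: set[int] = set()
        matches: list[tuple[int, int]] = []

        # (2) appearance association
        if features is not None and live and len(detections) > 0:
            cost = build_cost_matrix(live, features, cfg)
            for ti, dj in sorted(hungarian_solve(cost)):
                matched_tracks.add(ti)
                matched_dets.add(dj)
                matches.append((live[ti].track_id, dj))

        # (3) + (4) IoU fallback, greatest overlap first
        free_tracks = [
            i for i, t in enumerate(live)
            if i not in matched_tracks
            and (cfg.iou_fallback_scope == "all" or t.state is TrackState.TENTATIVE)
        ]
        free_dets = [j for j in range(len(detections)) if j not in matched_dets]
        if free_tracks and free_dets:
            candidates = []
            for i in free_tracks:
                tb = live[i].predicted_box
                if tb[2] <= tb[0] or tb[3] <= tb[1]:
                    continue  # degenerate prediction
                for j in free_dets:
                    v = iou(tb, to_corner_form(detections[j]))
                    if v >= cfg.iou_threshold:
                        candidates.append((v, live[i].track_id, i, j))
            for v, _, i, j in sorted(candidates, key=lambda t: (-t[0], t[1], t[3])):
                if i in matched_tracks or j in matched_dets:
                    continue
                matched_tracks.add(i)
                matched_dets.add(j)
                matches.append((live[i].track_id, j))

        # apply updates to matched tracks
        det_of_track: dict[int, int] = {}
        for tid, dj in matches:
            det_of_track[tid] = dj
        for i in matched_tracks:
            t = live[i]
            dj = det_of_track[t.track_id]
            d = detections[dj]
            t.mean, t.covariance = self.kf.update(
                t.mean, t.covariance, measurement_from_detection(d)
            )
            t.hits += 1
            t.time_since_update = 0
            if features is not None:
                t.add_feature(features[dj], cfg.gallery_size)

        # (5) spawn new tentative tracks from leftover detections
        claimed_boxes = [to_corner_form(detections[j]) for j in matched_dets]
        new_tracks: list[Track] = []
        for j in range(len(detections)):
            if j in matched_dets:
                continue
            box = to_corner_form(detections[j])
            if cfg.spawn_suppression_iou is not None and any(
                iou(box, cb) >= cfg.spawn_suppression_iou for cb in claimed_boxes
            ):
                continue  # duplicate of an already-claimed detection
            feat = features[j] if features is not None else None
            new_tracks.append(self._new_track(detections[j], feat))
            claimed_boxes.append(box)

        # (6) lifecycle
        newly_confirmed: list[int] = []
        deleted: list[int] = []
        for i, t in enumerate(live):
            if i not in matched_tracks:
                t.time_since_update += 1
                if t.state is TrackState.TENTATIVE:
                    # a miss before confirmation kills the track immediately
                    t.state = TrackState.DELETED
                    deleted.append(t.track_id)
                    continue
            if t.state is TrackState.TENTATIVE and t.hits >= cfg.confirm_hits:
                t.state = TrackState.CONFIRMED
                self.count += 1
                newly_confirmed.append(t.track_id)
            if t.state is not TrackState.DELETED and t.time_since_update > cfg.max_age:
                t.state = TrackState.DELETED
                deleted.append(t.track_id)
        for t in new_tracks:
            if t.hits >= cfg.confirm_hits:  # only possible with confirm_hits == 1
                t.state = TrackState.CONFIRMED
                self.count += 1
                newly_confirmed.append(t.track_id)

        # (7) ages advance for tracks that existed before this frame
        for t in self.tracks:
            if t.state is not TrackState.DELETED and id(t) in pre_existing:
                t.age += 1

        report = FrameReport(
            frame_index=self._frame,
            matches=matches,
            new_track_ids=[t.track_id for t in new_tracks],
            confirmed_track_ids=newly_confirmed,
            deleted_track_ids=deleted,
            cumulative_count=self.count,
        )
        self._frame += 1
        return report


def run_tracker(
    frames: Sequence[Sequence[Detection]],
    features_per_frame: Sequence[np.ndarray] | None,
    cfg: TrackerConfig | None = None,
) -> TrackingResult:
    """Run the tracker over an ordered frame sequence and count the yield.

    The final count equals the number of tracks that ever reached CONFIRMED;
    it is deterministic given identical inputs.
    """
    cfg = cfg or TrackerConfig()
    tracker = Tracker(cfg)
    reports: list[FrameReport] = []
    mot_rows: list[tuple] = []
    events: list[tuple[int, int]] = []
    for f, dets in enumerate(frames):
        feats = None
        if features_per_frame is not None:
            feats = features_per_frame[f]
        report = tracker.step(dets, feats)
        reports.append(report)
        for tid in report.confirmed_track_ids:
            events.append((tid, f))
        confirmed_ids = {
            t.track_id for t in tracker.tracks if t.state is TrackState.CONFIRMED
        }
        for tid, dj in report.matches:
            if tid in confirmed_ids:
                d = dets[dj]
                left, top, _, _ = to_corner_form(d)
                mot_rows.append((f, tid, left, top, d.w, d.h, d.confidence))
    return TrackingResult(
        count=tracker.count, reports=reports, mot_rows=mot_rows, confirmation_events=events
    )


def write_mot_csv(rows: Sequence[tuple], path) -> None:
    """MOT-Challenge-like track log: frame,track_id,left,top,w,h,confidence."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "track_id", "left", "top", "w", "h", "confidence"])
        for row in rows:
            writer.writerow(row)


def write_confirmation_csv(events: Sequence[tuple[int, int]], path) -> None:
    """Lifecycle-event log: track_id,frame_confirmed."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["track_id", "frame_confirmed"])
        for tid, f in events:
            writer.writerow([tid, f])


def read_confirmation_csv(path) -> list[tuple[int, int]]:
    import csv

    events: list[tuple[int, int]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (lineno == 1 and row[0].strip().lower() == "track_id"):
                continue
            events.append((int(row[0]), int(row[1])))
    return events
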