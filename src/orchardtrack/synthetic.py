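"""Synthetic orchard scenes with ground truth.

The simulator emulates the statistics of detections from a camera panning
laterally along a fruit-tree row, without rendering any pixels: each fruit is
a box scrolling horizontally through the viewport with a latent unit-norm
appearance vector; per-frame observations add appearance noise, random
detection dropouts, occlusion windows (absence plus blurred, low-confidence
flanking frames), and small distant-row "clutter" boxes whose dimensions fall
below the 30-pixel correction threshold. Everything is deterministic under a
fixed seed, with per-fruit sub-streams spawned from the master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detection_io import Detection
from .geospatial import GPSPoint, SyncConfig, frames_per_gps_point
from .container_opt import ContainerConfig

EARTH_RADIUS_M = 6_371_000.0
FEET_PER_METER = 3.28084


@dataclass(frozen=True)
class SceneConfig:
    """Scene generation parameters.

    The defaults describe a lateral pan along one tree row at 30 fps with a
    1920x1080 viewport: ~45 px fruit, 5% random detection dropout, occasional
    multi-frame occlusions with blurred flanking detections (confidence drawn
    from ``blur_conf_range`` and appearance noise inflated by
    ``blur_noise_multiplier``), and a handful of distant-row clutter boxes
    under 30 px. ``feature_noise_sigma`` is the expected Euclidean norm of
    the appearance noise relative to the unit-norm latent vector.
    """

    n_fruits: int = 40
    n_frames: int = 240
    fps: float = 30.0
    camera_speed_px: float = 16.0
    frame_width: int = 1920
    frame_height: int = 1080
    fruit_size_px: float = 45.0
    fruit_size_sigma: float = 6.0
    feature_dim: int = 512
    feature_noise_sigma: float = 0.05
    dropout_prob: float = 0.05
    occlusion_prob: float = 0.3
    occlusion_duration: tuple[int, int] = (3, 8)
    blur_noise_multiplier: float = 8.0
    blur_conf_range: tuple[float, float] = (0.4, 0.7)
    conf_range: tuple[float, float] = (0.75, 0.99)
    clutter_count: int = 5
    clutter_size_range: tuple[float, float] = (10.0, 29.0)
    jitter_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.dropout_prob, self.occlusion_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.fruit_size_px <= 0 or self.camera_speed_px <= 0:
            raise ValueError("sizes and camera speed must be positive")
        if self.n_frames < 1 or self.n_fruits < 0 or self.clutter_count < 0:
            raise ValueError("n_frames >= 1, counts >= 0 required")


@dataclass
class SceneTruth:
    """Ground truth for a synthetic scene.

    ``true_count`` excludes clutter; ``trajectories`` maps, per real fruit,
    frame index -> (cx, cy, w, h); ``visibility`` flags geometric presence in
    the viewport (a visible fruit may still go undetected through dropout or
    occlusion). Clutter trajectories are kept separately.
    """

    true_count: int
    trajectories: list[dict[int, tuple[float, float, float, float]]]
    latents: np.ndarray  # (n_fruits, feature_dim), unit rows
    visibility: np.ndarray  # (n_fruits, n_frames) bool
    clutter_trajectories: list[dict[int, tuple[float, float, float, float]]] = field(
        default_factory=list
    )


def _fruit_noise(rng: np.random.Generator, sigma: float, dim: int, n: int) -> np.ndarray:
    # per-component std sigma/sqrt(dim) => expected noise norm ~ sigma
    if sigma == 0.0:
        return np.zeros((n, dim))
    return rng.normal(0.0, sigma / math.sqrt(dim), size=(n, dim))


def simulate_scene(
    cfg: SceneConfig,
) -> tuple[list[list[Detection]], list[np.ndarray], SceneTruth]:
    """Generate per-frame detections + appearance features and the truth.

    Each fruit is guaranteed at least ~10 frames of geometric visibility so
    that, absent dropout and occlusion, it can always accumulate enough hits
    to be counted.
    """
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_fruits + cfg.clutter_count)
    s = cfg.camera_speed_px
    w_view = cfg.frame_width
    min_guarantee = 10

    # accumulate (frame, detection, feature) then assemble
    per_frame: list[list[tuple[Detection, np.ndarray]]] = [[] for _ in range(cfg.n_frames)]
    trajectories: list[dict[int, tuple[float, float, float, float]]] = []
    clutter_traj: list[dict[int, tuple[float, float, float, float]]] = []
    visibility = np.zeros((cfg.n_fruits, cfg.n_frames), dtype=bool)
    latents = np.zeros((cfg.n_fruits, cfg.feature_dim))

    def simulate_one(
        rng: np.random.Generator, w0: float, h0: float, is_clutter: bool, fruit_idx: int
    ) -> None:
        # first fully visible frame, leaving room for the guaranteed span
        f0 = int(rng.integers(0, max(1, cfg.n_frames - min_guarantee)))
        x_world = f0 * s + w_view - w0 / 2.0 - rng.uniform(0.0, s)
        margin = 10.0
        lo = h0 / 2.0 + margin
        hi = cfg.frame_height - h0 / 2.0 - margin
        y = rng.uniform(lo, max(lo + 1.0, hi))
        latent = rng.normal(size=cfg.feature_dim)
        latent /= np.linalg.norm(latent)
        if not is_clutter:
            latents[fruit_idx] = latent

        # frames where the box is fully inside the viewport
        vis_frames = [
            f
            for f in range(f0, cfg.n_frames)
            if x_world - w0 / 2.0 >= f * s and x_world + w0 / 2.0 <= f * s + w_view
        ]
        if not vis_frames:
            return
        traj: dict[int, tuple[float, float, float, float]] = {}

        # one occlusion window per affected fruit
        occluded: set[int] = set()
        flanks: set[int] = set()
        if (
            not is_clutter
            and cfg.occlusion_prob > 0
            and rng.random() < cfg.occlusion_prob
            and len(vis_frames) > cfg.occlusion_duration[0] + 4
        ):
            dur = int(rng.integers(cfg.occlusion_duration[0], cfg.occlusion_duration[1] + 1))
            dur = min(dur, len(vis_frames) - 4)
            start_pos = int(rng.integers(2, len(vis_frames) - dur - 1))
            occluded = set(vis_frames[start_pos : start_pos + dur])
            flanks = {vis_frames[start_pos - 1], vis_frames[min(start_pos + dur, len(vis_frames) - 1)]}

        noise = _fruit_noise(rng, cfg.feature_noise_sigma, cfg.feature_dim, len(vis_frames))
        for k, f in enumerate(vis_frames):
            cx_true = x_world - f * s
            box = (cx_true, y, w0, h0)
            traj[f] = box
            if not is_clutter:
                visibility[fruit_idx, f] = True
            if f in occluded:
                continue
            if cfg.dropout_prob > 0 and rng.random() < cfg.dropout_prob:
                continue
            blurred = f in flanks
            eps = noise[k] * (cfg.blur_noise_multiplier if blurred else 1.0)
            feat = latent + eps
            if cfg.feature_noise_sigma > 0:
                feat = feat / np.linalg.norm(feat)
            conf_lo, conf_hi = cfg.blur_conf_range if blurred else cfg.conf_range
            jitter = rng.normal(0.0, cfg.jitter_px, size=2) if cfg.jitter_px > 0 else (0.0, 0.0)
            det = Detection(
                frame_index=f,
                cx=cx_true + jitter[0],
                cy=y + jitter[1],
                w=w0,
                h=h0,
                confidence=float(rng.uniform(conf_lo, conf_hi)),
                class_id=0,
            )
            per_frame[f].append((det, feat))
        (clutter_traj if is_clutter else trajectories).append(traj)

    for i in range(cfg.n_fruits):
        rng = np.random.default_rng(children[i])
        w0 = max(32.0, rng.normal(cfg.fruit_size_px, cfg.fruit_size_sigma))
        h0 = max(32.0, w0 * rng.uniform(0.9, 1.1))
        simulate_one(rng, w0, h0, is_clutter=False, fruit_idx=i)

    for j in range(cfg.clutter_count):
        rng = np.random.default_rng(children[cfg.n_fruits + j])
        w0 = rng.uniform(*cfg.clutter_size_range)
        h0 = rng.uniform(*cfg.clutter_size_range)
        simulate_one(rng, w0, h0, is_clutter=True, fruit_idx=-1)

    frames: list[list[Detection]] = []
    feats: list[np.ndarray] = []
    for f in range(cfg.n_frames):
        frames.append([d for d, _ in per_frame[f]])
        if per_frame[f]:
            feats.append(np.vstack([e for _, e in per_frame[f]]))
        else:
            feats.append(np.zeros((0, cfg.feature_dim)))

    truth = SceneTruth(
        true_count=cfg.n_fruits,
        trajectories=trajectories,
        latents=latents,
        visibility=visibility,
        clutter_trajectories=clutter_traj,
    )
    return frames, feats, truth


def _destination(p: GPSPoint, bearing_deg: float, dist_m: float, seq: int) -> GPSPoint:
    """Spherical destination point along an initial bearing."""
    delta = dist_m / EARTH_RADIUS_M
    theta = math.radians(bearing_deg)
    lat1 = math.radians(p.lat)
    lng1 = math.radians(p.lng)
    lat2 = math.asin(
        math.sin(lat1) * math.cos(delta) + math.cos(lat1) * math.sin(delta) * math.cos(theta)
    )
    lng2 = lng1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(lat1),
        math.cos(delta) - math.sin(lat1) * math.sin(lat2),
    )
    return GPSPoint(lat=math.degrees(lat2), lng=math.degrees(lng2), seq=seq)


def simulate_gps_track(
    start: GPSPoint,
    bearing_deg: float,
    speed_ft_s: float,
    duration_s: float,
    gps_period_s: float,
) -> list[GPSPoint]:
    """Evenly spaced fixes along a constant bearing.

    Consecutive points lie ``speed_ft_s * gps_period_s`` feet apart; the
    track has ``floor(duration_s / gps_period_s) + 1`` points.
    """
    if gps_period_s <= 0 or duration_s < 0 or speed_ft_s < 0:
        raise ValueError("durations and speeds must be non-negative, period positive")
    n = int(math.floor(duration_s / gps_period_s + 1e-9)) + 1
    step_m = speed_ft_s * gps_period_s / FEET_PER_METER
    points = [GPSPoint(lat=start.lat, lng=start.lng, seq=0)]
    for k in range(1, n):
        if step_m == 0.0:
            points.append(GPSPoint(lat=start.lat, lng=start.lng, seq=k))
        else:
            points.append(_destination(points[-1], bearing_deg, step_m, seq=k))
    return points


@dataclass
class FixtureBundle:
    """A mutually consistent scene + GPS fixture for end-to-end runs."""

    frames: list[list[Detection]]
    features: list[np.ndarray]
    gps_points: list[GPSPoint]
    truth: SceneTruth
    scene_cfg: SceneConfig
    sync_cfg: SyncConfig
    container_cfg: ContainerConfig


def end_to_end_fixture(
    scene_cfg: SceneConfig | None = None,
    sync_cfg: SyncConfig | None = None,
    container_cfg: ContainerConfig | None = None,
    start: GPSPoint | None = None,
    bearing_deg: float = 20.0,
    speed_ft_s: float = 4.0,
) -> FixtureBundle:
    """Wire a scene and a GPS track so frame count and fixes are consistent:
    the track has exactly one fix per frame window."""
    scene_cfg = scene_cfg or SceneConfig()
    sync_cfg = sync_cfg or SyncConfig()
    container_cfg = container_cfg or ContainerConfig()
    start = start or GPSPoint(lat=43.91709, lng=-78.6277, seq=0)
    frames, feats, truth = simulate_scene(scene_cfg)
    w = frames_per_gps_point(sync_cfg)
    n_windows = math.ceil(len(frames) / w)
    duration = (n_windows - 1) * sync_cfg.gps_period_s
    gps = simulate_gps_track(start, bearing_deg, speed_ft_s, duration, sync_cfg.gps_period_s)
    if len(gps) < n_windows:
        raise ValueError(
            f"GPS track too short: {len(gps)} points for {n_windows} frame windows"
        )
    return FixtureBundle(
        frames=frames,
        features=feats,
        gps_points=gps,
        truth=truth,
        scene_cfg=scene_cfg,
        sync_cfg=sync_cfg,
        container_cfg=container_cfg,
    )
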