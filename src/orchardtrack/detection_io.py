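"""Per-frame detection records: reading, writing, and size/confidence filtering.

The detector itself (a CNN in the original pipeline) is out of scope here; it
is represented by a plug-in contract plus a CSV dialect, so the tracker can be
fed either from files or from the synthetic scene simulator.

Detection CSV dialect
---------------------
Header ``frame,cx,cy,w,h,confidence,class_id``; comma separated, UTF-8, '.'
decimal separator, one detection per line.  Frame indices are 0-based.
An optional companion feature file (CSV matrix, one row per detection in file
order) carries appearance vectors; see :mod:`orchardtrack.tracking`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np

DETECTION_HEADER = ("frame", "cx", "cy", "w", "h", "confidence", "class_id")


class DetectionParseError(ValueError):
    """Raised when a detection file row cannot be parsed; names the line."""


@dataclass(frozen=True)
class Detection:
    """One detected fruit in one frame.

    ``cx, cy`` are the pixel-wise center coordinates of the bounding box,
    ``w, h`` its width and height in pixels, ``confidence`` the detector
    score in [0, 1] and ``class_id`` the integer class label.
    """

    frame_index: int
    cx: float
    cy: float
    w: float
    h: float
    confidence: float
    class_id: int = 0

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box dimensions must be positive, got w={self.w}, h={self.h}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class DetectionFilterConfig:
    """Detection-correction thresholds.

    ``min_box_size`` discards small boxes coming from fruit in distant tree
    rows; ``min_confidence`` discards low-scoring detections before tracking.
    With ``require_both_dims_small`` (default) a box is discarded only when
    BOTH width and height are below ``min_box_size``; set it to False for the
    disjunctive reading (either dimension small suffices).
    """

    min_box_size: float = 30.0
    min_confidence: float = 0.4
    require_both_dims_small: bool = True

    def __post_init__(self) -> None:
        if self.min_box_size < 0:
            raise ValueError("min_box_size must be >= 0")
        if not (0.0 <= self.min_confidence <= 1.0):
            raise ValueError("min_confidence must be in [0, 1]")


class Detector(Protocol):
    """Plug-in contract: frame image -> detections. Never implemented here."""

    def __call__(self, frame_index: int, image: "np.ndarray") -> list[Detection]: ...


class FeatureExtractor(Protocol):
    """Plug-in contract: detections -> appearance vectors (one row each)."""

    def __call__(self, frame_index: int, detections: Sequence[Detection]) -> np.ndarray: ...


def to_corner_form(d: Detection) -> tuple[float, float, float, float]:
    """Return ``(left, top, right, bottom)`` for a detection's box."""
    return (d.cx - d.w / 2.0, d.cy - d.h / 2.0, d.cx + d.w / 2.0, d.cy + d.h / 2.0)


def from_corner_form(
    frame_index: int,
    corners: tuple[float, float, float, float],
    confidence: float,
    class_id: int = 0,
) -> Detection:
    """Inverse of :func:`to_corner_form`."""
    left, top, right, bottom = corners
    return Detection(
        frame_index=frame_index,
        cx=(left + right) / 2.0,
        cy=(top + bottom) / 2.0,
        w=right - left,
        h=bottom - top,
        confidence=confidence,
        class_id=class_id,
    )


def _is_small(d: Detection, cfg: DetectionFilterConfig) -> bool:
    below_w = d.w < cfg.min_box_size
    below_h = d.h < cfg.min_box_size
    return (below_w and below_h) if cfg.require_both_dims_small else (below_w or below_h)


def filter_detections(
    dets: Sequence[Detection], cfg: DetectionFilterConfig | None = None
) -> list[Detection]:
    """Apply the size and confidence thresholds, preserving order.

    Boxes below the size threshold (strictly; boxes AT the threshold are
    kept) are discarded, as are detections under ``min_confidence``.
    Idempotent; the input is not modified.
    """
    cfg = cfg or DetectionFilterConfig()
    return [d for d in dets if d.confidence >= cfg.min_confidence and not _is_small(d, cfg)]


def filter_frames(
    frames: Sequence[Sequence[Detection]], cfg: DetectionFilterConfig | None = None
) -> tuple[list[list[Detection]], list[list[int]]]:
    """Filter every frame; also return, per frame, the kept row ordinals.

    The ordinals let a caller subset a companion feature matrix so feature
    rows stay aligned with the surviving detections.
    """
    cfg = cfg or DetectionFilterConfig()
    kept_frames: list[list[Detection]] = []
    kept_idx: list[list[int]] = []
    for dets in frames:
        idx = [
            i
            for i, d in enumerate(dets)
            if d.confidence >= cfg.min_confidence and not _is_small(d, cfg)
        ]
        kept_idx.append(idx)
        kept_frames.append([dets[i] for i in idx])
    return kept_frames, kept_idx


def read_detections(path: str | Path) -> list[list[Detection]]:
    """Read a detection CSV, returning detections grouped by frame index.

    Frames with no detections are represented as empty groups up to the
    maximum frame index present. An empty file yields an empty sequence.
    """
    rows: list[Detection] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if not rows and row[0].strip().lower() == "frame":
                continue  # header
            if len(row) != len(DETECTION_HEADER):
                raise DetectionParseError(
                    f"{path}: line {lineno}: expected {len(DETECTION_HEADER)} fields, got {len(row)}"
                )
            try:
                det = Detection(
                    frame_index=int(row[0]),
                    cx=float(row[1]),
                    cy=float(row[2]),
                    w=float(row[3]),
                    h=float(row[4]),
                    confidence=float(row[5]),
                    class_id=int(row[6]),
                )
            except ValueError as exc:
                raise DetectionParseError(f"{path}: line {lineno}: {exc}") from exc
            rows.append(det)
    if not rows:
        return []
    n_frames = max(d.frame_index for d in rows) + 1
    frames: list[list[Detection]] = [[] for _ in range(n_frames)]
    for d in rows:
        frames[d.frame_index].append(d)
    return frames


def write_detections(frames: Sequence[Sequence[Detection]], path: str | Path) -> None:
    """Write detections grouped by frame to the CSV dialect (0-based frames)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("# frame indices are 0-based\n")
        writer = csv.writer(fh)
        writer.writerow(DETECTION_HEADER)
        for dets in frames:
            for d in dets:
                writer.writerow(
                    [d.frame_index, _fmt(d.cx), _fmt(d.cy), _fmt(d.w), _fmt(d.h),
                     _fmt(d.confidence), d.class_id]
                )


def read_feature_csv(path: str | Path) -> np.ndarray:
    """Read a companion feature matrix (total detections x feature_dim)."""
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    return arr


def write_feature_csv(features: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(features), delimiter=",")


def split_features_by_frame(
    frames: Sequence[Sequence[Detection]], features: np.ndarray
) -> list[np.ndarray]:
    """Split a stacked feature matrix into per-frame blocks, in file order."""
    counts = [len(dets) for dets in frames]
    total = sum(counts)
    if features.shape[0] != total:
        raise ValueError(
            f"feature matrix has {features.shape[0]} rows but detections total {total}"
        )
    out: list[np.ndarray] = []
    start = 0
    for c in counts:
        out.append(features[start : start + c])
        start += c
    return out


def _fmt(x: float) -> str:
    """Compact decimal rendering: no scientific notation, no trailing zeros."""
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s not in ("", "-") else "0"
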