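"""GPS synchronization of fruit counts and geo-count export.

A GPS device logs one fix every ``gps_period_s`` seconds while the camera
records at ``fps`` frames per second, so each fix owns a window of
``gps_period_s * fps`` consecutive frames. Newly confirmed tracks within a
window are summed and attached to the fix that opens it, producing geo-count
rows (Lat, Lng, Count) and a GeoJSON layer for mapping.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

EARTH_RADIUS_M = 6_371_000.0
FEET_PER_METER = 3.28084


@dataclass(frozen=True)
class GPSPoint:
    """A WGS84 fix with its order index within the track log."""

    lat: float
    lng: float
    seq: int = 0

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude out of range: {self.lat}")
        if not (-180.0 <= self.lng <= 180.0):
            raise ValueError(f"longitude out of range: {self.lng}")
        if self.seq < 0:
            raise ValueError("seq must be >= 0")


@dataclass(frozen=True)
class SyncConfig:
    """GPS/video synchronization parameters."""

    gps_period_s: float = 3.0
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.gps_period_s <= 0 or self.fps <= 0:
            raise ValueError("gps_period_s and fps must be positive")


@dataclass(frozen=True)
class GeoCount:
    """A GPS coordinate paired with the fruit newly counted in its window."""

    lat: float
    lng: float
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")


def frames_per_gps_point(cfg: SyncConfig) -> int:
    """Number of frames attributed to each GPS fix: period x frame rate.

    The product must be integral (within 1e-9); silent truncation would
    slowly desynchronize counts from coordinates.
    """
    product = cfg.gps_period_s * cfg.fps
    rounded = round(product)
    if rounded <= 0 or abs(product - rounded) > 1e-9:
        raise ValueError(
            f"gps_period_s * fps must be a positive integer; "
            f"got {cfg.gps_period_s} * {cfg.fps} = {product}"
        )
    return int(rounded)


def annotate_counts(
    per_frame_new_confirmations: Sequence[int],
    gps_points: Sequence[GPSPoint],
    cfg: SyncConfig | None = None,
) -> list[GeoCount]:
    """Partition frames into GPS windows and sum new confirmations per window.

    Window k covers frames [k*W, (k+1)*W) and is paired with gps_points[k];
    a trailing partial window is emitted with its partial sum so the total
    over all geo-counts equals the total number of confirmations.
    """
    cfg = cfg or SyncConfig()
    w = frames_per_gps_point(cfg)
    n_frames = len(per_frame_new_confirmations)
    n_windows = math.ceil(n_frames / w) if n_frames else 0
    if len(gps_points) < n_windows:
        raise ValueError(
            f"{n_windows} frame windows but only {len(gps_points)} GPS points"
        )
    out: list[GeoCount] = []
    for k in range(n_windows):
        window_sum = int(sum(per_frame_new_confirmations[k * w : (k + 1) * w]))
        p = gps_points[k]
        out.append(GeoCount(lat=p.lat, lng=p.lng, count=window_sum))
    return out


def haversine_feet(p1: GPSPoint, p2: GPSPoint) -> float:
    """Great-circle distance in feet on a sphere of radius 6,371,000 m."""
    lat1, lat2 = math.radians(p1.lat), math.radians(p2.lat)
    dlat = lat2 - lat1
    dlng = math.radians(p2.lng - p1.lng)
    a = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlng / 2) ** 2
    meters = 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))
    return meters * FEET_PER_METER


def _fmt_coord(x: float) -> str:
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s not in ("", "-") else "0"


def write_geocount_csv(rows: Sequence[GeoCount], path: str | Path) -> None:
    """Write geo-counts with header ``Lat,Lng,Count`` (6-decimal coordinates)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Lat", "Lng", "Count"])
        for r in rows:
            writer.writerow([_fmt_coord(r.lat), _fmt_coord(r.lng), r.count])


def read_geocount_csv(path: str | Path) -> list[GeoCount]:
    rows: list[GeoCount] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if lineno == 1 and row[0].strip().lower() == "lat":
                continue
            if len(row) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields, got {len(row)}")
            try:
                rows.append(GeoCount(lat=float(row[0]), lng=float(row[1]), count=int(row[2])))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return rows


def read_gps_log(path: str | Path) -> list[GPSPoint]:
    """Read a GPS track log CSV with header ``seq,lat,lng``."""
    points: list[GPSPoint] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if lineno == 1 and row[0].strip().lower() == "seq":
                continue
            if len(row) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields, got {len(row)}")
            try:
                points.append(GPSPoint(seq=int(row[0]), lat=float(row[1]), lng=float(row[2])))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    for a, b in zip(points, points[1:]):
        if b.seq <= a.seq:
            raise ValueError(f"{path}: seq must be strictly increasing ({a.seq} -> {b.seq})")
    return points


def write_gps_log(points: Sequence[GPSPoint], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["seq", "lat", "lng"])
        for p in points:
            writer.writerow([p.seq, _fmt_coord(p.lat), _fmt_coord(p.lng)])


def export_geojson(rows: Sequence[GeoCount]) -> dict:
    """RFC 7946 FeatureCollection: one Point per geo-count, (lng, lat) order,
    with the count in ``properties.count`` (suitable for a map tooltip)."""
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [r.lng, r.lat]},
                "properties": {"count": int(r.count)},
            }
            for r in rows
        ],
    }
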