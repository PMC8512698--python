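"""Harvest-container placement along an ordered row of geo-counts.

The optimization minimizes the number of containers subject to (i) every
apple being assigned to exactly one container and (ii) no container holding
more than its capacity in weight. The shipped solver is the sequential scan
the harvest actually follows: apples accumulate into the open container as
the row is traversed; the container is closed and placed at the current
geo-point when it fills (overflow spills into a fresh container — a point's
apples may split across the boundary) or when the distance from the previous
placement reaches ``max_distance_ft``. Without a distance trigger the greedy
forward fill is provably optimal: it uses exactly ceil(total * w / m)
containers.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .geospatial import GeoCount, GPSPoint, haversine_feet

_EPS = 1e-9


@dataclass(frozen=True)
class ContainerConfig:
    """Capacity and placement parameters.

    ``capacity_m`` is the maximum weight per container and ``apple_weight_w``
    the weight per apple; with the default weight of 1 the capacity is
    denominated directly in apples. ``max_distance_ft`` places the open
    container once the traversed distance from the previous placement
    reaches it, even if not full; ``None`` disables the trigger.
    ``allow_split`` lets a geo-point's apples divide across the container
    boundary (required for exact conservation with full containers).
    """

    capacity_m: float = 300.0
    apple_weight_w: float = 1.0
    max_distance_ft: float | None = None
    allow_split: bool = True

    def __post_init__(self) -> None:
        if self.capacity_m <= 0 or self.apple_weight_w <= 0:
            raise ValueError("capacity and apple weight must be positive")
        if self.capacity_m < self.apple_weight_w:
            raise ValueError("capacity must hold at least one apple")
        if self.max_distance_ft is not None and self.max_distance_ft <= 0:
            raise ValueError("max_distance_ft must be positive or None")


@dataclass(frozen=True)
class Container:
    """A placed container: coordinates, assigned apples, and utilization %."""

    lat: float
    lng: float
    assigned: float
    utilization: float  # percent of capacity

    def __post_init__(self) -> None:
        if self.assigned <= 0:
            raise ValueError("a placed container must hold at least some fruit")
        if not (0.0 < self.utilization <= 100.0 + _EPS):
            raise ValueError(f"utilization out of range: {self.utilization}")


@dataclass
class PlacementPlan:
    containers: list[Container]
    total_assigned: float
    #: assignment witness: (geo-point index, container index, apples) spans
    spans: list[tuple[int, int, float]] = field(default_factory=list)
    #: geo-point index at which each container was placed
    placement_indices: list[int] = field(default_factory=list)


@dataclass
class VerificationReport:
    ok: bool
    violations: list[str]


def min_containers_lower_bound(total_count: float, cfg: ContainerConfig) -> int:
    """ceil(total * w / m); 0 for zero apples."""
    if total_count < 0:
        raise ValueError("total_count must be >= 0")
    if total_count == 0:
        return 0
    return math.ceil(total_count * cfg.apple_weight_w / cfg.capacity_m - _EPS)


def place_containers(
    geocounts: Sequence[GeoCount], cfg: ContainerConfig | None = None
) -> PlacementPlan:
    """Single forward scan over the ordered geo-counts.

    At each geo-point, the distance trigger is checked first (the open
    container, if non-empty, is placed here once the gap from the previous
    placement reaches ``max_distance_ft``); then the point's apples fill the
    open container, spilling into fresh containers placed at this point
    whenever capacity is reached. The final open container is placed at the
    last geo-point.
    """
    cfg = cfg or ContainerConfig()
    m, w = cfg.capacity_m, cfg.apple_weight_w
    containers: list[Container] = []
    placement_indices: list[int] = []
    spans: list[tuple[int, int, float]] = []
    open_spans: list[tuple[int, float]] = []
    open_load = 0.0  # weight units
    ref: GPSPoint | None = None  # location of the previous placement

    def place(idx: int, point: GeoCount) -> None:
        nonlocal open_load, ref, open_spans
        k = len(containers)
        containers.append(
            Container(
                lat=point.lat,
                lng=point.lng,
                assigned=open_load / w,
                utilization=100.0 * open_load / m,
            )
        )
        placement_indices.append(idx)
        spans.extend((gi, k, apples) for gi, apples in open_spans)
        open_spans = []
        open_load = 0.0
        ref = GPSPoint(lat=point.lat, lng=point.lng)

    total = 0.0
    for idx, point in enumerate(geocounts):
        total += point.count
        here = GPSPoint(lat=point.lat, lng=point.lng)
        if ref is None:
            ref = here  # traversal start anchors the first distance check
        if (
            cfg.max_distance_ft is not None
            and open_load > _EPS
            and haversine_feet(ref, here) >= cfg.max_distance_ft - _EPS
        ):
            place(idx, point)
        remaining = point.count * w
        while open_load + remaining > m + _EPS:
            if cfg.allow_split:
                take = m - open_load
                if take > _EPS:
                    open_spans.append((idx, take / w))
                    open_load += take
                    remaining -= take
                place(idx, point)
            elif open_load > _EPS:
                # close without splitting: the point's apples start a new container
                place(idx, point)
            else:
                raise ValueError(
                    f"geo-point {idx} holds {point.count} apples, above capacity "
                    f"{m / w:g}, and splitting is disabled"
                )
        if remaining > _EPS:
            open_spans.append((idx, remaining / w))
            open_load += remaining
    if open_load > _EPS:
        last = geocounts[-1]
        place(len(geocounts) - 1, last)

    return PlacementPlan(
        containers=containers,
        total_assigned=total,
        spans=spans,
        placement_indices=placement_indices,
    )


def verify_plan(
    plan: PlacementPlan,
    geocounts: Sequence[GeoCount],
    cfg: ContainerConfig | None = None,
) -> VerificationReport:
    """Audit a plan against the assignment program's constraints.

    Checks conservation (every apple assigned exactly once), per-container
    capacity, the distance-trigger semantics (no container stayed open past a
    geo-point at or beyond ``max_distance_ft`` from the previous placement),
    and that the container count is at least the capacity lower bound.
    Failures are report entries, never exceptions.
    """
    cfg = cfg or ContainerConfig()
    violations: list[str] = []
    total = sum(g.count for g in geocounts)
    assigned = sum(c.assigned for c in plan.containers)
    if abs(assigned - total) > 1e-6:
        violations.append(
            f"exactly-once assignment violated: containers hold {assigned} "
            f"apples but geo-counts total {total}"
        )
    for k, c in enumerate(plan.containers):
        if c.assigned * cfg.apple_weight_w > cfg.capacity_m + 1e-6:
            violations.append(
                f"capacity violated: container {k} holds {c.assigned} apples "
                f"(weight {c.assigned * cfg.apple_weight_w}) > {cfg.capacity_m}"
            )
    lb = min_containers_lower_bound(total, cfg)
    if len(plan.containers) < lb:
        violations.append(
            f"container count {len(plan.containers)} below lower bound {lb}"
        )
    if cfg.max_distance_ft is not None and plan.placement_indices:
        # The trigger must have fired at the first opportunity: every geo-point
        # strictly between consecutive placements lies within max_distance of
        # the earlier placement. (GPS fixes are discrete, so the placement
        # itself may land at or slightly beyond the threshold.)
        prev_idx = 0
        prev_loc = GPSPoint(lat=geocounts[0].lat, lng=geocounts[0].lng)
        for k, idx in enumerate(plan.placement_indices):
            for q in range(prev_idx, idx):
                g = geocounts[q]
                d = haversine_feet(prev_loc, GPSPoint(lat=g.lat, lng=g.lng))
                if d >= cfg.max_distance_ft - _EPS:
                    violations.append(
                        f"distance trigger missed: geo-point {q} is {d:.1f} ft from "
                        f"the previous placement but container {k} stayed open"
                    )
                    break
            prev_idx = idx
            prev_loc = GPSPoint(lat=plan.containers[k].lat, lng=plan.containers[k].lng)
    return VerificationReport(ok=not violations, violations=violations)


def format_utilization(pct: float, decimals: int = 1) -> str:
    """'76.7%'-style rendering; whole percentages print without decimals."""
    r = round(pct, decimals)
    if abs(r - round(r)) < 10 ** (-decimals - 6):
        return f"{int(round(r))}%"
    return f"{r:.{decimals}f}%"


def utilization_table(
    plan: PlacementPlan, decimals: int = 1
) -> list[tuple[float, float, str]]:
    """One row per container: (Latitude, Longitude, Utilization %)."""
    return [
        (c.lat, c.lng, format_utilization(c.utilization, decimals))
        for c in plan.containers
    ]


def write_plan_csv(plan: PlacementPlan, path: str | Path, decimals: int = 1) -> None:
    """Plan CSV with header ``Latitude,Longitude,Utilization``."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Latitude", "Longitude", "Utilization"])
        for lat, lng, util in utilization_table(plan, decimals):
            writer.writerow([f"{lat:.6f}".rstrip("0").rstrip("."),
                             f"{lng:.6f}".rstrip("0").rstrip("."), util])


def plan_geojson(plan: PlacementPlan) -> dict:
    """FeatureCollection of container Points with assigned count/utilization."""
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [c.lng, c.lat]},
                "properties": {
                    "assigned": c.assigned,
                    "utilization_pct": c.utilization,
                },
            }
            for c in plan.containers
        ],
    }
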