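"""Planar route and training-path geometry.

All coordinates are metres in a local, flat, east/north frame (x east-positive,
y north-positive); routes are well under a kilometre so no geodesy is needed.
Bearings follow the map/compass convention: degrees clockwise from north,
normalised to [0, 360).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Point2D",
    "Bearing",
    "RouteMap",
    "TrainingPath",
    "bearing_between",
    "polyline_length",
    "route_distance",
    "absolute_angular_error",
    "DegenerateGeometryError",
]

#: how far (m) an anchor may sit off the polyline before the route is rejected
ANCHOR_ON_ROUTE_TOL = 0.5


class DegenerateGeometryError(ValueError):
    """Raised for geometrically meaningless requests (e.g. bearing of a point
    from itself)."""


@dataclass(frozen=True)
class Point2D:
    """A point in the local planar frame, metres east (x) and north (y)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")

    def __sub__(self, other: "Point2D") -> tuple[float, float]:
        return (self.x - other.x, self.y - other.y)

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class Bearing:
    """Compass bearing: degrees clockwise from north, in [0, 360)."""

    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("non-finite bearing")
        object.__setattr__(self, "value", float(self.value) % 360.0)

    def __add__(self, deg: float) -> "Bearing":
        return Bearing(self.value + deg)

    def __float__(self) -> float:
        return self.value


def bearing_between(a: Point2D, b: Point2D) -> Bearing:
    """Compass bearing of ``b`` as seen from ``a``.

    Note the argument order inside ``atan2``: compass bearings grow clockwise
    from the +y (north) axis, so it is ``atan2(dx, dy)``, not ``atan2(dy, dx)``.
    """
    dx, dy = b.x - a.x, b.y - a.y
    if dx == 0.0 and dy == 0.0:
        raise DegenerateGeometryError("bearing undefined for coincident points")
    return Bearing(math.degrees(math.atan2(dx, dy)))


def polyline_length(vertices: Sequence[Point2D]) -> float:
    """Total arc length of a polyline (sum of segment lengths)."""
    if len(vertices) < 2:
        raise ValueError("a polyline needs at least 2 vertices")
    return float(
        sum(vertices[i].distance_to(vertices[i + 1]) for i in range(len(vertices) - 1))
    )


def absolute_angular_error(estimated: Bearing | float, correct: Bearing | float) -> float:
    """Smallest absolute angle between two bearings, in [0, 180] degrees."""
    d = abs(float(estimated) % 360.0 - float(correct) % 360.0)
    return min(d, 360.0 - d)


def _project_onto_polyline(p: Point2D, vertices: Sequence[Point2D]) -> tuple[float, float]:
    """Return (arc-length position of nearest point on polyline, distance to it)."""
    best_s, best_d = 0.0, math.inf
    s0 = 0.0
    for i in range(len(vertices) - 1):
        a, b = vertices[i], vertices[i + 1]
        abx, aby = b.x - a.x, b.y - a.y
        seg_len = math.hypot(abx, aby)
        if seg_len == 0.0:
            continue
        t = ((p.x - a.x) * abx + (p.y - a.y) * aby) / (seg_len * seg_len)
        t = min(1.0, max(0.0, t))
        qx, qy = a.x + t * abx, a.y + t * aby
        d = math.hypot(p.x - qx, p.y - qy)
        if d < best_d:
            best_d, best_s = d, s0 + t * seg_len
        s0 += seg_len
    return best_s, best_d


@dataclass(frozen=True)
class Anchor:
    """A labelled point on a route; landmarks carry the walker's facing bearing."""

    label: str
    point: Point2D
    facing: Bearing | None = None


@dataclass
class RouteMap:
    """A walked test route: polyline from start to goal plus labelled anchors.

    Anchors are kept in walking order. Paper-style routes carry eleven anchors:
    start, goal, four landmarks and five turns; each landmark's ``facing``
    bearing is the direction the walker faced on encountering it (defaulting to
    the bearing of the polyline segment being walked there).
    """

    name: str
    vertices: list[Point2D]
    anchors: dict[str, Anchor] = field(default_factory=dict)
    north_bearing: float = 0.0

    def __post_init__(self) -> None:
        if polyline_length(self.vertices) <= 0:
            raise ValueError("route has zero length")
        for anc in self.anchors.values():
            _, d = _project_onto_polyline(anc.point, self.vertices)
            if d > ANCHOR_ON_ROUTE_TOL:
                raise ValueError(
                    f"anchor {anc.label!r} lies {d:.2f} m off the polyline "
                    f"(tolerance {ANCHOR_ON_ROUTE_TOL} m)"
                )

    # -- anchor access ------------------------------------------------------
    def anchor_point(self, label: str) -> Point2D:
        try:
            return self.anchors[label].point
        except KeyError:
            raise KeyError(f"unknown anchor label {label!r}") from None

    def facing_at(self, label: str) -> Bearing:
        """Facing direction at an anchor: stored bearing, else the bearing of
        the polyline segment being walked at that anchor."""
        anc = self.anchors[label]
        if anc.facing is not None:
            return anc.facing
        s, _ = _project_onto_polyline(anc.point, self.vertices)
        s0 = 0.0
        for i in range(len(self.vertices) - 1):
            seg = self.vertices[i].distance_to(self.vertices[i + 1])
            if s <= s0 + seg or i == len(self.vertices) - 2:
                return bearing_between(self.vertices[i], self.vertices[i + 1])
            s0 += seg
        raise RuntimeError("unreachable")

    @property
    def landmark_labels(self) -> list[str]:
        return [l for l in self.anchors if l.startswith("landmark")]

    def length(self) -> float:
        return polyline_length(self.vertices)

    # -- distances ----------------------------------------------------------
    def arc_position(self, label: str) -> float:
        s, _ = _project_onto_polyline(self.anchor_point(label), self.vertices)
        return s

    def straight_distance(self, label_a: str, label_b: str) -> float:
        return self.anchor_point(label_a).distance_to(self.anchor_point(label_b))

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "vertices": [[v.x, v.y] for v in self.vertices],
            "anchors": {
                lbl: {
                    "xy": [a.point.x, a.point.y],
                    **({"facing": a.facing.value} if a.facing is not None else {}),
                }
                for lbl, a in self.anchors.items()
            },
            "north_bearing": self.north_bearing,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RouteMap":
        anchors = {
            lbl: Anchor(
                lbl,
                Point2D(*spec["xy"]),
                Bearing(spec["facing"]) if "facing" in spec else None,
            )
            for lbl, spec in d.get("anchors", {}).items()
        }
        return cls(
            name=d.get("name", "route"),
            vertices=[Point2D(x, y) for x, y in d["vertices"]],
            anchors=anchors,
            north_bearing=float(d.get("north_bearing", 0.0)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RouteMap":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_geojson(self) -> dict:
        """GeoJSON FeatureCollection (LineString + labelled Points) for maps."""
        feats = [
            {
                "type": "Feature",
                "properties": {"name": self.name, "kind": "route"},
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[v.x, v.y] for v in self.vertices],
                },
            }
        ]
        for lbl, a in self.anchors.items():
            feats.append(
                {
                    "type": "Feature",
                    "properties": {"label": lbl, "kind": "anchor"},
                    "geometry": {"type": "Point", "coordinates": [a.point.x, a.point.y]},
                }
            )
        return {"type": "FeatureCollection", "features": feats}


def route_distance(route: RouteMap, label_a: str, label_b: str) -> float:
    """Arc length along the route polyline between two anchors.

    ``label_a`` must precede ``label_b`` in walking order; the result is never
    smaller than the straight-line distance between the anchors.
    """
    sa, sb = route.arc_position(label_a), route.arc_position(label_b)
    if sb < sa:
        raise ValueError(
            f"anchor {label_b!r} precedes {label_a!r} in walking order"
        )
    return sb - sa


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper intersection test between open segments p1p2 and p3p4."""

    def cross(o, a, b):
        return (a.x - o.x) * (b.y - o.y) - (a.y - o.y) * (b.x - o.x)

    d1 = cross(p3, p4, p1)
    d2 = cross(p3, p4, p2)
    d3 = cross(p1, p2, p3)
    d4 = cross(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


@dataclass
class TrainingPath:
    """A blindfolded pathway-completion practice path from start S to end E.

    ``shape`` mirrors the three path families used in training: walking the
    outbound legs plus the direct return E->S traces a triangle, a
    quadrilateral, or (for ``crossing``) a figure whose return leg crosses an
    earlier segment. ``north_bearing`` is the direction of true north expressed
    in the path's own coordinate frame.
    """

    shape: str
    vertices: list[Point2D]
    north_bearing: float = 0.0

    VALID_SHAPES = ("triangle", "quadrilateral", "crossing")

    def __post_init__(self) -> None:
        if self.shape not in self.VALID_SHAPES:
            raise ValueError(f"shape must be one of {self.VALID_SHAPES}")
        if len(self.vertices) < 3:
            raise ValueError("a training path needs at least 2 walked segments")
        if self.shape == "crossing" and not self.return_crosses_path():
            raise ValueError("crossing path whose return segment crosses nothing")

    @property
    def start(self) -> Point2D:
        return self.vertices[0]

    @property
    def end(self) -> Point2D:
        return self.vertices[-1]

    def return_crosses_path(self) -> bool:
        """Whether the direct return segment E->S crosses an earlier walked
        segment (ignoring the first and last, which share its endpoints)."""
        e, s = self.end, self.start
        for i in range(1, len(self.vertices) - 2):
            if _segments_intersect(e, s, self.vertices[i], self.vertices[i + 1]):
                return True
        return False

    def walked_length(self) -> float:
        return polyline_length(self.vertices)

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "vertices": [[v.x, v.y] for v in self.vertices],
            "north_bearing": self.north_bearing,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingPath":
        return cls(
            shape=d["shape"],
            vertices=[Point2D(x, y) for x, y in d["vertices"]],
            north_bearing=float(d.get("north_bearing", 0.0)),
        )
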