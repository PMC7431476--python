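"""Scoring of the behavioural tasks.

One participant-session bundle (:class:`ResponseSet`) holds relative direction
estimates among the four route landmarks, route/straight-line distance
estimates expressed as ratios to a walked standard distance, the sketch-map
anchor coordinates, and (for trained participants) pathway-completion and
north-pointing outcomes. Scoring reduces each bundle to a
:class:`SessionScores` row:

- mean absolute direction error (degrees, 0-180) over the six landmark pairs,
- Pearson correlation of estimated vs correct distances and the mean
  estimated/correct ratio, per distance kind,
- bidimensional correlation of the sketch map against the true anchor layout,
- for training tasks: stop-point distance deviation (cm), return-heading
  angular deviation and north-pointing error (degrees).

Direction estimates are recorded the way the response sheet collects them: an
angle measured clockwise from the facing direction at the imagined landmark
("up" on the sheet). Scoring converts to absolute compass bearings using the
route's facing bearing at that landmark.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats as sps

from .bidimreg import PointConfig, fit_similarity
from .geometry import (
    Bearing,
    Point2D,
    RouteMap,
    TrainingPath,
    absolute_angular_error,
    bearing_between,
    route_distance,
)

__all__ = [
    "DirectionEstimate",
    "DistanceEstimate",
    "PathwayOutcome",
    "ResponseSet",
    "SessionScores",
    "score_directions",
    "score_distances",
    "score_pathway",
    "score_sketch",
    "score_response_set",
    "landmark_pairs",
    "direction_errors",
    "distance_ratio_pairs",
]

#: standard distance walked at the start of each session, metres
STANDARD_DISTANCE_M = 32.0


@dataclass(frozen=True)
class DirectionEstimate:
    """Direction from one landmark to another, drawn on the circle sheet.

    ``estimated_bearing_relative`` is measured clockwise from the facing
    direction at ``from_label`` (the sheet's upward reference line).
    """

    from_label: str
    to_label: str
    estimated_bearing_relative: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "estimated_bearing_relative", self.estimated_bearing_relative % 360.0
        )


@dataclass(frozen=True)
class DistanceEstimate:
    """A distance judged as a ratio to the walked standard distance."""

    from_label: str
    to_label: str
    kind: Literal["route", "straight_line"]
    estimated_ratio_to_standard: float

    def __post_init__(self) -> None:
        if self.estimated_ratio_to_standard <= 0:
            raise ValueError("distance ratio must be positive")
        if self.kind not in ("route", "straight_line"):
            raise ValueError(f"unknown distance kind {self.kind!r}")


@dataclass(frozen=True)
class PathwayOutcome:
    """One pathway-completion trial: where the walker stopped and where they
    said north was."""

    stop_point: Point2D
    pointed_north: Bearing
    trial_index: int

    def __post_init__(self) -> None:
        if self.trial_index not in (1, 2):
            raise ValueError("trial_index must be 1 or 2")


@dataclass
class ResponseSet:
    """Everything one participant produced in one session."""

    participant_id: str
    condition: str
    session: int
    directions: list[DirectionEstimate] = field(default_factory=list)
    distances: list[DistanceEstimate] = field(default_factory=list)
    sketch: PointConfig | None = None
    pathway_outcomes: dict[str, list[PathwayOutcome]] = field(default_factory=dict)
    card_rotations_score: float | None = None


@dataclass
class SessionScores:
    """Scored measures for one participant-session."""

    participant_id: str
    condition: str
    session: int
    mean_abs_direction_error: float | None = None
    route_distance_correlation: float | None = None
    straight_distance_correlation: float | None = None
    mean_route_ratio: float | None = None
    mean_straight_ratio: float | None = None
    sketch_bidim_r: float | None = None
    distance_deviation_cm: float | None = None
    direction_deviation_deg: float | None = None
    north_error_deg: float | None = None
    card_rotations_score: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def landmark_pairs(route: RouteMap) -> list[tuple[str, str]]:
    """The six unordered landmark pairs, in walking order."""
    lms = route.landmark_labels
    return list(itertools.combinations(lms, 2))


def direction_errors(route: RouteMap, estimates: Sequence[DirectionEstimate]) -> list[float]:
    """Per-estimate absolute direction errors (degrees, in [0, 180]).

    Each relative estimate is converted to an absolute bearing by adding the
    facing bearing at the imagined landmark, then compared with the true
    bearing between the two landmarks.
    """
    expected = set(landmark_pairs(route)) | {(b, a) for a, b in landmark_pairs(route)}
    errors = []
    for est in estimates:
        pair = (est.from_label, est.to_label)
        if pair not in expected:
            raise KeyError(f"{pair} is not a landmark pair on route {route.name!r}")
        facing = route.facing_at(est.from_label)
        estimated_abs = facing + est.estimated_bearing_relative
        correct = bearing_between(
            route.anchor_point(est.from_label), route.anchor_point(est.to_label)
        )
        errors.append(absolute_angular_error(estimated_abs, correct))
    return errors


def distance_ratio_pairs(
    route: RouteMap,
    estimates: Sequence[DistanceEstimate],
    standard_m: float = STANDARD_DISTANCE_M,
) -> dict[str, tuple[list[float], list[float]]]:
    """Per kind, (estimated metres, correct metres) for each estimate."""
    out: dict[str, tuple[list[float], list[float]]] = {}
    for e in estimates:
        true = (
            route_distance(route, e.from_label, e.to_label)
            if e.kind == "route"
            else route.straight_distance(e.from_label, e.to_label)
        )
        est_m, corr_m = out.setdefault(e.kind, ([], []))
        est_m.append(e.estimated_ratio_to_standard * standard_m)
        corr_m.append(true)
    return out


def score_directions(route: RouteMap, estimates: Sequence[DirectionEstimate]) -> float:
    """Mean absolute error (degrees) of the six relative direction estimates."""
    errors = direction_errors(route, estimates)
    seen = {frozenset((e.from_label, e.to_label)) for e in estimates}
    if len(seen) < len(landmark_pairs(route)):
        missing = {frozenset(p) for p in landmark_pairs(route)} - seen
        raise ValueError(f"missing direction estimates for pairs: {sorted(map(tuple, missing))}")
    return float(np.mean(errors))


def score_distances(
    route: RouteMap,
    estimates: Sequence[DistanceEstimate],
    standard_m: float = STANDARD_DISTANCE_M,
) -> dict[str, tuple[float, float]]:
    """Per distance kind, (Pearson r of estimated vs correct, mean ratio).

    Estimated metres are ``ratio_to_standard * standard_m``; the correct value
    is the route arc length or straight-line distance between the two
    landmarks. The correlation is invariant to ``standard_m`` (a common scale
    factor); the mean estimated/correct ratio is not, which is exactly the
    calibration the ratio measure is meant to expose.
    """
    if standard_m <= 0:
        raise ValueError("standard_m must be positive")
    out: dict[str, tuple[float, float]] = {}
    pairs = distance_ratio_pairs(route, estimates, standard_m)
    for kind, (estimated, correct) in pairs.items():
        if len(estimated) < 3:
            raise ValueError(f"need >= 3 {kind} estimates, got {len(estimated)}")
        correct_arr = np.asarray(correct)
        if np.allclose(correct_arr, correct_arr[0]):
            raise ValueError("correct distances have zero variance; correlation undefined")
        r = float(sps.pearsonr(estimated, correct)[0])
        mean_ratio = float(np.mean(np.asarray(estimated) / correct_arr))
        out[kind] = (r, mean_ratio)
    return out


def score_pathway(
    path: TrainingPath,
    outcome: PathwayOutcome,
    *,
    direction_reference: Literal["return_heading", "start_pointing"] = "return_heading",
) -> tuple[float, float, float]:
    """Score one pathway-completion trial.

    Returns ``(distance_deviation_cm, direction_deviation_deg, north_error_deg)``:
    distance from the stop point to the true start (cm); angular deviation of
    the walked return from the correct return direction (degrees); and the
    north-pointing error (degrees). By default the direction deviation
    compares return-path headings from the path's end E (the walked E->stop
    versus the correct E->S); ``direction_reference="start_pointing"``
    compares bearings of the true and estimated start as seen from E as well
    but anchored at the stop point — selectable because either reading of the
    deviation is defensible.
    """
    s, e = path.start, path.end
    stop = outcome.stop_point
    if stop.distance_to(e) == 0.0:
        raise ValueError("stop point coincides with path end; return heading undefined")
    dist_dev_cm = stop.distance_to(s) * 100.0
    correct_return = bearing_between(e, s)
    if direction_reference == "return_heading":
        walked_return = bearing_between(e, stop)
        dir_dev = absolute_angular_error(walked_return, correct_return)
    elif direction_reference == "start_pointing":
        if stop.distance_to(s) == 0.0:
            dir_dev = 0.0
        else:
            dir_dev = absolute_angular_error(bearing_between(stop, s), correct_return)
    else:
        raise ValueError(f"unknown direction_reference {direction_reference!r}")
    north_err = absolute_angular_error(outcome.pointed_north, Bearing(path.north_bearing))
    return dist_dev_cm, dir_dev, north_err


def route_anchor_config(route: RouteMap) -> PointConfig:
    """True anchor configuration of a route (all labelled anchors, equal weight)."""
    labels = list(route.anchors)
    return PointConfig(labels, [route.anchor_point(l) for l in labels])


def score_sketch(route: RouteMap, sketch: PointConfig) -> float:
    """Bidimensional correlation of a sketch map against the true anchors."""
    return fit_similarity(route_anchor_config(route), sketch).r


def score_response_set(
    route: RouteMap,
    responses: ResponseSet,
    training_paths: dict[str, TrainingPath] | None = None,
    standard_m: float = STANDARD_DISTANCE_M,
) -> SessionScores:
    """Score a full participant-session bundle into one :class:`SessionScores`."""
    scores = SessionScores(
        participant_id=responses.participant_id,
        condition=responses.condition,
        session=responses.session,
        card_rotations_score=responses.card_rotations_score,
    )
    if responses.directions:
        scores.mean_abs_direction_error = score_directions(route, responses.directions)
    if responses.distances:
        by_kind = score_distances(route, responses.distances, standard_m)
        if "route" in by_kind:
            scores.route_distance_correlation, scores.mean_route_ratio = by_kind["route"]
        if "straight_line" in by_kind:
            (
                scores.straight_distance_correlation,
                scores.mean_straight_ratio,
            ) = by_kind["straight_line"]
    if responses.sketch is not None:
        scores.sketch_bidim_r = score_sketch(route, responses.sketch)
    if responses.pathway_outcomes and training_paths:
        dists, dirs, norths = [], [], []
        for path_name, outcomes in responses.pathway_outcomes.items():
            path = training_paths[path_name]
            for oc in outcomes:
                d, a, n = score_pathway(path, oc)
                dists.append(d)
                dirs.append(a)
                norths.append(n)
        scores.distance_deviation_cm = float(np.mean(dists))
        scores.direction_deviation_deg = float(np.mean(dirs))
        scores.north_error_deg = float(np.mean(norths))
    return scores
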