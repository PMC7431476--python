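"""Synthetic route-learning experiments.

Generates complete experiments with the structure of a six-session spatial
learning study: six 450-m test routes with five turns and four landmarks each,
eighteen short training paths (six triangles, six quadrilaterals, six whose
return leg crosses an earlier segment), and a cohort of participants — two
poor-sense-of-direction conditions (feedback_only, training; 20 each, six
sessions) plus an average-sense-of-direction comparison group (20, first
session only) — producing per-session direction estimates, distance-ratio
estimates, sketch maps and (for the training condition) pathway-completion
outcomes.

The noise model is the statistical shell the analysis assumes, not a model of
learning: directions get wrapped-normal noise whose SD is chosen to hit a
target mean absolute error; distance estimates are the true distance times a
positive normal ratio whose mean drifts across sessions; sketch maps are the
true anchor layout under a random similarity transform plus isotropic jitter
calibrated to a target bidimensional correlation. Default targets follow the
published magnitudes for this paradigm (direction errors ~40-52 degrees,
route-distance ratios drifting from ~0.78 toward 1, sketch-map r ~.91-.93,
average group r ~.95). Everything is driven by one integer seed; identical
seeds give identical experiments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import optimize

from .bidimreg import PointConfig
from .geometry import (
    Anchor,
    Bearing,
    Point2D,
    RouteMap,
    TrainingPath,
    _segments_intersect,
    bearing_between,
    polyline_length,
)
from .metrics import (
    STANDARD_DISTANCE_M,
    DirectionEstimate,
    DistanceEstimate,
    PathwayOutcome,
    ResponseSet,
    landmark_pairs,
    route_anchor_config,
)

__all__ = [
    "ConditionParams",
    "CohortSpec",
    "SyntheticExperiment",
    "generate_route",
    "generate_training_paths",
    "generate_responses",
    "generate_experiment",
    "wrapped_normal_mae",
    "wrapped_normal_sd_for_mae",
    "sketch_jitter_for_target_r",
]


# --------------------------------------------------------------------------
# angular-noise calibration
# --------------------------------------------------------------------------

def wrapped_normal_mae(sd: float) -> float:
    """Expected absolute angular error (degrees, in [0, 180]) of wrapped
    N(0, sd) noise.

    Computed by quadrature over the real line, folding each 360-degree band
    back onto (-180, 180]. Approaches sd * sqrt(2/pi) for small sd and 90 (the
    circular-uniform limit) as sd grows.
    """
    if sd == 0:
        return 0.0
    # integrate |wrap(x)| phi(x; 0, sd) on a generous grid
    half_width = max(6 * sd, 360.0)
    x = np.linspace(-half_width, half_width, 20001)
    wrapped = np.abs((x + 180.0) % 360.0 - 180.0)
    phi = np.exp(-0.5 * (x / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
    return float(np.trapezoid(wrapped * phi, x))


@lru_cache(maxsize=1024)
def wrapped_normal_sd_for_mae(target_mae: float) -> float:
    """SD of wrapped-normal angular noise with the given mean absolute error.

    Valid for targets in (0, 90); 90 degrees is the circular-uniform ceiling.
    """
    if target_mae <= 0:
        return 0.0
    if target_mae >= 90:
        raise ValueError("mean absolute angular error must be < 90 degrees")
    return float(optimize.brentq(lambda s: wrapped_normal_mae(s) - target_mae,
                                 1e-6, 2000.0))


def sketch_jitter_for_target_r(route: RouteMap, target_r: float) -> float:
    """Isotropic per-coordinate jitter SD (m) giving roughly the target
    bidimensional correlation for sketches of this route.

    Uses E[SSE] ~ 2(n-2) sigma^2 for n anchors under a similarity fit (four
    parameters absorb part of the noise), so sigma = sqrt(SST (1 - r^2) /
    (2(n-2))).
    """
    if not (0 < target_r <= 1):
        raise ValueError("target r must be in (0, 1]")
    cfg = route_anchor_config(route)
    xy = cfg.as_array()
    sst = float(((xy - xy.mean(axis=0)) ** 2).sum())
    n = len(cfg)
    return math.sqrt(sst * (1 - target_r**2) / (2 * (n - 2)))


# --------------------------------------------------------------------------
# geometry generation
# --------------------------------------------------------------------------

def _polyline_self_intersects(vertices: list[Point2D]) -> bool:
    for i in range(len(vertices) - 1):
        for j in range(i + 2, len(vertices) - 1):
            if _segments_intersect(vertices[i], vertices[i + 1],
                                   vertices[j], vertices[j + 1]):
                return True
    return False


def generate_route(seed: int, length_m: float = 450.0, n_turns: int = 5,
                   n_landmarks: int = 4, name: str | None = None,
                   max_retries: int = 500) -> RouteMap:
    """Generate one self-avoiding test route.

    The polyline has ``n_turns`` interior turn vertices (turn angles around
    +/-90 degrees with jitter) and total length ``length_m``; landmarks are
    placed mid-segment on distinct segments so no two share a segment and none
    sits on a turn. Anchors are labelled in walking order: start, then
    alternating turns/landmarks as encountered, then goal.
    """
    if length_m <= 0:
        raise ValueError("length_m must be positive")
    rng = np.random.default_rng(seed)
    n_segments = n_turns + 1
    for _ in range(max_retries):
        # segment lengths: positive shares of the total, none too short
        w = rng.dirichlet(np.full(n_segments, 4.0))
        seg_lens = length_m * (0.5 * w + 0.5 / n_segments)
        heading = rng.uniform(0, 360)
        turn_signs = rng.choice([-1.0, 1.0], size=n_turns)
        turn_angles = turn_signs * (90.0 + rng.normal(0, 10.0, size=n_turns))
        verts = [Point2D(0.0, 0.0)]
        h = heading
        for i in range(n_segments):
            rad = math.radians(h)
            prev = verts[-1]
            verts.append(Point2D(prev.x + seg_lens[i] * math.sin(rad),
                                 prev.y + seg_lens[i] * math.cos(rad)))
            if i < n_turns:
                h += turn_angles[i]
        if _polyline_self_intersects(verts):
            continue
        # landmarks at quasi-even arc positions (jittered), the way study
        # landmarks are pointed out spread along a walked route; even spacing
        # keeps inter-landmark steps comparable
        fracs = (np.arange(n_landmarks) + 0.5) / n_landmarks
        fracs = np.clip(fracs + rng.uniform(-0.07, 0.07, size=n_landmarks), 0.02, 0.98)
        lm_positions = np.sort(fracs) * length_m
        seg_ends = np.cumsum(seg_lens)
        landmarks: list[tuple[float, Anchor]] = []
        for j, s_pos in enumerate(lm_positions, start=1):
            i = int(np.searchsorted(seg_ends, s_pos))
            i = min(i, n_segments - 1)
            s0 = seg_ends[i - 1] if i > 0 else 0.0
            t = (s_pos - s0) / seg_lens[i]
            a, b = verts[i], verts[i + 1]
            p = Point2D(a.x + t * (b.x - a.x), a.y + t * (b.y - a.y))
            landmarks.append(
                (s_pos, Anchor(f"landmark{j}", p, bearing_between(a, b))))
        # interleave anchors in walking order
        anchors: dict[str, Anchor] = {"start": Anchor("start", verts[0])}
        events = [(seg_ends[i], Anchor(f"turn{i + 1}", verts[i + 1]))
                  for i in range(n_turns)] + landmarks
        for _, anc in sorted(events, key=lambda e: e[0]):
            anchors[anc.label] = anc
        anchors["goal"] = Anchor("goal", verts[-1])
        # the landmark configuration must have genuine 2-D spread: routes with
        # several alternating turns curl into compact shapes, and a nearly
        # collinear/elongated layout makes similarity fits degenerate
        lm_xy = np.array([[anchors[f"landmark{i}"].point.x,
                           anchors[f"landmark{i}"].point.y]
                          for i in range(1, n_landmarks + 1)])
        sv = np.linalg.svd(lm_xy - lm_xy.mean(axis=0), compute_uv=False)
        if n_landmarks >= 3 and sv[-1] < 0.3 * sv[0]:
            continue
        return RouteMap(name=name or f"route-{seed}", vertices=verts,
                        anchors=anchors, north_bearing=0.0)
    raise RuntimeError(f"failed to generate a self-avoiding route in {max_retries} tries")


_CROSSING_TEMPLATE = [(0.0, 0.0), (4.5, 0.0), (4.5, 4.5), (6.5, 2.0)]
_TRIANGLE_TEMPLATE = [(0.0, 0.0), (4.0, 0.0), (2.0, 3.0)]
_QUAD_TEMPLATE = [(0.0, 0.0), (4.0, 0.0), (4.5, 3.5), (0.5, 3.0)]


def _jittered_path(template: Sequence[tuple[float, float]], shape: str,
                   rng: np.random.Generator) -> TrainingPath:
    pts = np.asarray(template, dtype=float)
    pts = pts * rng.uniform(0.8, 1.3)           # overall size
    pts += rng.normal(0, 0.25, size=pts.shape)  # vertex jitter
    pts[0] = (0.0, 0.0)
    th = math.radians(rng.uniform(0, 360))      # random orientation
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    pts = pts @ R.T
    return TrainingPath(shape=shape,
                        vertices=[Point2D(float(x), float(y)) for x, y in pts],
                        north_bearing=float(rng.uniform(0, 360)))


def generate_training_paths(seed: int) -> list[TrainingPath]:
    """Eighteen training paths: 6 triangles, 6 quadrilaterals, 6 crossing.

    Each is a jittered, randomly oriented instance of a template at the scale
    of the practice paths (segments a few metres). Crossing paths are
    validated: the direct return E->S must cross an earlier walked segment
    (guaranteed by the template topology, re-jittered until it holds).
    """
    rng = np.random.default_rng(seed)
    paths: list[TrainingPath] = []
    for shape, template in (("triangle", _TRIANGLE_TEMPLATE),
                            ("quadrilateral", _QUAD_TEMPLATE),
                            ("crossing", _CROSSING_TEMPLATE)):
        made = 0
        while made < 6:
            try:
                paths.append(_jittered_path(template, shape, rng))
            except ValueError:
                continue  # jitter broke the crossing topology; redraw
            made += 1
    return paths


# --------------------------------------------------------------------------
# cohort specification
# --------------------------------------------------------------------------

@dataclass
class ConditionParams:
    """Per-condition noise targets, linearly interpolated across sessions."""

    name: str
    n_participants: int = 20
    sessions: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    direction_mae_first: float = 50.0
    direction_mae_last: float = 50.0
    route_ratio_first: float = 1.0
    route_ratio_last: float = 1.0
    straight_ratio_first: float = 1.0
    straight_ratio_last: float = 1.0
    ratio_sd: float = 0.18
    sketch_r_first: float = 0.91
    sketch_r_last: float = 0.93
    pathway: bool = False
    stop_sd_cm: float = 80.0
    pointing_mae_deg: float = 18.0

    def _interp(self, first: float, last: float, session: int) -> float:
        lo, hi = min(self.sessions), max(self.sessions)
        if hi == lo:
            return first
        frac = (session - lo) / (hi - lo)
        return first + frac * (last - first)

    def direction_mae(self, session: int) -> float:
        return self._interp(self.direction_mae_first, self.direction_mae_last, session)

    def route_ratio(self, session: int) -> float:
        return self._interp(self.route_ratio_first, self.route_ratio_last, session)

    def straight_ratio(self, session: int) -> float:
        return self._interp(self.straight_ratio_first, self.straight_ratio_last, session)

    def sketch_r(self, session: int) -> float:
        return self._interp(self.sketch_r_first, self.sketch_r_last, session)


def _default_conditions() -> dict[str, ConditionParams]:
    # magnitudes follow the published cohort for this paradigm
    return {
        "feedback_only": ConditionParams(
            name="feedback_only",
            direction_mae_first=51.60, direction_mae_last=49.84,
            route_ratio_first=0.78, route_ratio_last=1.11,
            straight_ratio_first=0.90, straight_ratio_last=1.07,
            sketch_r_first=0.90, sketch_r_last=0.94,
        ),
        "training": ConditionParams(
            name="training",
            direction_mae_first=44.57, direction_mae_last=38.60,
            route_ratio_first=0.78, route_ratio_last=1.11,
            straight_ratio_first=0.90, straight_ratio_last=1.07,
            sketch_r_first=0.91, sketch_r_last=0.93,
            pathway=True,
        ),
        "average": ConditionParams(
            name="average",
            sessions=(1,),
            direction_mae_first=27.06, direction_mae_last=27.06,
            route_ratio_first=1.02, route_ratio_last=1.02,
            straight_ratio_first=1.20, straight_ratio_last=1.20,
            sketch_r_first=0.95, sketch_r_last=0.95,
        ),
    }


@dataclass
class CohortSpec:
    """Everything needed to generate one synthetic experiment."""

    seed: int = 0
    n_sessions: int = 6
    route_length_m: float = 450.0
    n_turns: int = 5
    n_landmarks: int = 4
    standard_m: float = STANDARD_DISTANCE_M
    conditions: dict[str, ConditionParams] = field(default_factory=_default_conditions)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_sessions": self.n_sessions,
            "route_length_m": self.route_length_m,
            "n_turns": self.n_turns,
            "n_landmarks": self.n_landmarks,
            "standard_m": self.standard_m,
            "conditions": {k: asdict(v) for k, v in self.conditions.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        conds = {k: ConditionParams(**{**v, "sessions": tuple(v["sessions"])})
                 for k, v in d.get("conditions", {}).items()}
        return cls(seed=d.get("seed", 0), n_sessions=d.get("n_sessions", 6),
                   route_length_m=d.get("route_length_m", 450.0),
                   n_turns=d.get("n_turns", 5), n_landmarks=d.get("n_landmarks", 4),
                   standard_m=d.get("standard_m", STANDARD_DISTANCE_M),
                   conditions=conds or _default_conditions())


@dataclass
class SyntheticExperiment:
    """A generated experiment with its full ground truth retained."""

    spec: CohortSpec
    routes: list[RouteMap]
    training_paths: list[TrainingPath]
    responses: list[ResponseSet]

    def route_for_session(self, session: int) -> RouteMap:
        return self.routes[session - 1]

    def training_paths_for_session(self, session: int) -> dict[str, TrainingPath]:
        """Three paths (one per shape) assigned to a session, fixed across
        participants."""
        tri = self.training_paths[0:6]
        quad = self.training_paths[6:12]
        cross = self.training_paths[12:18]
        i = session - 1
        return {f"tri{i+1}": tri[i], f"quad{i+1}": quad[i], f"cross{i+1}": cross[i]}


# --------------------------------------------------------------------------
# response generation
# --------------------------------------------------------------------------

def _wrapped_noise(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    return rng.normal(0.0, sd, size=size) if sd > 0 else np.zeros(size)


def _positive_ratio(rng: np.random.Generator, mean: float, sd: float,
                    size: int, floor: float = 0.05) -> np.ndarray:
    r = rng.normal(mean, sd, size=size) if sd > 0 else np.full(size, mean)
    return np.maximum(r, floor)


def _simulate_session_responses(
    route: RouteMap,
    params: ConditionParams,
    session: int,
    spec: CohortSpec,
    rng: np.random.Generator,
    participant_id: str,
    training_paths: dict[str, TrainingPath] | None,
) -> ResponseSet:
    rs = ResponseSet(participant_id=participant_id, condition=params.name,
                     session=session)
    dir_sd = wrapped_normal_sd_for_mae(params.direction_mae(session))
    pairs = landmark_pairs(route)

    # direction estimates: relative angle = true bearing - facing + noise
    noise = _wrapped_noise(rng, dir_sd, len(pairs))
    for (a, b), eps in zip(pairs, noise):
        facing = route.facing_at(a).value
        true_b = bearing_between(route.anchor_point(a), route.anchor_point(b)).value
        rs.directions.append(
            DirectionEstimate(a, b, (true_b - facing + eps) % 360.0))

    # distance estimates as ratios to the walked standard
    for kind, mean in (("route", params.route_ratio(session)),
                       ("straight_line", params.straight_ratio(session))):
        ratios = _positive_ratio(rng, mean, params.ratio_sd, len(pairs))
        for (a, b), rr in zip(pairs, ratios):
            true = (route.arc_position(b) - route.arc_position(a) if kind == "route"
                    else route.straight_distance(a, b))
            rs.distances.append(DistanceEstimate(
                a, b, kind, rr * true / spec.standard_m))

    # sketch map: similarity transform of the true anchors + isotropic jitter
    truth = route_anchor_config(route)
    sigma = sketch_jitter_for_target_r(route, params.sketch_r(session))
    xy = truth.as_array() + rng.normal(0, sigma, size=(len(truth), 2))
    th = rng.uniform(0, 2 * math.pi)
    R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    scale = rng.uniform(0.02, 0.05)  # page units per metre
    xy = scale * xy @ R.T + rng.uniform(5, 15, size=2)
    rs.sketch = PointConfig.from_array(truth.labels, xy)

    # pathway completion + north pointing (training condition only)
    if params.pathway and training_paths:
        point_sd = wrapped_normal_sd_for_mae(params.pointing_mae_deg)
        for pname, path in training_paths.items():
            outs = []
            for trial in (1, 2):
                shrink = 1.0 if trial == 1 else 0.75  # feedback helps trial 2
                stop = Point2D(
                    path.start.x + rng.normal(0, shrink * params.stop_sd_cm / 100),
                    path.start.y + rng.normal(0, shrink * params.stop_sd_cm / 100))
                pointed = Bearing(path.north_bearing +
                                  float(_wrapped_noise(rng, point_sd, 1)[0]))
                outs.append(PathwayOutcome(stop_point=stop, pointed_north=pointed,
                                           trial_index=trial))
            rs.pathway_outcomes[pname] = outs
    return rs


def generate_responses(spec: CohortSpec, routes: list[RouteMap],
                       training_paths: list[TrainingPath]) -> list[ResponseSet]:
    """Generate every participant-session response bundle for a cohort."""
    rng = np.random.default_rng(spec.seed)
    prefix = {"feedback_only": "f", "training": "t", "average": "a"}
    responses: list[ResponseSet] = []
    tri, quad, cross = (training_paths[0:6], training_paths[6:12],
                        training_paths[12:18])
    for cname, params in spec.conditions.items():
        for i in range(params.n_participants):
            pid = f"{prefix.get(cname, cname[:1])}{i + 1:02d}"
            for session in params.sessions:
                tp = None
                if params.pathway:
                    j = session - 1
                    tp = {f"tri{j+1}": tri[j], f"quad{j+1}": quad[j],
                          f"cross{j+1}": cross[j]}
                responses.append(_simulate_session_responses(
                    routes[session - 1], params, session, spec, rng, pid, tp))
    return responses


def generate_experiment(spec: CohortSpec | None = None) -> SyntheticExperiment:
    """Generate routes, training paths and all responses from one seed."""
    spec = spec or CohortSpec()
    # route/path seeds derived deterministically from the cohort seed
    root = np.random.SeedSequence(spec.seed)
    route_seeds = root.spawn(spec.n_sessions + 1)
    routes = [
        generate_route(int(s.generate_state(1)[0] % (2**31)),
                       length_m=spec.route_length_m, n_turns=spec.n_turns,
                       n_landmarks=spec.n_landmarks, name=f"route-{i + 1}")
        for i, s in enumerate(route_seeds[:-1])
    ]
    paths = generate_training_paths(
        int(route_seeds[-1].generate_state(1)[0] % (2**31)))
    responses = generate_responses(spec, routes, paths)
    return SyntheticExperiment(spec=spec, routes=routes, training_paths=paths,
                               responses=responses)
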