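import math

import numpy as np
import pytest
from scipy import stats as sps

from surveylearn.bidimreg import PointConfig
from surveylearn.geometry import Bearing, Point2D, TrainingPath, bearing_between
from surveylearn.metrics import (
    DirectionEstimate,
    DistanceEstimate,
    PathwayOutcome,
    ResponseSet,
    landmark_pairs,
    route_anchor_config,
    score_directions,
    score_distances,
    score_pathway,
    score_response_set,
    score_sketch,
)


def perfect_direction_estimates(route, offset=0.0):
    """Relative estimates that are exactly correct (plus a constant offset)."""
    ests = []
    for a, b in landmark_pairs(route):
        facing = route.facing_at(a).value
        true_b = bearing_between(route.anchor_point(a), route.anchor_point(b)).value
        ests.append(DirectionEstimate(a, b, (true_b - facing + offset) % 360))
    return ests


class TestScoreDirections:
    def test_exact_estimates_zero_error(self, l_route):
        assert score_directions(l_route, perfect_direction_estimates(l_route)) == 0.0

    def test_constant_offset_scores_the_offset(self, l_route):
        assert score_directions(
            l_route, perfect_direction_estimates(l_route, offset=30.0)
        ) == pytest.approx(30.0)

    def test_randomized_fixture_matches_hand_oracle(self, l_route):
        rng = np.random.default_rng(8)
        ests, oracle_errors = [], []
        for a, b in landmark_pairs(l_route):
            rel = rng.uniform(0, 360)
            ests.append(DirectionEstimate(a, b, rel))
            # hand computation: absolute estimate, then wrapped difference
            facing = l_route.facing_at(a).value
            true_b = bearing_between(
                l_route.anchor_point(a), l_route.anchor_point(b)).value
            diff = abs((facing + rel) % 360 - true_b)
            oracle_errors.append(min(diff, 360 - diff))
        assert score_directions(l_route, ests) == pytest.approx(np.mean(oracle_errors))

    def test_missing_pair_rejected(self, l_route):
        with pytest.raises(ValueError, match="missing direction estimates"):
            score_directions(l_route, perfect_direction_estimates(l_route)[:-1] or [])

    def test_unknown_pair_rejected(self, l_route):
        with pytest.raises(KeyError):
            score_directions(l_route, [DirectionEstimate("start", "goal", 0.0)])


def estimates_from_truth(route, factor, kind, standard=32.0):
    ests = []
    for a, b in landmark_pairs(route):
        true = (route.arc_position(b) - route.arc_position(a)
                if kind == "route" else route.straight_distance(a, b))
        ests.append(DistanceEstimate(a, b, kind, factor * true / standard))
    return ests


class TestScoreDistances:
    def test_exact_estimates(self, l_route):
        # only one landmark pair on the 2-landmark fixture: use synthetic route
        from surveylearn.synth import generate_route

        route = generate_route(12)
        out = score_distances(route, estimates_from_truth(route, 1.0, "route"))
        r, ratio = out["route"]
        assert r == pytest.approx(1.0)
        assert ratio == pytest.approx(1.0)

    def test_half_scale_blind_spot_of_r(self):
        from surveylearn.synth import generate_route

        route = generate_route(12)
        out = score_distances(route, estimates_from_truth(route, 0.5, "straight_line"))
        r, ratio = out["straight_line"]
        assert r == pytest.approx(1.0)
        assert ratio == pytest.approx(0.5)

    def test_noisy_fixture_matches_pearson_oracle(self):
        from surveylearn.synth import generate_route

        route = generate_route(12)
        rng = np.random.default_rng(3)
        ests, est_m, corr_m = [], [], []
        for a, b in landmark_pairs(route):
            true = route.straight_distance(a, b)
            noisy = true * rng.uniform(0.6, 1.4)
            ests.append(DistanceEstimate(a, b, "straight_line", noisy / 32.0))
            est_m.append(noisy)
            corr_m.append(true)
        r, ratio = score_distances(route, ests)["straight_line"]
        assert r == pytest.approx(sps.pearsonr(est_m, corr_m)[0], abs=1e-12)
        assert ratio == pytest.approx(np.mean(np.array(est_m) / np.array(corr_m)))

    def test_correlation_invariant_to_standard_calibration(self):
        from surveylearn.synth import generate_route

        route = generate_route(12)
        rng = np.random.default_rng(3)
        ests = [
            DistanceEstimate(a, b, "route",
                             rng.uniform(0.5, 3.0))
            for a, b in landmark_pairs(route)
        ]
        r1, ratio1 = score_distances(route, ests, standard_m=32.0)["route"]
        r2, ratio2 = score_distances(route, ests, standard_m=64.0)["route"]
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert ratio2 == pytest.approx(2 * ratio1)  # ratio scales with standard

    def test_too_few_estimates(self, l_route):
        ests = estimates_from_truth(l_route, 1.0, "route")  # single pair
        with pytest.raises(ValueError, match=">= 3"):
            score_distances(l_route, ests)


class TestScorePathway:
    def test_perfect_return(self, triangle_path):
        out = PathwayOutcome(stop_point=Point2D(0, 0), pointed_north=Bearing(0), trial_index=1)
        assert score_pathway(triangle_path, out) == pytest.approx((0.0, 0.0, 0.0))

    def test_explicit_trig_oracle(self):
        # E due south of S; stop 1 m east of S
        path = TrainingPath("triangle",
                            [Point2D(0, 0), Point2D(3, -2), Point2D(0, -4)],
                            north_bearing=0.0)
        out = PathwayOutcome(stop_point=Point2D(1, 0), pointed_north=Bearing(25),
                             trial_index=2)
        dist_cm, dir_dev, north_err = score_pathway(path, out)
        assert dist_cm == pytest.approx(100.0)
        # correct return bearing E->S is due north (0); walked E->stop is
        # atan2(1, 4) east of north
        assert dir_dev == pytest.approx(math.degrees(math.atan2(1, 4)))
        assert north_err == pytest.approx(25.0)

    def test_start_pointing_variant(self):
        path = TrainingPath("triangle",
                            [Point2D(0, 0), Point2D(3, -2), Point2D(0, -4)])
        out = PathwayOutcome(stop_point=Point2D(1, 0), pointed_north=Bearing(0),
                             trial_index=1)
        _, dev, _ = score_pathway(path, out, direction_reference="start_pointing")
        # bearing from stop (1,0) to S (0,0) is due west = 270; correct 0
        assert dev == pytest.approx(90.0)

    def test_stop_at_end_degenerate(self, triangle_path):
        out = PathwayOutcome(stop_point=triangle_path.end, pointed_north=Bearing(0),
                             trial_index=1)
        with pytest.raises(ValueError, match="return heading undefined"):
            score_pathway(triangle_path, out)

    def test_noisy_agents_in_reported_human_range(self, triangle_path):
        # agents with moderate encoding noise land near published human
        # pathway-completion deviations (~100-170 cm, ~15-24 deg)
        rng = np.random.default_rng(21)
        dists, devs = [], []
        for _ in range(400):
            stop = Point2D(triangle_path.start.x + rng.normal(0, 1.1),
                           triangle_path.start.y + rng.normal(0, 1.1))
            out = PathwayOutcome(stop_point=stop, pointed_north=Bearing(0),
                                 trial_index=1)
            d, a, _ = score_pathway(triangle_path, out)
            dists.append(d)
            devs.append(a)
        assert 80 < np.mean(dists) < 200
        assert 5 < np.mean(devs) < 35


class TestScoreResponseSet:
    def test_zero_noise_bundle_scores_perfectly(self):
        from surveylearn.synth import generate_route

        route = generate_route(12)
        rs = ResponseSet("p1", "training", 1)
        rs.directions = perfect_direction_estimates(route)
        rs.distances = (estimates_from_truth(route, 1.0, "route")
                        + estimates_from_truth(route, 1.0, "straight_line"))
        rs.sketch = route_anchor_config(route)
        scores = score_response_set(route, rs)
        assert scores.mean_abs_direction_error == pytest.approx(0.0, abs=1e-9)
        assert scores.route_distance_correlation == pytest.approx(1.0)
        assert scores.mean_straight_ratio == pytest.approx(1.0)
        assert scores.sketch_bidim_r == pytest.approx(1.0)

    def test_sketch_score_invariant_to_page_frame(self):
        from conftest import similarity_transform
        from surveylearn.synth import generate_route

        route = generate_route(12)
        truth = route_anchor_config(route)
        page = similarity_transform(truth.as_array(), 0.03, 124.0, 9.0, 4.0)
        drawn = PointConfig.from_array(truth.labels, page)
        assert score_sketch(route, drawn) == pytest.approx(1.0, abs=1e-9)
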