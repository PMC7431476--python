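"""Monte Carlo simulation of sketch-map drawing from distance/direction errors.

The simulation asks: if a participant drew a map using nothing but their
(noisy) straight-line distance and relative direction judgments, how accurate
would it look? Starting from the first landmark of a route (fixed at its true
position), each subsequent landmark is placed at

    sampled_ratio * true straight-line distance from the previous landmark,

along the true inter-landmark bearing perturbed by a sampled direction error.
Ratios and direction-error magnitudes are drawn from normal distributions with
the mean/SD observed for (or assigned to) the cohort; each simulated
configuration is scored against the true landmark layout by bidimensional
regression, and the mean r over iterations summarises how much configural
accuracy the distance/direction judgments alone could support.

An *absolute* direction error carries no sign, so the default sign convention
("symmetric") samples a non-negative magnitude from the stated normal
(truncated at zero) and applies a random +/- sign at each step; the
"positive" variant applies every sampled magnitude clockwise, which rotates
the chain coherently and is kept selectable for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

from .bidimreg import PointConfig, bidim_r
from .geometry import Point2D, RouteMap, bearing_between
from .stats import fisher_z, one_sample_t

__all__ = ["ErrorModel", "SimulationResult", "simulate_sketch", "run_simulation",
           "compare_observed_vs_simulated"]

#: floor for sampled distance ratios, keeps placements non-degenerate
RATIO_FLOOR = 0.01


@dataclass(frozen=True)
class ErrorModel:
    """Normal error distributions for straight-line distance ratios and
    absolute direction errors (degrees)."""

    ratio_mean: float = 1.0
    ratio_sd: float = 0.0
    direrr_mean: float = 0.0
    direrr_sd: float = 0.0
    sign_convention: Literal["symmetric", "positive"] = "symmetric"

    def __post_init__(self) -> None:
        if self.ratio_sd < 0 or self.direrr_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.sign_convention not in ("symmetric", "positive"):
            raise ValueError("sign_convention must be 'symmetric' or 'positive'")


@dataclass
class SimulationResult:
    """Outcome of a seeded Monte Carlo run."""

    iterations: int
    mean_bidim_r: float
    per_iteration_r: list[float]
    seed: int

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if len(self.per_iteration_r) != self.iterations:
            raise ValueError("per-iteration list length mismatch")

    @property
    def se_r(self) -> float:
        """Monte Carlo standard error of the mean per-iteration r."""
        if self.iterations < 2:
            return float("nan")
        return float(np.std(self.per_iteration_r, ddof=1) / math.sqrt(self.iterations))

    def to_dict(self) -> dict:
        return {"iterations": self.iterations, "mean_bidim_r": self.mean_bidim_r,
                "seed": self.seed, "se_r": self.se_r}


def _sample_truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                             lower: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated below at ``lower``; degenerate sd collapses
    to the (clipped) mean."""
    if sd == 0.0:
        return np.full(size, max(mean, lower))
    a = (lower - mean) / sd
    return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_sketch(route: RouteMap, model: ErrorModel,
                    rng: np.random.Generator) -> PointConfig:
    """Draw one simulated landmark configuration for a route.

    The first landmark is pinned to its true position; each later landmark is
    chained from the previous one with a sampled distance ratio and a
    perturbed bearing. Only consecutive-landmark distances and bearings enter
    the placement.
    """
    labels = route.landmark_labels
    if len(labels) < 2:
        raise ValueError("route needs at least 2 landmarks to simulate")
    n_steps = len(labels) - 1
    ratios = _sample_truncated_normal(rng, model.ratio_mean, model.ratio_sd,
                                      RATIO_FLOOR, n_steps)
    magnitudes = _sample_truncated_normal(rng, model.direrr_mean, model.direrr_sd,
                                          0.0, n_steps)
    if model.sign_convention == "symmetric":
        signs = rng.choice([-1.0, 1.0], size=n_steps)
    else:
        signs = np.ones(n_steps)
    if not (np.all(np.isfinite(ratios)) and np.all(np.isfinite(magnitudes))):
        raise ValueError("non-finite samples from the error model")

    pts = [route.anchor_point(labels[0])]
    for i in range(n_steps):
        prev_true = route.anchor_point(labels[i])
        next_true = route.anchor_point(labels[i + 1])
        true_dist = prev_true.distance_to(next_true)
        true_bearing = bearing_between(prev_true, next_true).value
        bearing = math.radians(true_bearing + signs[i] * magnitudes[i])
        step = ratios[i] * true_dist
        prev = pts[-1]
        # compass convention: x += sin(bearing), y += cos(bearing)
        pts.append(Point2D(prev.x + step * math.sin(bearing),
                           prev.y + step * math.cos(bearing)))
    return PointConfig(list(labels), pts)


def run_simulation(route: RouteMap, model: ErrorModel, iterations: int = 1000,
                   seed: int = 0) -> SimulationResult:
    """Run the sketch-drawing simulation and average the bidimensional r.

    Bit-reproducible for a given seed. If the route's landmarks are nearly
    collinear the no-reflection fit becomes unstable; a warning is emitted.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    labels = route.landmark_labels
    truth = PointConfig(list(labels), [route.anchor_point(l) for l in labels])
    xy = truth.as_array()
    centered = xy - xy.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-6 * sv[0]:
        import warnings

        warnings.warn("landmarks are nearly collinear; bidimensional fits are "
                      "reflection-sensitive", stacklevel=2)
    rng = np.random.default_rng(seed)
    rs = [bidim_r(truth, simulate_sketch(route, model, rng)) for _ in range(iterations)]
    return SimulationResult(iterations=iterations, mean_bidim_r=float(np.mean(rs)),
                            per_iteration_r=[float(v) for v in rs], seed=seed)


def compare_observed_vs_simulated(
    observed_r: Sequence[float], result: SimulationResult
) -> dict:
    """Test observed sketch-map correlations against the simulated mean.

    One-sample t of the participants' Fisher-z transformed r values against
    the z-transformed simulated mean r. Returns a dict with t, df, p, d_z and
    both means on the r scale.
    """
    if len(observed_r) < 2:
        raise ValueError("need at least 2 observed correlations")
    # r = 1 (a perfect map) has infinite z; clip just inside the boundary
    clip = 1.0 - 1e-12
    z_obs = np.arctanh(np.clip(np.asarray(observed_r, dtype=float), -clip, clip))
    mu0 = fisher_z(min(max(result.mean_bidim_r, -clip), clip))
    t, df, p, d_z = one_sample_t(z_obs, mu0)
    return {
        "t": t,
        "df": df,
        "p": p,
        "d_z": d_z,
        "observed_mean_r": float(np.tanh(z_obs.mean())),
        "simulated_mean_r": result.mean_bidim_r,
        "n_observed": len(observed_r),
    }
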