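"""Simulation-based validation: planted-effect recovery and null calibration.

These routines close the loop on the synthetic generator: plant a known
condition effect, push the data through the scorer and the split-plot ANOVA,
and check that the effect size comes back unbiased and the F tests hold their
nominal size under the null.

The direction-error measure makes the planted effect analytically tractable:
a scored participant-session mean absolute direction error is the mean of six
iid absolute wrapped-normal draws, so the between-participant SD of the
across-session mean is sd(|wrapped noise|) / sqrt(6 * sessions), computable by
quadrature. A condition separation of d * that SD therefore plants a true
standardized mean difference of exactly d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .metrics import score_directions
from .stats import MixedAnova, SummaryStat, cohens_d_pooled
from .synth import (
    CohortSpec,
    ConditionParams,
    generate_responses,
    generate_route,
    wrapped_normal_mae,
    wrapped_normal_sd_for_mae,
)

__all__ = ["wrapped_normal_abs_sd", "planted_effect_recovery", "null_type_one_error",
           "analytic_two_sample_power"]


def wrapped_normal_abs_sd(sd: float) -> float:
    """SD of |wrapped N(0, sd)| (degrees), by quadrature."""
    if sd == 0:
        return 0.0
    half_width = max(6 * sd, 360.0)
    x = np.linspace(-half_width, half_width, 20001)
    wrapped = np.abs((x + 180.0) % 360.0 - 180.0)
    phi = np.exp(-0.5 * (x / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
    m1 = float(np.trapezoid(wrapped * phi, x))
    m2 = float(np.trapezoid(wrapped**2 * phi, x))
    return math.sqrt(max(m2 - m1**2, 0.0))


def analytic_two_sample_power(d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Power of the two-sided pooled t test for true standardized difference d."""
    df = 2 * n_per_group - 2
    ncp = d * math.sqrt(n_per_group / 2)
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


@dataclass
class RecoveryResult:
    d_true: float
    mean_d_hat: float
    bias: float
    power_empirical: float
    power_analytic: float
    n_replicates: int
    n_per_group: int


def planted_effect_recovery(n_replicates: int = 200, d_true: float = 0.8,
                            n_per_group: int = 20, n_sessions: int = 6,
                            base_mae: float = 52.32, seed: int = 0) -> RecoveryResult:
    """Generate -> score -> test, repeatedly, with a planted condition effect.

    Two conditions differ only in their direction-error level: the second
    condition's mean absolute error is lowered by ``d_true`` times the
    analytic between-participant SD of the across-session mean error. Each
    replicate regenerates all responses, scores the direction task, estimates
    Cohen's d from the participant means, and runs the split-plot ANOVA's
    condition test at alpha = .05. Route geometry is fixed across replicates;
    only the behavioural noise is redrawn.
    """
    import pandas as pd

    n_obs = 6 * n_sessions  # six direction estimates per session
    # analytic between-participant SD at the two noise levels (fixed point)
    delta = 0.0
    for _ in range(3):
        s_a = wrapped_normal_abs_sd(wrapped_normal_sd_for_mae(base_mae))
        s_b = wrapped_normal_abs_sd(wrapped_normal_sd_for_mae(base_mae - delta))
        s_between = math.sqrt((s_a**2 + s_b**2) / 2) / math.sqrt(n_obs)
        delta = d_true * s_between
    mae_b = base_mae - delta

    sessions = tuple(range(1, n_sessions + 1))
    routes = [generate_route(1000 + i) for i in range(n_sessions)]
    root = np.random.SeedSequence(seed)
    d_hats, detected = [], 0
    for rep_seq in root.spawn(n_replicates):
        rep_seed = int(rep_seq.generate_state(1)[0] % (2**31))
        spec = CohortSpec(seed=rep_seed, n_sessions=n_sessions, conditions={
            "feedback_only": ConditionParams(
                name="feedback_only", n_participants=n_per_group, sessions=sessions,
                direction_mae_first=base_mae, direction_mae_last=base_mae),
            "training": ConditionParams(
                name="training", n_participants=n_per_group, sessions=sessions,
                direction_mae_first=mae_b, direction_mae_last=mae_b),
        })
        responses = generate_responses(spec, routes, [])
        rows = [
            {"participant_id": rs.participant_id, "condition": rs.condition,
             "session": rs.session,
             "value": score_directions(routes[rs.session - 1], rs.directions)}
            for rs in responses
        ]
        df = pd.DataFrame(rows)
        per_part = df.groupby(["participant_id", "condition"], observed=True)["value"].mean()
        a = per_part.xs("feedback_only", level="condition")
        b = per_part.xs("training", level="condition")
        d_hats.append(cohens_d_pooled(SummaryStat.from_values(a.to_numpy()),
                                      SummaryStat.from_values(b.to_numpy())))
        res = MixedAnova.from_dataframe(df).fit()
        if res.effect("condition")["p"] < 0.05:
            detected += 1

    mean_d = float(np.mean(d_hats))
    return RecoveryResult(
        d_true=d_true, mean_d_hat=mean_d, bias=mean_d - d_true,
        power_empirical=detected / n_replicates,
        power_analytic=analytic_two_sample_power(d_true, n_per_group),
        n_replicates=n_replicates, n_per_group=n_per_group)


def null_type_one_error(n_datasets: int = 2000, n_per_group: int = 10,
                        n_sessions: int = 6, alpha: float = 0.05,
                        seed: int = 0) -> dict[str, float]:
    """Empirical rejection rate of each split-plot F test under the null.

    Datasets are pure noise (iid standard normal, no effects); rates should
    sit at the nominal alpha up to binomial error.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_total = 2 * n_per_group
    subj = [f"s{i}" for i in range(n_total)]
    cond = ["A"] * n_per_group + ["B"] * n_per_group
    base = pd.DataFrame({
        "participant_id": np.repeat(subj, n_sessions),
        "condition": np.repeat(cond, n_sessions),
        "session": np.tile(np.arange(1, n_sessions + 1), n_total),
    })
    rejections = {"condition": 0, "session": 0, "session:condition": 0}
    for _ in range(n_datasets):
        df = base.copy()
        df["value"] = rng.standard_normal(len(base))
        res = MixedAnova.from_dataframe(df).fit()
        for eff in rejections:
            if res.effect(eff)["p"] < alpha:
                rejections[eff] += 1
    return {eff: cnt / n_datasets for eff, cnt in rejections.items()}
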