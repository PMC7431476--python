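"""End-to-end pipeline: generate -> score -> analyze -> simulate -> report.

`run_full_analysis` reproduces the analysis workflow of the six-session
route-learning design: per-participant-session scores, a split-plot ANOVA with
polynomial session trends per measure (poor-sense-of-direction conditions),
condition-vs-average-group comparisons from summary statistics, and a
simulated-vs-observed sketch-map table built by running the Monte Carlo
drawing simulation with error parameters estimated from the scored data.
Correlation-valued measures are Fisher-z transformed before averaging or
testing. All outputs are tidy CSV plus one JSON report; a manifest records
config, seeds and package versions so a rerun is byte-identical.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .metrics import (
    ResponseSet,
    SessionScores,
    direction_errors,
    distance_ratio_pairs,
    score_response_set,
)
from .simulation import ErrorModel, compare_observed_vs_simulated, run_simulation
from .stats import (
    MixedAnova,
    SummaryStat,
    cohens_d_pooled,
    fisher_z,
    fisher_z_inverse,
    independent_t_from_summary,
)
from .synth import CohortSpec, SyntheticExperiment, generate_experiment

log = logging.getLogger("surveylearn")

__all__ = ["PipelineConfig", "score_experiment", "run_full_analysis"]

#: measures analysed in the mixed ANOVA, with whether they are correlations
MEASURES: dict[str, bool] = {
    "mean_abs_direction_error": False,
    "route_distance_correlation": True,
    "straight_distance_correlation": True,
    "mean_route_ratio": False,
    "mean_straight_ratio": False,
    "sketch_bidim_r": True,
}


@dataclass
class PipelineConfig:
    """Switches and seeds for one reproducible pipeline run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    simulation_iterations: int = 1000
    simulation_seed: int = 0
    sign_convention: Literal["symmetric", "positive"] = "symmetric"
    trend_error: Literal["contrast_specific", "pooled"] = "contrast_specific"
    outdir: Path | None = None

    def manifest(self) -> dict:
        return {
            "surveylearn_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "cohort_spec": self.cohort.to_dict(),
            "simulation_iterations": self.simulation_iterations,
            "simulation_seed": self.simulation_seed,
            "sign_convention": self.sign_convention,
            "trend_error": self.trend_error,
        }


def score_experiment(exp: SyntheticExperiment) -> pd.DataFrame:
    """Score every response bundle; one row per participant-session."""
    rows = []
    for rs in exp.responses:
        tp = (exp.training_paths_for_session(rs.session)
              if rs.pathway_outcomes else None)
        scores = score_response_set(exp.route_for_session(rs.session), rs, tp,
                                    standard_m=exp.spec.standard_m)
        rows.append(scores.to_dict())
    df = pd.DataFrame(rows)
    log.info("scored %d participant-sessions", len(df))
    return df


def _measure_values(scores: pd.DataFrame, measure: str, is_corr: bool) -> pd.DataFrame:
    """Long table for one measure, Fisher-z transformed if a correlation."""
    d = scores[["participant_id", "condition", "session", measure]].dropna().copy()
    d = d.rename(columns={measure: "value"})
    if is_corr:
        d["value"] = np.arctanh(np.clip(d["value"], -0.999999, 0.999999))
    return d


def _condition_summaries(scores: pd.DataFrame) -> pd.DataFrame:
    """Across-session participant means per condition and measure (r values on
    the Fisher-z scale for averaging, back-transformed means for display)."""
    rows = []
    for measure, is_corr in MEASURES.items():
        d = _measure_values(scores, measure, is_corr)
        per_part = d.groupby(["participant_id", "condition"], observed=True)["value"].mean()
        for cond, vals in per_part.groupby("condition", observed=True):
            mean = float(vals.mean())
            rows.append({
                "measure": measure, "condition": cond, "n": len(vals),
                "mean": fisher_z_inverse(mean) if is_corr else mean,
                "mean_z": mean if is_corr else np.nan,
                "sd": float(vals.std(ddof=1)),
            })
    return pd.DataFrame(rows)


def _anova_per_measure(scores: pd.DataFrame, trend_error: str) -> dict[str, pd.DataFrame]:
    """Mixed ANOVA (+ trends) per measure on the two experimental conditions."""
    out: dict[str, pd.DataFrame] = {}
    poor = scores[scores["condition"].isin(["feedback_only", "training"])]
    for measure, is_corr in MEASURES.items():
        d = _measure_values(poor, measure, is_corr)
        if d.empty or d["session"].nunique() < 2:
            continue
        res = MixedAnova.from_dataframe(d).fit(trends=True, trend_error=trend_error)
        tab = res.table.copy()
        tab["measure"] = measure
        trends = res.trends.copy()
        trends["effect"] = "session trend: " + trends.pop("order")
        trends["measure"] = measure
        out[measure] = pd.concat([tab, trends], ignore_index=True)
    return out


def _group_comparisons(scores: pd.DataFrame) -> pd.DataFrame:
    """Each experimental condition vs the average group, from summary stats.

    The average group only has the first session, so comparisons use
    session-level summaries: across-session means per participant for the
    experimental conditions against the average group's single session.
    """
    rows = []
    for measure, is_corr in MEASURES.items():
        d = _measure_values(scores, measure, is_corr)
        per_part = (d.groupby(["participant_id", "condition"], observed=True)["value"]
                    .mean().reset_index())
        avg = per_part.loc[per_part["condition"] == "average", "value"]
        if len(avg) < 2:
            continue
        b = SummaryStat.from_values(avg.to_numpy())
        for cond in ("feedback_only", "training"):
            vals = per_part.loc[per_part["condition"] == cond, "value"]
            if len(vals) < 2:
                continue
            a = SummaryStat.from_values(vals.to_numpy())
            t, df, p = independent_t_from_summary(a, b)
            rows.append({
                "measure": measure, "condition": cond, "t": t, "df": df, "p": p,
                "d": cohens_d_pooled(a, b),
                "condition_mean": fisher_z_inverse(a.mean) if is_corr else a.mean,
                "average_mean": fisher_z_inverse(b.mean) if is_corr else b.mean,
            })
    return pd.DataFrame(rows)


def estimate_error_model(exp: SyntheticExperiment, condition: str, session: int,
                         sign_convention: str = "symmetric") -> ErrorModel:
    """Error distributions for the drawing simulation, from raw responses.

    The simulation's inputs are the mean and SD of the *estimates themselves*:
    all absolute direction errors and all straight-line estimated/correct
    ratios produced by the cell's participants, pooled per estimate (not the
    narrower spread of participant session means).
    """
    route = exp.route_for_session(session)
    errs: list[float] = []
    ratios: list[float] = []
    for rs in exp.responses:
        if rs.condition != condition or rs.session != session:
            continue
        errs.extend(direction_errors(route, rs.directions))
        by_kind = distance_ratio_pairs(route, rs.distances, exp.spec.standard_m)
        if "straight_line" in by_kind:
            est_m, corr_m = by_kind["straight_line"]
            ratios.extend(np.asarray(est_m) / np.asarray(corr_m))
    if not errs or not ratios:
        raise ValueError(f"no responses for {condition!r} session {session}")
    return ErrorModel(
        ratio_mean=float(np.mean(ratios)), ratio_sd=float(np.std(ratios, ddof=1)),
        direrr_mean=float(np.mean(errs)), direrr_sd=float(np.std(errs, ddof=1)),
        sign_convention=sign_convention,  # type: ignore[arg-type]
    )


def _simulation_table(exp: SyntheticExperiment, scores: pd.DataFrame,
                      config: PipelineConfig) -> pd.DataFrame:
    """Simulated-vs-observed sketch accuracy, mirroring the first/last-session
    per-condition layout.

    For each condition and session of interest the straight-line ratio and
    direction-error distributions are estimated from the cell's raw estimates,
    the drawing simulation is run on that session's route, and the simulated
    mean r is tested against the participants' observed sketch r values.
    """
    cells = [("feedback_only", 1), ("training", 1),
             ("feedback_only", exp.spec.n_sessions), ("training", exp.spec.n_sessions),
             ("average", 1)]
    rows = []
    for idx, (cond, session) in enumerate(cells):
        cell = scores[(scores["condition"] == cond) & (scores["session"] == session)]
        if cell.empty:
            continue
        model = estimate_error_model(exp, cond, session, config.sign_convention)
        sim = run_simulation(exp.route_for_session(session), model,
                             iterations=config.simulation_iterations,
                             seed=config.simulation_seed + idx)
        observed = cell["sketch_bidim_r"].dropna().to_numpy()
        cmp = compare_observed_vs_simulated(observed, sim)
        rows.append({"condition": cond, "session": session,
                     "observed_mean_r": cmp["observed_mean_r"],
                     "simulated_mean_r": cmp["simulated_mean_r"],
                     "t": cmp["t"], "df": cmp["df"], "p": cmp["p"],
                     "n": cmp["n_observed"]})
    return pd.DataFrame(rows)


def run_full_analysis(config: PipelineConfig | None = None,
                      experiment: SyntheticExperiment | None = None) -> dict:
    """Run the whole pipeline; returns the report bundle as a dict of frames.

    If ``experiment`` is None one is generated from ``config.cohort``. When
    ``config.outdir`` is set, scores/ANOVA/comparison/simulation tables are
    written as CSV next to a JSON report and run manifest.
    """
    config = config or PipelineConfig()
    exp = experiment or generate_experiment(config.cohort)
    log.info("experiment: %d routes, %d training paths, %d response bundles",
             len(exp.routes), len(exp.training_paths), len(exp.responses))

    scores = score_experiment(exp)
    summaries = _condition_summaries(scores)
    anovas = _anova_per_measure(scores, config.trend_error)
    comparisons = _group_comparisons(scores)
    simulation = _simulation_table(exp, scores, config)

    bundle = {"scores": scores, "summaries": summaries, "anovas": anovas,
              "comparisons": comparisons, "simulation": simulation,
              "manifest": config.manifest()}

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        scores.to_csv(out / "session_scores.csv", index=False)
        summaries.to_csv(out / "condition_summaries.csv", index=False)
        for measure, tab in anovas.items():
            tab.to_csv(out / f"anova_{measure}.csv", index=False)
        comparisons.to_csv(out / "group_comparisons.csv", index=False)
        simulation.to_csv(out / "simulation_vs_observed.csv", index=False)
        report = {
            "manifest": bundle["manifest"],
            "summaries": summaries.to_dict(orient="records"),
            "comparisons": comparisons.to_dict(orient="records"),
            "simulation_vs_observed": simulation.to_dict(orient="records"),
            "anovas": {m: t.to_dict(orient="records") for m, t in anovas.items()},
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
        log.info("report written to %s", out)
    return bundle
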