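# surveylearn

Analysis machinery for **route-learning (cognitive mapping) experiments**: the
six-session paradigm in which participants walk an unfamiliar 450-m urban
route and their survey knowledge is probed with relative direction estimates,
route/straight-line distance estimates, sketch maps, and (for trained
participants) blindfolded pathway completion and north pointing.

It is written for researchers in spatial cognition who need to score these
tasks reproducibly, run the standard inferential battery, and stress-test the
whole pipeline on synthetic cohorts with known ground truth.

## What it computes

- **Task scoring** (`surveylearn.metrics`): mean absolute direction error over
  the six landmark pairs (estimates are recorded relative to the facing
  direction at the imagined landmark and converted to compass bearings);
  Pearson correlation and mean estimated/correct ratio for distances judged
  against a walked 32-m standard; stop-point and return-heading deviations and
  north-pointing error for pathway completion.
- **Bidimensional regression** (`surveylearn.bidimreg`): Tobler's Euclidean
  bidimensional regression between a drawn and a true anchor configuration.
  A similarity transform (scale, rotation, translation — no reflection) is
  fitted by closed-form complex least squares, and the correspondence is
  summarised by the bidimensional correlation
  `r = sqrt(1 − SSE/SST) ∈ [0, 1]`, the standard sketch-map accuracy score.
- **Monte Carlo sketch simulation** (`surveylearn.simulation`): how accurate
  would a map drawn purely from noisy inter-landmark distance/direction
  judgments look? Landmarks are chained from sampled distance ratios and
  perturbed bearings, each simulated map is scored by bidimensional
  regression, and the mean r over (by default) 1000 iterations is compared
  with observed sketch-map scores by a one-sample t test on Fisher-z values.
- **Inference** (`surveylearn.stats`): split-plot (mixed) ANOVA — condition
  between subjects, session within — with partial eta-squared, orthogonal
  polynomial session trends (for six sessions: linear −5,−3,−1,1,3,5;
  quadratic 5,−1,−4,−4,−1,5; cubic −5,7,4,−4,−7,5), Fisher r-to-z, pooled and
  paired effect sizes, and t tests that work from printed (M, SD, n) triples
  as well as raw data.
- **Synthetic experiments** (`surveylearn.synth`): seeded generation of
  routes (450 m, five turns, four landmarks), the 18 practice paths
  (triangles, quadrilaterals, crossing paths), and full cohorts — two
  poor-sense-of-direction conditions over six sessions plus a single-session
  average-sense-of-direction comparison group — with calibrated wrapped-normal
  direction noise, drifting distance-ratio means and sketch jitter.
- **Pipeline & CLI** (`surveylearn.pipeline`, `surveylearn` command):
  generate → score → analyze → simulate → report, emitting tidy CSVs, a JSON
  report and a manifest that makes reruns byte-identical.

## Worked example

```python
from surveylearn import (SummaryStat, cohens_d_pooled, independent_t_from_summary,
                         generate_route, ErrorModel, run_simulation)

# effect of training on direction errors, from condition-level summaries
feedback = SummaryStat(52.32, 17.66, 20)   # mean absolute error (deg), SD, n
training = SummaryStat(39.57, 12.70, 20)
print("d =", round(cohens_d_pooled(feedback, training), 2))

# poor- vs average-sense-of-direction comparison
t, df, p = independent_t_from_summary(feedback, SummaryStat(27.06, 17.89, 20))
print(f"t({df}) = {t:.2f}, p = {p:.3g}")

# sketch accuracy supported by distance/direction judgments alone
route = generate_route(seed=12)            # 450 m, 5 turns, 4 landmarks
model = ErrorModel(ratio_mean=0.90, ratio_sd=0.35, direrr_mean=52.3, direrr_sd=17.7)
res = run_simulation(route, model, iterations=1000, seed=0)
print(f"simulated mean bidimensional r = {res.mean_bidim_r:.3f} (SE {res.se_r:.3f})")
```

prints

```
d = 0.83
t(38) = 4.49, p = 6.36e-05
simulated mean bidimensional r = 0.820 (SE 0.005)
```

A `d` of 0.83 is a large training advantage in direction estimation; the
t test shows even trained participants remain well short of the average-SOD
group; and the simulated r of ~0.82 — well below typically observed sketch-map
scores of ~0.9 — shows that drawn maps encode more configural structure than
the explicit distance/direction judgments alone would support.

The same workflow from the shell:

```bash
surveylearn analyze --outdir out --seed 7 --iterations 1000
surveylearn report --outdir out
```

## Layout

| module | contents |
| --- | --- |
| `surveylearn.geometry` | points, bearings, routes, training paths, route/straight distances |
| `surveylearn.bidimreg` | `BidimensionalRegression(...).fit() -> SimilarityFit` |
| `surveylearn.metrics` | per-task scoring, `ResponseSet -> SessionScores` |
| `surveylearn.simulation` | `ErrorModel`, `run_simulation`, observed-vs-simulated test |
| `surveylearn.stats` | `MixedAnova.from_dataframe(...).fit()`, trends, effect sizes |
| `surveylearn.synth` | seeded routes, training paths, cohorts with ground truth |
| `surveylearn.validation` | planted-effect recovery, null-calibration checks |
| `surveylearn.pipeline` / `surveylearn.cli` | end-to-end runs and the CLI |

See `docs/methods.md` for the model, its assumptions and numerical choices.
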