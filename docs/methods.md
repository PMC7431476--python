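# Methods

This note documents the models and procedures implemented in `surveylearn`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generator does and does not emulate.

## The experimental design being modelled

The package targets a six-session route-learning design. Each session a
participant walks one unfamiliar urban route of 450 m with five turns, along
which four salient landmarks are pointed out, then (at the goal) estimates
relative directions between landmark pairs, estimates route and straight-line
distances as ratios to a 32-m standard walked at the start of the session, and
draws a sketch map of the route. Two conditions of poor-sense-of-direction
participants (n = 20 each) differ in whether they additionally practice
allocentric spatial updating on short blindfolded paths (pathway completion
plus north pointing, 3 paths × 2 trials per session); a third group with an
average sense of direction (n = 20) completes the first session only, as a
reference level.

## Coordinate and bearing conventions

Coordinates are metres in a local planar frame (x east, y north); with routes
under a kilometre, geodesy is ignored. Bearings are compass bearings — degrees
clockwise from north, normalised to [0, 360) — because the tasks are phrased
that way (point north, direction from A to B). All trigonometry converts
internally (`atan2(dx, dy)`).

Anchors (start, goal, four landmarks, five turns) must lie on the route
polyline within 0.5 m, a tolerance that accommodates hand-digitised fixtures.
The facing direction at a landmark — the reference for the response sheet's
"up" — defaults to the bearing of the polyline segment being walked at that
anchor, since walkers encounter landmarks mid-stride; it can be stored
explicitly when known.

## Task scoring

**Direction estimates.** The response sheet records an angle relative to the
facing direction at the imagined landmark. Scoring converts to an absolute
bearing (facing + relative angle) and takes the smallest angular difference to
the true bearing, in [0, 180]. A session score is the mean over the six
landmark pairs. The error is invariant to rotating both arguments, so the
score does not depend on the route's frame.

**Distance estimates.** Estimated metres are ratio-to-standard × 32 m. Two
summaries are kept per kind (route arc length vs straight line): the Pearson
correlation between estimated and correct distances — invariant to a
miscalibrated standard, it measures relative (ordinal-metric) knowledge — and
the mean estimated/correct ratio, which measures calibration and scales
linearly with the standard.

**Sketch maps.** Scored by bidimensional regression (below) against the true
configuration of all eleven anchors, equally weighted. Weighting landmarks
against turns differently would be defensible; equal weight is the simplest
rule and is stated here so it can be revisited.

**Pathway completion.** Distance deviation is the stop-point to true-start
distance in cm. The angular deviation compares the walked return heading
(end → stop point) with the correct return heading (end → start); an
alternative reading — the bearing of the estimated versus true start — is
selectable (`direction_reference="start_pointing"`), since published
descriptions admit either. North error is the absolute angular error of the
pointed north against the path frame's true north.

## Bidimensional regression

Given a reference configuration z and a drawn configuration w (complex
representation of planar points, matched by label), the Euclidean
(4-parameter) fit minimises ‖z − α − βw‖² over complex α, β. After centring,
β = Σ conj(w)z / Σ|w|²; |β| is scale, arg β rotation, α translation. Complex
multiplication cannot reflect, so the standard no-reflection constraint of
sketch-map scoring holds by construction; a reflection-allowed variant
(conjugate w, keep the better SSE) is available for diagnostics only.

The bidimensional correlation is r = √(1 − SSE/SST) with SST the dispersion
of the reference about its centroid, reported in [0, 1]. r = 1 iff the
drawing is an exact similarity copy of the truth; r is invariant to
translating, rotating or uniformly scaling either configuration and symmetric
under exchanging them. The closed form is the global optimum (the problem is
linear least squares after centring), which makes the statistic deterministic
and testable against a numerical optimizer.

Degenerate cases: a dispersion-free reference (all points coincident) has no
defined correlation and raises; anchors missing from a drawing are dropped
pairwise with a warning, and at least three common points are required.

## Monte Carlo sketch simulation

The simulation asks how much configural accuracy the explicit distance and
direction judgments alone could support. Starting from the first landmark
(pinned at truth), each next landmark is placed at
`sampled_ratio × true straight-line distance` from the previous one, along
the true inter-landmark bearing perturbed by a sampled direction error; only
consecutive-landmark steps are used. Ratios and error magnitudes are normal
with the mean/SD observed for (or assigned to) the cohort; each simulated
4-landmark map is scored by bidimensional regression against the true
landmark configuration, and the mean r over iterations (default 1000) is the
result.

Two numerical choices matter:

- **Sign of the direction error.** The input distribution describes
  *absolute* errors, which carry no sign. The default (`symmetric`) samples a
  non-negative magnitude from the stated normal truncated at zero and applies
  a random ± at each step. The alternative (`positive`) applies every error
  clockwise; it rotates the chain coherently, part of which the similarity
  fit absorbs, so it is kept only as a sensitivity variant.
- **Ratio floor.** Distance ratios are truncated at 0.01 to avoid degenerate
  zero-length placements.

When the pipeline drives the simulation from a cohort's own data, the error
model is estimated from the pooled per-estimate distributions — every
absolute direction error and every straight-line estimated/correct ratio
produced in that condition-session cell — because those are the
distributions the drawing procedure samples from; the spread of participant
session *means* is far narrower and would understate the noise.

Observed-vs-simulated comparisons use a one-sample t of the participants'
Fisher-z transformed sketch correlations against the z-transformed simulated
mean. Correlations of exactly 1 (possible in noise-free synthetic cohorts)
are clipped just inside ±1 before the transform.

Runs are bit-reproducible given a seed. If a route's landmarks are nearly
collinear the no-reflection fit becomes unstable and a warning is emitted;
the route generator screens such layouts out.

## Inference

**Split-plot ANOVA.** The classic univariate decomposition for one
between-subjects factor (condition, a levels) crossed with one
within-subjects factor (session, k levels), n subjects per condition:

    SS_total = SS_cond + SS_subj(cond) + SS_session + SS_session:cond + SS_resid

with condition tested against subjects-within-condition (df a−1, N−a) and the
within effects against the residual stratum (df k−1 or (a−1)(k−1), (N−a)(k−1)).
Effect size is partial eta-squared, SS_effect/(SS_effect + SS_error-for-it).
Sums of squares are computed from cell/marginal means directly, and
conservation (components summing to SS_total) is enforced by test. Sphericity
is assumed in the reported tests; the Greenhouse–Geisser epsilon (from the
pooled within-group covariance of the session columns) is computed and
attached for diagnostics but not applied, so degrees of freedom match the
uncorrected F(k−1, (N−a)(k−1)) convention of the literature this design comes
from. The implementation is validated against an independent package
(pingouin) and a hand-worked toy design in the test suite.

**Polynomial trends.** Session trends use single-df orthogonal polynomial
contrasts built by QR-orthogonalising the Vandermonde matrix of centred level
codes and rescaled to the familiar integer tables where those exist. Each
subject is reduced to a contrast score L = Σ c_s y_s; the trend F tests the
grand mean of L against zero. The default error term is contrast-specific —
the variance of L within groups, df N − a — the standard repeated-measures
practice; a pooled within-cell error variant is selectable because reports
rarely state which was used.

**Summary-statistic tests.** Cohen's d uses the (n−1)-weighted pooled SD;
two-sample t is the pooled-variance (not Welch) version, so df = n₁+n₂−2
matches printed dfs; one-sample t reports d_z = |m − μ₀|/sd alongside. These
operate on (M, SD, n) triples so published tables can be recomputed exactly;
recomputations can differ from printed values in the last digit because the
published inputs are themselves rounded. Correlations are Fisher-z
transformed before averaging or testing and back-transformed for display.
A zero-SD one-sample t with a nonzero effect returns an explicit infinite t
rather than raising, since the direction is well defined.

**Bonferroni.** Adjusted p = min(1, m·p), decided at α = .05.

## Synthetic-data generator

The generator produces the statistical shell the analysis assumes — not a
model of spatial learning. Per condition it takes target magnitudes that are
linearly interpolated across sessions:

| parameter | feedback-only | training | average (session 1) |
| --- | --- | --- | --- |
| direction MAE (deg) | 51.60 → 49.84 | 44.57 → 38.60 | 27.06 |
| route-distance ratio | 0.78 → 1.11 | same | 1.02 |
| straight-line ratio | 0.90 → 1.07 | same | 1.20 |
| sketch bidimensional r | 0.90 → 0.94 | 0.91 → 0.93 | 0.95 |
| per-pair ratio SD | 0.18 | 0.18 | 0.18 |

These defaults follow the published magnitudes for this paradigm;
session-level SDs are largely unpublished, so the interpolation is a labelled
synthetic choice, configurable per run.

Mechanics:

- **Direction noise** is wrapped-normal. Because targets are stated as mean
  absolute errors, a calibration utility inverts E|wrapped N(0, σ)| (computed
  by quadrature; ≈ σ√(2/π) for small σ, → 90° in the circular-uniform limit)
  to find σ for a target MAE. Scoring exactly inverts generation, so a scored
  error is |wrapped noise| and calibration is checkable analytically.
- **Distance estimates** are true distance × positive normal ratio (floored
  at 0.05) divided by the 32-m standard.
- **Sketch maps** are the true 11-anchor configuration plus isotropic jitter,
  then pushed through a random page transform (rotation, 0.02–0.05 page units
  per metre, offset) that the bidimensional fit must undo. The jitter SD for
  a target r uses E[SSE] ≈ 2(n−2)σ² under a similarity fit — approximate, so
  realised r runs slightly above the nominal target; monotonicity in the
  target is what the tests rely on.
- **Pathway outcomes** are bivariate-normal stop scatter around the true
  start (second trials get 0.75× the SD, emulating feedback within a session)
  and wrapped-normal pointing noise.
- **Routes** are self-avoiding polylines: segment lengths are Dirichlet
  shares of the total length, turn angles ±90° ± 10° jitter, resampled until
  no segments intersect. Landmarks are placed at quasi-even arc positions
  (jittered), the way study landmarks are pointed out spread along a walked
  route, and layouts whose landmark configuration is too elongated (smaller
  singular value below 0.3 of the larger) are rejected: five-turn routes curl
  into compact 2-D shapes, and an elongated landmark chain would let the
  four-point similarity fit absorb bearing errors that real layouts expose.
  Training paths are jittered, randomly
  oriented templates (triangle, quadrilateral, and a crossing shape whose
  return leg provably intersects an earlier segment), six of each.

Identical seeds give identical experiments; route geometry, path set and all
responses derive from one `SeedSequence`.

What the generator does **not** emulate: participant-level trait variance
(between-participant spread arises only from finite sampling of estimates),
learning dynamics within the noise model, correlated errors across tasks,
route-specific difficulty, and drop-out. Consequently, passing
parameter-recovery tests shows the pipeline is unbiased and calibrated under
its own assumptions — it does not validate those assumptions against human
data.

## Validation experiments

- **Planted-effect recovery.** Two conditions differ only in direction-error
  level; the separation is d × the analytic between-participant SD of the
  across-session mean error (sd(|wrapped noise|)/√36 for 6 pairs × 6
  sessions), so the true standardized difference is known exactly. 200
  replicates of generate → score → test give the mean recovered d̂ and the
  empirical power of the ANOVA condition test, compared with the analytic
  power of the equivalent two-sample t.
- **Null calibration.** 2000 pure-noise datasets; each F test's rejection
  rate at α = .05 must sit within the binomial 95% band around .05.
- Problem sizes used by the default runs: 1000 simulation iterations, 2000
  null datasets (n = 10/group, 6 sessions), 200 recovery replicates
  (n = 20/group). These match the sizes the design questions call for while
  keeping a full run in tens of seconds.

## Known limitations

- The ANOVA handles the balanced complete design only; missing cells raise
  rather than being imputed, by design.
- Greenhouse–Geisser correction is reported, not applied; strongly
  non-spherical data should be re-tested with the corrected df externally.
- The sketch-jitter calibration is first-order; targets below r ≈ 0.7 are
  increasingly approximate.
- Simulated sketch chains use consecutive landmarks only; a drawing strategy
  that triangulates against multiple anchors would need a different model.
- The average group is modelled with session 1 only, mirroring the design it
  emulates; comparisons against it are therefore cross-sectional.
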