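"""Inferential statistics for the session-by-session behavioural measures.

The workhorse is a split-plot (mixed) ANOVA: one between-subjects factor
(condition) crossed with one within-subjects factor (session), in the classic
univariate decomposition

    SS_total = SS_condition + SS_subjects(condition)
             + SS_session + SS_session:condition + SS_residual,

with the between effect tested against subjects-within-condition and the
within effects against the residual stratum. Effect size is partial
eta-squared, SS_effect / (SS_effect + SS_error-for-that-effect). Sphericity is
assumed for the reported tests (Greenhouse-Geisser epsilon is computed and
carried in the results for diagnostics, not applied by default).

Session trends are tested with single-df orthogonal polynomial contrasts
(linear, quadratic, cubic). By default each contrast is tested against its own
subject-level error (the variance of per-subject contrast scores within
groups, df = N - groups), the standard repeated-measures practice; a pooled
within-cell error variant is selectable.

Correlation-valued measures are Fisher r-to-z transformed before averaging or
testing and back-transformed for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryStat",
    "EffectSize",
    "MixedAnova",
    "MixedAnovaResults",
    "fisher_z",
    "fisher_z_inverse",
    "cohens_d_pooled",
    "cohens_d_z",
    "independent_t_from_summary",
    "one_sample_t",
    "paired_t",
    "trend_contrasts",
    "polynomial_contrasts",
    "bonferroni",
]


# --------------------------------------------------------------------------
# summary-statistic primitives
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStat:
    """A printed (mean, SD, n) triple — enough to recompute t and d."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "SummaryStat":
        arr = np.asarray(values, dtype=float)
        return cls(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size))


@dataclass(frozen=True)
class EffectSize:
    """A standardized mean difference: Cohen's d (pooled) or d_z (paired)."""

    kind: Literal["d_pooled", "d_z"]
    value: float


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher r-to-z: arctanh(r). Requires |r| < 1."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def fisher_z_inverse(z: float | np.ndarray) -> float | np.ndarray:
    """Inverse Fisher transform: tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) or out.ndim == 0 else out


def cohens_d_pooled(a: SummaryStat, b: SummaryStat) -> float:
    """Cohen's d for independent groups with (n-1)-weighted pooled SD."""
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    if pooled_var == 0:
        raise ZeroDivisionError("both groups have zero variance")
    return (a.mean - b.mean) / math.sqrt(pooled_var)


def cohens_d_z(diffs: Sequence[float] | None = None, *, mean_diff: float | None = None,
               sd_diff: float | None = None) -> float:
    """d_z for a paired contrast: |mean difference| / SD of differences."""
    if diffs is not None:
        arr = np.asarray(diffs, dtype=float)
        mean_diff, sd_diff = float(arr.mean()), float(arr.std(ddof=1))
    if mean_diff is None or sd_diff is None:
        raise ValueError("provide raw differences or (mean_diff, sd_diff)")
    if sd_diff == 0:
        raise ZeroDivisionError("zero SD of differences")
    return abs(mean_diff) / sd_diff


def independent_t_from_summary(a: SummaryStat, b: SummaryStat) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from summary statistics.

    Returns (t, df, two-tailed p) with df = n_a + n_b - 2.
    """
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if pooled_var == 0:
        raise ZeroDivisionError("zero pooled variance")
    se = math.sqrt(pooled_var * (1 / a.n + 1 / b.n))
    t = (a.mean - b.mean) / se
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, float(p)


def one_sample_t(
    data: Sequence[float] | SummaryStat, mu0: float = 0.0
) -> tuple[float, int, float, float]:
    """One-sample t test against mu0; returns (t, df, p, d_z).

    d_z is |mean - mu0| / sd. A zero SD with mean != mu0 yields an explicit
    infinite t (p = 0) rather than an exception, since the direction of the
    effect is still well defined.
    """
    stat = data if isinstance(data, SummaryStat) else SummaryStat.from_values(data)
    df = stat.n - 1
    if stat.sd == 0:
        if stat.mean == mu0:
            return 0.0, df, 1.0, 0.0
        return math.copysign(math.inf, stat.mean - mu0), df, 0.0, math.inf
    t = (stat.mean - mu0) / (stat.sd / math.sqrt(stat.n))
    p = 2 * sps.t.sf(abs(t), df)
    d_z = abs(stat.mean - mu0) / stat.sd
    return t, df, float(p), d_z


def paired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float, float]:
    """Paired t test via the one-sample t on differences; returns (t, df, p, d_z)."""
    diffs = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return one_sample_t(diffs, 0.0)


def bonferroni(pvals: Sequence[float], m: int | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni adjustment: p_adj = min(1, m * p), decision at alpha."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    if m < len(p):
        raise ValueError("m must be at least the number of tests")
    adj = np.minimum(1.0, m * p)
    return pd.DataFrame({"p": p, "p_adj": adj, "significant": adj < alpha})


# --------------------------------------------------------------------------
# orthogonal polynomial contrasts
# --------------------------------------------------------------------------

def polynomial_contrasts(k: int, orders: Sequence[int] = (1, 2, 3)) -> dict[int, np.ndarray]:
    """Orthogonal polynomial contrast coefficients for k equally spaced levels.

    Built by QR-orthogonalising the Vandermonde matrix of centred level codes
    (the construction behind R's ``contr.poly``), then rescaled so the entries
    are the familiar small integers where those exist (e.g. for k = 6 the
    linear contrast is (-5, -3, -1, 1, 3, 5)). Each contrast sums to zero and
    is orthogonal to the others; F ratios are invariant to the scaling.
    """
    if k < 2:
        raise ValueError("need at least 2 levels")
    x = np.arange(1, k + 1, dtype=float)
    X = np.vander(x - x.mean(), N=k, increasing=True)
    Q, _ = np.linalg.qr(X)
    out: dict[int, np.ndarray] = {}
    for order in orders:
        if order >= k:
            raise ValueError(f"order-{order} contrast needs at least {order + 1} levels")
        c = Q[:, order]
        c = c - c.mean()  # exact zero-sum against rounding
        # integer rescale when the pattern is rational (it is for small k)
        base = c / np.min(np.abs(c[np.abs(c) > 1e-12]))
        for mult in range(1, 33):
            scaled = base * mult
            if np.allclose(scaled, np.round(scaled), atol=1e-8):
                c = np.round(scaled)
                break
        if c[-1] < 0:  # sign convention: increasing at the top level
            c = -c
        out[order] = c
    return out


_ORDER_NAMES = {1: "linear", 2: "quadratic", 3: "cubic"}


# --------------------------------------------------------------------------
# split-plot mixed ANOVA
# --------------------------------------------------------------------------

class MixedAnovaResults:
    """Fitted split-plot ANOVA: the effects table plus optional trend rows.

    ``table`` has one row per effect with sums of squares, dfs, F, p and
    partial eta-squared; ``trends`` (after :meth:`MixedAnova.fit` with
    ``trends=True`` or a call to :func:`trend_contrasts`) holds the
    polynomial-contrast rows.
    """

    def __init__(self, model: "MixedAnova", table: pd.DataFrame,
                 gg_epsilon: float | None, trends: pd.DataFrame | None = None) -> None:
        self.model = model
        self.table = table
        self.gg_epsilon = gg_epsilon
        self.trends = trends

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]

    @property
    def ss_total(self) -> float:
        return float(self.table["ss"].sum())

    def summary(self) -> str:
        with pd.option_context("display.float_format", lambda v: f"{v:.4f}"):
            lines = [
                f"Split-plot ANOVA: {self.model.dv} ~ {self.model.between} x {self.model.within}",
                "=" * 72,
                self.table.to_string(index=False),
            ]
            if self.gg_epsilon is not None:
                lines.append(f"Greenhouse-Geisser epsilon = {self.gg_epsilon:.4f} (not applied)")
            if self.trends is not None:
                lines += ["", "Polynomial trends for " + self.model.within,
                          self.trends.to_string(index=False)]
        return "\n".join(lines)


class MixedAnova:
    """Split-plot ANOVA model for a long-format balanced table.

    Parameters
    ----------
    data
        Long table with one row per subject x within-level observation.
    dv, subject, between, within
        Column names for the response, subject id, between-subjects factor
        and within-subjects factor. Every subject must have exactly one
        observation at every within level (balanced, complete).
    """

    def __init__(self, data: pd.DataFrame, dv: str, subject: str,
                 between: str, within: str) -> None:
        self.data = data
        self.dv, self.subject, self.between, self.within = dv, subject, between, within
        self._validate()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, dv: str = "value",
                       subject: str = "participant_id", between: str = "condition",
                       within: str = "session") -> "MixedAnova":
        return cls(data, dv=dv, subject=subject, between=between, within=within)

    def _validate(self) -> None:
        d = self.data
        for col in (self.dv, self.subject, self.between, self.within):
            if col not in d.columns:
                raise KeyError(f"column {col!r} not in data")
        counts = d.groupby([self.subject, self.within], observed=True).size()
        if (counts != 1).any():
            raise ValueError("design must have exactly one observation per subject x level")
        per_subj = d.groupby(self.subject, observed=True)[self.within].nunique()
        k = d[self.within].nunique()
        if (per_subj != k).any():
            raise ValueError("missing cells: every subject needs all within levels")
        cond_per_subj = d.groupby(self.subject, observed=True)[self.between].nunique()
        if (cond_per_subj != 1).any():
            raise ValueError("a subject appears under more than one between level")
        n_per_cond = (
            d.drop_duplicates(self.subject).groupby(self.between, observed=True).size()
        )
        if (n_per_cond < 2).any():
            raise ValueError("need at least 2 subjects per between level")
        self.k_within = int(k)
        self.n_subjects = int(d[self.subject].nunique())
        self.n_between = int(d[self.between].nunique())

    # -- the decomposition --------------------------------------------------
    def _wide(self) -> tuple[np.ndarray, np.ndarray, list]:
        """Return (subjects x sessions matrix, group code per subject, level order)."""
        d = self.data
        levels = sorted(d[self.within].unique())
        wide = d.pivot_table(index=self.subject, columns=self.within, values=self.dv,
                             observed=True).loc[:, levels]
        groups = d.drop_duplicates(self.subject).set_index(self.subject)[self.between]
        groups = groups.loc[wide.index]
        return wide.to_numpy(dtype=float), groups.to_numpy(), levels

    def fit(self, *, trends: bool = False,
            trend_error: Literal["contrast_specific", "pooled"] = "contrast_specific",
            ) -> MixedAnovaResults:
        y, groups, levels = self._wide()
        n_total, k = y.shape
        uniq = np.unique(groups)
        a = len(uniq)
        if a < 2:
            raise ValueError("between factor needs >= 2 levels (use trend_contrasts "
                             "directly for a single-group repeated-measures trend)")
        grand = y.mean()

        subj_means = y.mean(axis=1)
        cond_means = {g: y[groups == g].mean() for g in uniq}
        n_per = {g: int((groups == g).sum()) for g in uniq}

        ss_between_subj = k * float(((subj_means - grand) ** 2).sum())
        ss_cond = k * sum(n_per[g] * (cond_means[g] - grand) ** 2 for g in uniq)
        ss_subj_within = ss_between_subj - ss_cond

        sess_means = y.mean(axis=0)
        ss_sess = n_total * float(((sess_means - grand) ** 2).sum())
        cell_means = np.vstack([y[groups == g].mean(axis=0) for g in uniq])
        ss_inter = 0.0
        for i, g in enumerate(uniq):
            ss_inter += n_per[g] * float(
                ((cell_means[i] - cond_means[g] - sess_means + grand) ** 2).sum()
            )
        ss_total = float(((y - grand) ** 2).sum())
        ss_resid = ss_total - ss_cond - ss_subj_within - ss_sess - ss_inter

        df_cond, df_subj = a - 1, n_total - a
        df_sess, df_inter = k - 1, (a - 1) * (k - 1)
        df_resid = (n_total - a) * (k - 1)

        def row(effect, ss, df1, ss_err, df2):
            ms, ms_err = ss / df1, ss_err / df2
            F = ms / ms_err if ms_err > 0 else 0.0
            p = float(sps.f.sf(F, df1, df2)) if ms_err > 0 else 1.0
            pes = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
            return {"effect": effect, "ss": ss, "df1": df1, "df2": df2,
                    "F": F, "p": p, "partial_eta_sq": pes}

        table = pd.DataFrame([
            row(self.between, ss_cond, df_cond, ss_subj_within, df_subj),
            {"effect": f"subjects({self.between})", "ss": ss_subj_within,
             "df1": df_subj, "df2": np.nan, "F": np.nan, "p": np.nan,
             "partial_eta_sq": np.nan},
            row(self.within, ss_sess, df_sess, ss_resid, df_resid),
            row(f"{self.within}:{self.between}", ss_inter, df_inter, ss_resid, df_resid),
            {"effect": "residual", "ss": ss_resid, "df1": df_resid, "df2": np.nan,
             "F": np.nan, "p": np.nan, "partial_eta_sq": np.nan},
        ])

        eps = self._gg_epsilon(y, groups, uniq) if k > 2 else None
        trends_df = None
        if trends:
            trends_df = trend_contrasts(self.data, dv=self.dv, subject=self.subject,
                                        within=self.within, between=self.between,
                                        error=trend_error)
        return MixedAnovaResults(self, table, eps, trends_df)

    @staticmethod
    def _gg_epsilon(y: np.ndarray, groups: np.ndarray, uniq: np.ndarray) -> float:
        """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
        k = y.shape[1]
        S = np.zeros((k, k))
        dof = 0
        for g in uniq:
            sub = y[groups == g]
            S += (sub - sub.mean(axis=0)).T @ (sub - sub.mean(axis=0))
            dof += sub.shape[0] - 1
        S /= dof
        mean_diag = np.trace(S) / k
        mean_all = S.mean()
        row_means = S.mean(axis=1)
        num = (k * (mean_diag - mean_all)) ** 2
        den = (k - 1) * (np.sum(S**2) - 2 * k * np.sum(row_means**2) + k**2 * mean_all**2)
        return float(num / den) if den > 0 else 1.0


def trend_contrasts(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "participant_id",
    within: str = "session",
    between: str | None = "condition",
    orders: Sequence[int] = (1, 2, 3),
    error: Literal["contrast_specific", "pooled"] = "contrast_specific",
) -> pd.DataFrame:
    """Single-df orthogonal polynomial trend tests for the within factor.

    Each subject is reduced to a contrast score L_i = sum_s c_s y_is. The
    trend F tests the grand mean of L against zero. With
    ``error="contrast_specific"`` (default) the error is the variance of L
    about its group means, df = N - (number of groups); ``error="pooled"``
    uses the omnibus within-cell residual instead. ``between=None`` treats the
    data as a single-group repeated-measures design.
    """
    levels = sorted(data[within].unique())
    k = len(levels)
    wide = data.pivot_table(index=subject, columns=within, values=dv,
                            observed=True).loc[:, levels]
    y = wide.to_numpy(dtype=float)
    n_total = y.shape[0]
    if between is not None:
        gser = data.drop_duplicates(subject).set_index(subject)[between]
        groups = gser.loc[wide.index].to_numpy()
        uniq = list(np.unique(groups))
    else:
        groups = np.zeros(n_total, dtype=int)
        uniq = [0]
    a = len(uniq)

    contrasts = polynomial_contrasts(k, [o for o in orders if o < k])

    pooled_ms = pooled_df = None
    if error == "pooled":
        # within-cell residual of the omnibus split-plot decomposition
        ss_resid = 0.0
        for g in uniq:
            sub = y[groups == g]
            cell = sub.mean(axis=0)
            resid = sub - sub.mean(axis=1, keepdims=True) - cell + sub.mean()
            ss_resid += float((resid**2).sum())
        pooled_df = (n_total - a) * (k - 1)
        pooled_ms = ss_resid / pooled_df

    rows = []
    for order, c in contrasts.items():
        csq = float((c**2).sum())
        L = y @ c
        Lbar = L.mean()
        ss_trend = n_total * Lbar**2 / csq
        if error == "contrast_specific":
            ss_err = sum(
                float(((L[groups == g] - L[groups == g].mean()) ** 2).sum())
                for g in uniq
            ) / csq
            df_err = n_total - a
            ms_err = ss_err / df_err
        else:
            ms_err, df_err = pooled_ms, pooled_df
            ss_err = ms_err * df_err
        F = ss_trend / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(F, 1, df_err)) if ms_err > 0 else 1.0
        pes = ss_trend / (ss_trend + ss_err) if (ss_trend + ss_err) > 0 else 0.0
        rows.append({"order": _ORDER_NAMES.get(order, f"order{order}"), "ss": ss_trend,
                     "df1": 1, "df2": df_err, "F": F, "p": p, "partial_eta_sq": pes})
    return pd.DataFrame(rows)
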