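"""Euclidean bidimensional regression (Tobler) between labelled 2-D point sets.

Bidimensional regression fits a planar similarity transform (uniform scale,
rotation, translation — no reflection by default) from a drawn configuration to
a reference configuration by least squares, and summarises the configural
correspondence with the bidimensional correlation

    r = sqrt(1 - SSE / SST),   r in [0, 1],

where SSE is the residual sum of squares of the transformed drawn points about
the reference points and SST the total sum of squares of the reference points
about their centroid. It is the standard score for sketch-map accuracy: r = 1
iff the drawn map is an exact similarity copy of the true layout.

The solution is closed-form. Writing each point as a complex number z = x + iy
and centring both configurations, the least-squares similarity is a single
complex coefficient

    beta = sum(conj(w_k) z_k) / sum(|w_k|^2)

(w drawn, z reference); |beta| is the scale and arg(beta) the rotation.
Complex multiplication cannot reflect, so the no-reflection constraint holds by
construction; the reflection-allowed diagnostic variant conjugates w first and
keeps whichever fit has smaller SSE.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import Point2D

__all__ = ["PointConfig", "SimilarityFit", "BidimensionalRegression", "fit_similarity", "bidim_r"]


class UndefinedCorrelationError(ValueError):
    """Reference configuration has no dispersion (SST = 0)."""


@dataclass
class PointConfig:
    """An ordered, labelled planar point configuration (e.g. map anchors)."""

    labels: list[str]
    points: list[Point2D]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.points):
            raise ValueError("labels and points differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.points], dtype=float)

    def as_complex(self) -> np.ndarray:
        a = self.as_array()
        return a[:, 0] + 1j * a[:, 1]

    @classmethod
    def from_array(cls, labels: Sequence[str], xy: np.ndarray) -> "PointConfig":
        return cls(list(labels), [Point2D(float(x), float(y)) for x, y in np.asarray(xy)])

    def subset(self, labels: Sequence[str]) -> "PointConfig":
        idx = {l: i for i, l in enumerate(self.labels)}
        return PointConfig(list(labels), [self.points[idx[l]] for l in labels])

    @classmethod
    def from_csv(cls, path) -> "PointConfig":
        import pandas as pd

        df = pd.read_csv(path)
        return cls.from_array(df["label"].astype(str).tolist(), df[["x", "y"]].to_numpy())

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"label": self.labels, "x": [p.x for p in self.points], "y": [p.y for p in self.points]}
        ).to_csv(path, index=False)


@dataclass
class SimilarityFit:
    """Results of a fitted bidimensional regression.

    Attributes
    ----------
    scale, rotation, translation
        Parameters of the similarity transform mapping drawn -> reference:
        ``ref_hat = scale * R(rotation) @ drawn + translation`` with rotation in
        degrees counter-clockwise in the x/y frame.
    r
        Bidimensional correlation, sqrt(1 - sse/sst), in [0, 1].
    sse, sst
        Residual and total sums of squares (about the reference centroid).
    """

    scale: float
    rotation: float
    translation: tuple[float, float]
    r: float
    sse: float
    sst: float
    n_points: int
    reflected: bool = False
    dropped_labels: list[str] = field(default_factory=list)

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Apply the fitted transform to an (n, 2) array of drawn points."""
        th = math.radians(self.rotation)
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        pts = np.asarray(points, dtype=float)
        if self.reflected:
            pts = pts * np.array([1.0, -1.0])
        return self.scale * pts @ R.T + np.asarray(self.translation)

    def summary(self) -> str:
        lines = [
            "Bidimensional regression (Euclidean)",
            "=" * 38,
            f"n points            {self.n_points:>10d}",
            f"bidimensional r     {self.r:>10.4f}",
            f"scale               {self.scale:>10.4f}",
            f"rotation (deg)      {self.rotation:>10.2f}",
            f"translation      ({self.translation[0]:.2f}, {self.translation[1]:.2f})",
            f"SSE                 {self.sse:>10.4f}",
            f"SST                 {self.sst:>10.4f}",
        ]
        if self.reflected:
            lines.append("note: reflection applied (diagnostic fit)")
        if self.dropped_labels:
            lines.append(f"dropped anchors: {', '.join(self.dropped_labels)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "r": self.r,
            "scale": self.scale,
            "rotation_deg": self.rotation,
            "translation": list(self.translation),
            "sse": self.sse,
            "sst": self.sst,
            "reflected": self.reflected,
            "dropped_labels": self.dropped_labels,
        }


class BidimensionalRegression:
    """Model object pairing a reference configuration with a drawn one.

    Parameters
    ----------
    reference
        True anchor configuration (ground truth).
    drawn
        Participant-drawn configuration in arbitrary page units/orientation.
        Labels present in the reference but missing from the drawing are
        dropped pairwise with a warning; >= 3 common labels are required.
    allow_reflection
        Fit the mirror-image transform too and keep the better one
        (diagnostic only; the reported statistic in sketch-map work is the
        no-reflection fit).
    """

    def __init__(
        self,
        reference: PointConfig,
        drawn: PointConfig,
        *,
        allow_reflection: bool = False,
    ) -> None:
        common = [l for l in reference.labels if l in set(drawn.labels)]
        dropped = [l for l in reference.labels if l not in set(drawn.labels)]
        if dropped:
            warnings.warn(
                f"dropping anchors missing from the drawn configuration: {dropped}",
                stacklevel=2,
            )
        if len(common) < 3:
            raise ValueError("need at least 3 common labelled points to fit")
        self.reference = reference.subset(common)
        self.drawn = drawn.subset(common)
        self.allow_reflection = allow_reflection
        self._dropped = dropped

    @staticmethod
    def _solve(z_ref: np.ndarray, w_drawn: np.ndarray) -> tuple[complex, complex, float]:
        """Least-squares beta and intercept for z ~ alpha + beta w; returns sse."""
        zc = z_ref - z_ref.mean()
        wc = w_drawn - w_drawn.mean()
        denom = float(np.sum(np.abs(wc) ** 2))
        if denom == 0.0:
            # all drawn points coincide: best fit collapses to the centroid
            beta = 0.0 + 0.0j
        else:
            beta = complex(np.sum(np.conj(wc) * zc) / denom)
        alpha = complex(z_ref.mean() - beta * w_drawn.mean())
        resid = z_ref - (alpha + beta * w_drawn)
        return beta, alpha, float(np.sum(np.abs(resid) ** 2))

    def fit(self) -> SimilarityFit:
        z = self.reference.as_complex()
        w = self.drawn.as_complex()
        sst = float(np.sum(np.abs(z - z.mean()) ** 2))
        if sst == 0.0:
            raise UndefinedCorrelationError(
                "reference points are coincident; correlation undefined"
            )

        beta, alpha, sse = self._solve(z, w)
        reflected = False
        if self.allow_reflection:
            beta_m, alpha_m, sse_m = self._solve(z, np.conj(w))
            if sse_m < sse:
                beta, alpha, sse, reflected = beta_m, alpha_m, sse_m, True

        # guard against tiny negative rounding in 1 - sse/sst
        r = math.sqrt(max(0.0, 1.0 - sse / sst))
        return SimilarityFit(
            scale=abs(beta),
            rotation=math.degrees(math.atan2(beta.imag, beta.real)),
            translation=(alpha.real, alpha.imag),
            r=min(1.0, r),
            sse=sse,
            sst=sst,
            n_points=len(z),
            reflected=reflected,
            dropped_labels=self._dropped,
        )


def fit_similarity(
    reference: PointConfig, drawn: PointConfig, *, allow_reflection: bool = False
) -> SimilarityFit:
    """Fit the similarity transform drawn -> reference; see
    :class:`BidimensionalRegression`."""
    return BidimensionalRegression(reference, drawn, allow_reflection=allow_reflection).fit()


def bidim_r(reference: PointConfig, drawn: PointConfig) -> float:
    """Bidimensional correlation between two labelled configurations."""
    return fit_similarity(reference, drawn).r
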