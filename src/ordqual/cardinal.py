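"""Cardinal quality scores in the statistical-preference framework.

Cardinal indicators (e.g. percentage attainment of clinical-achievement
points) enter the framework by rounding scores to a stated number of decimals
and treating the resulting support points as an ordered scale; the pairwise
difference can then be computed exactly like any ordinal indicator, to any
required accuracy.  For two groups of scores the pairwise difference also has
a closed form as a ratio of between-group Gini coefficients — the
Yitzhaki–Lerman variant (which registers overlap through mean ranks in the
pooled distribution) over the conventional Pyatt form (which sees only group
means) — signed so that the group with the higher mean is favoured.  The
rank-based Gini route is an independent verification of the profile-based
computation, and is pinned to it by test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .indices import pairwise_comparison
from .profiles import ProviderSet, QualityScale

__all__ = ["CardinalScores", "discretize", "pairwise_delta_gini"]


@dataclass
class CardinalScores:
    """Provider-level cardinal quality scores with registration weights.

    One row per observation; multiple rows per provider yield a genuine
    within-provider score distribution.  ``groups`` maps each row's provider
    to its group (default: every provider its own group).
    """

    provider_ids: Sequence[str]
    scores: np.ndarray
    weights: np.ndarray
    groups: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.provider_ids = [str(p) for p in self.provider_ids]
        self.scores = np.asarray(self.scores, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.provider_ids)
        if self.scores.shape != (n,) or self.weights.shape != (n,):
            raise ValidationError("provider_ids, scores and weights must be aligned")
        if not np.all(np.isfinite(self.scores)):
            bad = self.provider_ids[int(np.argmax(~np.isfinite(self.scores)))]
            raise ValidationError(f"non-finite score for provider {bad!r}")
        if np.any(self.weights < 0):
            raise ValidationError("negative weight")
        if self.groups is None:
            self.groups = list(self.provider_ids)
        else:
            self.groups = [str(g) for g in self.groups]
            by_provider = pd.Series(self.groups).groupby(pd.Series(self.provider_ids)).nunique()
            if (by_provider > 1).any():
                raise ValidationError(f"provider {by_provider.idxmax()!r} appears in more than one group")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, provider_col="provider_id", score_col="score",
                   weight_col="weight", group_col="group_id") -> "CardinalScores":
        groups = df[group_col] if group_col in df.columns else None
        return cls(df[provider_col].astype(str).tolist(), df[score_col].to_numpy(),
                   df[weight_col].to_numpy(), None if groups is None else groups.astype(str).tolist())


def _round_half_away(x: np.ndarray, decimals: int) -> np.ndarray:
    """Round half away from zero, the convention of published score tables."""
    f = 10.0 ** decimals
    return np.copysign(np.floor(np.abs(x) * f + 0.5), x) / f


def discretize(scores: CardinalScores, decimals: int) -> ProviderSet:
    """Turn cardinal scores into an ordinal provider set by rounding.

    The scale's levels are the distinct rounded values in ascending order.
    A provider with a single score gets a degenerate profile; with several
    weighted scores, its weighted distribution over the rounded values.
    """
    if decimals < 0:
        raise ValidationError("decimals must be >= 0")
    rounded = _round_half_away(scores.scores, decimals)
    levels = np.unique(rounded)
    if levels.size == 1:
        # all scores coincide: pad one zero-mass level so the ordered scale
        # stays valid; every index is then exactly zero
        levels = np.append(levels, levels[0] + 10.0 ** -decimals)
    scale = QualityScale("cardinal-discretized", tuple(levels.tolist()))
    level_of = {v: q for q, v in enumerate(levels.tolist())}

    order: dict[str, int] = {}
    for pid in scores.provider_ids:
        order.setdefault(pid, len(order))
    ids = list(order)
    mass = np.zeros((len(ids), scale.Q))
    weight = np.zeros(len(ids))
    groups = [None] * len(ids)
    for pid, val, w, g in zip(scores.provider_ids, rounded, scores.weights, scores.groups):
        i = order[pid]
        # within-provider mixing weight: the row weight (uniform if all zero)
        mass[i, level_of[float(val)]] += w if w > 0 else 1.0
        weight[i] += w
        groups[i] = g
    rowsum = mass.sum(axis=1)
    mass /= rowsum[:, None]
    if weight.sum() <= 0:
        weight = np.ones(len(ids))
    return ProviderSet(scale, ids, mass, weight, groups)


def _weighted_mean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x) / np.sum(w))


def _mid_cdf(points: np.ndarray, probs: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Mid-distribution function P(X < x) + 0.5 P(X = x) of a discrete law."""
    order = np.argsort(points)
    pts, pr = points[order], probs[order]
    cum = np.cumsum(pr)
    below = np.concatenate([[0.0], cum[:-1]])
    idx = np.searchsorted(pts, x)
    return below[idx] + 0.5 * pr[idx]


def pairwise_delta_gini(
    sample_a: tuple[np.ndarray, np.ndarray],
    sample_b: tuple[np.ndarray, np.ndarray],
) -> float:
    """Pairwise quality difference of two weighted score samples via Ginis.

    Computes Delta_ab = P(B > A) - P(B < A) as the ratio of the
    Yitzhaki–Lerman between-group Gini to the Pyatt between-group Gini of the
    pooled two-group distribution, signed so that the group with the higher
    mean is favoured.  Positive values mean ``sample_b`` has the better
    profile.  When the group means coincide the ratio is 0/0: identical
    pooled distributions return 0; otherwise the identity is inapplicable and
    a ``ValidationError`` is raised (use the discretized profile route).
    """
    xa, wa = (np.asarray(v, dtype=float) for v in sample_a)
    xb, wb = (np.asarray(v, dtype=float) for v in sample_b)
    for x, w, name in ((xa, wa, "a"), (xb, wb, "b")):
        if x.size == 0:
            raise ValidationError(f"sample_{name} is empty")
        if x.shape != w.shape:
            raise ValidationError(f"sample_{name}: scores and weights misaligned")
        if not np.all(np.isfinite(x)):
            raise ValidationError(f"sample_{name}: non-finite score")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValidationError(f"sample_{name}: invalid weights")

    tot_a, tot_b = wa.sum(), wb.sum()
    pi_a = tot_a / (tot_a + tot_b)
    pi_b = 1.0 - pi_a
    mu_a = _weighted_mean(xa, wa)
    mu_b = _weighted_mean(xb, wb)
    mu = pi_a * mu_a + pi_b * mu_b

    # pooled discrete law
    pooled = np.concatenate([xa, xb])
    pooled_w = np.concatenate([wa / tot_a * pi_a, wb / tot_b * pi_b])
    pts, inv = np.unique(pooled, return_inverse=True)
    probs = np.bincount(inv, weights=pooled_w, minlength=pts.size)

    if mu == 0:
        # Gini undefined at zero mean; shift (both Ginis shift-covariant in
        # the numerator, so the ratio is shift-invariant)
        shift = 1.0 - float(pooled.min())
        xa, xb, mu_a, mu_b, mu = xa + shift, xb + shift, mu_a + shift, mu_b + shift, mu + shift
        pts = pts + shift

    g_pyatt = pi_a * pi_b * abs(mu_b - mu_a) / mu
    if g_pyatt <= 1e-14:
        fa = _mid_cdf(pts, probs, _round_key(xa, pts))
        fb = _mid_cdf(pts, probs, _round_key(xb, pts))
        # equal means: return 0 only for genuinely identical pooled positions
        same = abs(_weighted_mean(fa, wa) - _weighted_mean(fb, wb)) <= 1e-12
        if same:
            return 0.0
        raise ValidationError(
            "group means coincide but distributions differ: the between-group "
            "Gini identity is undefined; compare discretized profiles instead"
        )
    # Yitzhaki–Lerman between-group Gini: 2 cov(group mean, pooled mid-rank)/mu
    f_all = _mid_cdf(pts, probs, pts)
    fbar = float(probs @ f_all)  # = 1/2 with the mid-rank convention
    fa_bar = _weighted_mean(_mid_cdf(pts, probs, _round_key(xa, pts)), wa)
    fb_bar = _weighted_mean(_mid_cdf(pts, probs, _round_key(xb, pts)), wb)
    cov = pi_a * mu_a * (fa_bar - fbar) + pi_b * mu_b * (fb_bar - fbar)
    g_yl = 2.0 * cov / mu
    return float(np.sign(mu_b - mu_a) * g_yl / g_pyatt)


def _round_key(x: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Map sample values onto the pooled support (exact by construction)."""
    idx = np.searchsorted(pts, x)
    idx = np.clip(idx, 0, pts.size - 1)
    return pts[idx]


def delta_from_samples(
    sample_a: tuple[np.ndarray, np.ndarray],
    sample_b: tuple[np.ndarray, np.ndarray],
) -> float:
    """Delta_ab by exact discretization of the two samples (default route)."""
    xa, wa = (np.asarray(v, dtype=float) for v in sample_a)
    xb, wb = (np.asarray(v, dtype=float) for v in sample_b)
    scores = CardinalScores(
        ["a"] * xa.size + ["b"] * xb.size,
        np.concatenate([xa, xb]),
        np.concatenate([wa, wb]),
    )
    pts = np.unique(scores.scores)
    scale = QualityScale("cardinal-discretized", tuple(pts.tolist()))
    level_of = {v: q for q, v in enumerate(pts.tolist())}
    mass = np.zeros((2, scale.Q))
    for i, (x, w) in enumerate(((xa, wa), (xb, wb))):
        for val, wt in zip(x, w):
            mass[i, level_of[float(val)]] += wt
    mass /= mass.sum(axis=1, keepdims=True)
    ps = ProviderSet(scale, ["a", "b"], mass, np.array([wa.sum(), wb.sum()]), ["a", "b"])
    return pairwise_comparison(ps.profile("a"), ps.profile("b")).delta
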