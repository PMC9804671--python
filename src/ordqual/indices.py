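"""Statistical-preference indices of provider quality and variation.

The building block is the pairwise quality difference

    Delta_kk' = P(Q_k' > Q_k) - P(Q_k > Q_k')

for independent random patients of two providers: the difference in chances
that the second provider's patient receives strictly better rather than
strictly worse care.  Unlike mean scores it is invariant to any monotone
relabelling of the ordinal categories, and unlike first-order stochastic
dominance it ranks every pair.  From it derive:

* the comparative quality index Delta_k, a provider's registration-weighted
  average pairwise difference against the whole population (weighted mean
  zero by construction);
* the lottery index L, the normalized patient-weighted mean absolute pairwise
  difference — 0 when all profiles are equivalent, 1 under complete
  separation of quality supports — computed within groups, between groups,
  or over all providers.

All computations use exact cumulative sums over the discrete profiles; no
sampling is involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateWeightsError, ScaleMismatchError, ValidationError
from .profiles import ProviderSet, QualityProfile, aggregate_to_groups

__all__ = [
    "PairwiseComparison",
    "ComparativeIndex",
    "LotteryResult",
    "pairwise_comparison",
    "comparative_indices",
    "lottery_index",
    "within_group_lottery",
    "between_group_lottery",
    "variance_decomposition",
    "rank_agreement",
]

#: internal consistency tolerance between the direct and shortcut forms
_IDENTITY_TOL = 1e-12


@dataclass(frozen=True)
class PairwiseComparison:
    """P(better), P(worse), P(tie) and the signed difference for one pair.

    ``p_better`` is the probability that the *second* provider's randomly
    drawn patient has strictly higher quality than the first's; ``delta`` is
    ``p_better - p_worse``, in [-1, 1].
    """

    p_better: float
    p_worse: float
    p_tie: float
    delta: float

    def __post_init__(self):
        total = self.p_better + self.p_worse + self.p_tie
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"comparison probabilities sum to {total!r}")


@dataclass(frozen=True)
class ComparativeIndex:
    """Comparative quality Delta_k of one provider against the population."""

    provider_id: str
    delta_k: float
    se: Optional[float] = None


@dataclass(frozen=True)
class LotteryResult:
    """Lottery index L = numerator / normalizer, with its two components.

    ``numerator`` is the patient-weighted mean absolute pairwise difference
    sum_k sum_k' p_k p_k' |Delta_kk'|; ``normalizer`` is 1 - sum_k p_k^2, the
    chance that two random patients come from different providers.
    """

    L: float
    numerator: float
    normalizer: float
    se: Optional[float] = None

    @property
    def choice_value(self) -> float:
        """Half of L: the mean gain in winning chances from choosing the
        better provider of a random pair rather than being assigned."""
        return self.L / 2.0


def _win_tie_matrices(mass: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Return (W, T): W[i, j] = P(Q_i > Q_j), T[i, j] = P(Q_i = Q_j)."""
    F = np.cumsum(mass, axis=1)
    F_prev = np.hstack([np.zeros((mass.shape[0], 1)), F[:, :-1]])
    W = mass @ F_prev.T
    T = mass @ mass.T
    return W, T


def _delta_matrix(mass: np.ndarray) -> np.ndarray:
    """Antisymmetric matrix D[k, k'] = Delta_kk' = P(Q_k' > Q_k) - P(Q_k > Q_k')."""
    W, T = _win_tie_matrices(mass)
    # shortcut form: Delta_kk' = 1 - 2*(P(Q_k > Q_k') + 0.5*P(Q_k = Q_k'))
    D = 1.0 - 2.0 * (W + 0.5 * T)
    np.fill_diagonal(D, 0.0)
    direct = W.T - W
    if np.max(np.abs(D - direct)) > 1e-9:  # pragma: no cover - internal identity
        raise AssertionError("cumulative-sum shortcut disagrees with direct form")
    return direct  # exact antisymmetry


def _check_common_scale(a: QualityProfile, b: QualityProfile) -> None:
    if a.Q != b.Q:
        raise ScaleMismatchError(f"profiles have {a.Q} and {b.Q} categories")
    if a.scale is not None and b.scale is not None and a.scale != b.scale:
        raise ScaleMismatchError(f"profiles on different scales: {a.scale.levels} vs {b.scale.levels}")


def pairwise_comparison(a: QualityProfile, b: QualityProfile) -> PairwiseComparison:
    """Compare two providers' quality profiles by statistical preference.

    Returns the probabilities that an independent random patient of ``b``
    draws strictly better, strictly worse, or equal quality than one of
    ``a``, and the signed difference ``delta = p_better - p_worse``.  A
    positive delta means ``b`` offers the better profile.
    """
    _check_common_scale(a, b)
    mass = np.vstack([a.mass, b.mass])
    W, T = _win_tie_matrices(mass)
    p_better = float(W[1, 0])  # P(Q_b > Q_a)
    p_worse = float(W[0, 1])
    p_tie = float(T[0, 1])
    delta = 1.0 - 2.0 * (p_worse + 0.5 * p_tie)  # shortcut identity
    if abs(delta - (p_better - p_worse)) > _IDENTITY_TOL:  # pragma: no cover
        raise AssertionError("shortcut identity violated")
    return PairwiseComparison(p_better, p_worse, p_tie, p_better - p_worse)


def comparative_indices(ps: ProviderSet) -> list[ComparativeIndex]:
    """Comparative quality index Delta_k for every provider.

    Delta_k = sum_k' p_k' [P(Q_k > Q_k') - P(Q_k' > Q_k)]: the difference in
    chances that provider k's random patient fares better rather than worse
    than a random patient drawn from the whole population.  Registration-
    weighted mean zero by construction; each |Delta_k| <= 1 - p_k.
    """
    if ps.K < 2:
        raise ValidationError("comparative indices need at least two providers")
    D = _delta_matrix(ps.mass)  # D[k, k'] = Delta_kk'
    # Delta_k = sum_k' p_k' * Delta_k'k = - sum_k' p_k' * D[k, k']
    delta_k = -D @ ps.weights
    mean = float(ps.weights @ delta_k)
    if abs(mean) > 1e-10:  # pragma: no cover - algebraic identity
        raise AssertionError(f"weighted mean of Delta_k is {mean}")
    return [ComparativeIndex(pid, float(d)) for pid, d in zip(ps.ids, delta_k)]


def lottery_index(ps: ProviderSet) -> LotteryResult:
    """Lottery index of variation in quality across the providers of ``ps``.

    L = sum_kk' p_k p_k' |Delta_kk'| / (1 - sum_k p_k^2): the patient-weighted
    mean absolute difference in the chances that care is better rather than
    worse as a result of being registered with one provider rather than
    another.  Equivalently (choice-value form) |Delta_kk'| =
    2 max{P(k'>k), P(k>k')} - [P(k'>k) + P(k>k')]; the two forms are checked
    against each other internally.
    """
    if ps.K < 2:
        raise DegenerateWeightsError("lottery index needs at least two providers")
    p = ps.weights
    normalizer = 1.0 - float(p @ p)
    if normalizer <= 1e-12:
        raise DegenerateWeightsError("one provider holds all registrations; normalizer is zero")
    W, _ = _win_tie_matrices(ps.mass)
    D = _delta_matrix(ps.mass)
    absD = np.abs(D)
    choice_value_form = 2.0 * np.maximum(W, W.T) - (W + W.T)
    np.fill_diagonal(choice_value_form, 0.0)
    if np.max(np.abs(absD - choice_value_form)) > _IDENTITY_TOL:  # pragma: no cover
        raise AssertionError("choice-value identity violated")
    numerator = float(p @ absD @ p)
    return LotteryResult(numerator / normalizer, numerator, normalizer)


@dataclass(frozen=True)
class WithinGroupLottery:
    """Per-group lottery indices and their weighted average.

    ``per_group`` has one row per group (columns ``L``, ``numerator``,
    ``normalizer``, ``group_weight``, ``n_providers``); groups for which the
    index is undefined (singletons) carry NaN and are excluded from
    ``average``.
    """

    per_group: pd.DataFrame
    average: float
    average_weights: str = "registration"


def within_group_lottery(ps: ProviderSet, *, equal_group_weights: bool = False) -> WithinGroupLottery:
    """Lottery index within each group, plus the average across groups.

    Each group's index is computed on its members with weights renormalized
    within the group.  The cross-group average weights groups by their
    registration shares (or equally with ``equal_group_weights``).  Singleton
    groups have no within-group variation to measure: they are reported as
    missing and excluded from the average with a warning.
    """
    gids = ps.group_ids()
    gw = ps.group_weights()
    rows = []
    for g in gids:
        members = np.flatnonzero(ps.groups == g)
        row = {"group_id": g, "group_weight": float(gw[g]), "n_providers": int(members.size)}
        if members.size < 2:
            row.update(L=np.nan, numerator=np.nan, normalizer=np.nan)
        else:
            try:
                res = lottery_index(ps.subset(members))
                row.update(L=res.L, numerator=res.numerator, normalizer=res.normalizer)
            except DegenerateWeightsError:
                row.update(L=np.nan, numerator=np.nan, normalizer=np.nan)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("group_id")
    defined = table["L"].notna()
    if not defined.any():
        raise ValidationError("within-group lottery undefined for every group (all singletons)")
    if (~defined).any():
        warnings.warn(
            f"{int((~defined).sum())} group(s) with a single provider excluded from the "
            "within-group average",
            UserWarning,
            stacklevel=2,
        )
    if equal_group_weights:
        w = defined.astype(float)
    else:
        w = table["group_weight"].where(defined, 0.0)
    avg = float((table["L"].fillna(0.0) * w).sum() / w.sum())
    return WithinGroupLottery(table, avg, "equal" if equal_group_weights else "registration")


def between_group_lottery(ps: ProviderSet) -> LotteryResult:
    """Lottery index across group-level profiles (groups as providers)."""
    if len(ps.group_ids()) < 2:
        raise DegenerateWeightsError("between-group lottery needs at least two groups")
    return lottery_index(aggregate_to_groups(ps))


@dataclass(frozen=True)
class VarianceShares:
    """Within/between-group split of the variance of comparative quality."""

    within_share: float
    between_share: float
    total_variance: float
    defined: bool = True


def variance_decomposition(indices: Sequence[ComparativeIndex], ps: ProviderSet) -> VarianceShares:
    """Split the patient-weighted variance of Delta_k within/between groups.

    Shares sum to one.  When the total variance is zero both shares are
    undefined and returned as NaN with ``defined=False``.
    """
    by_id = {ix.provider_id: ix.delta_k for ix in indices}
    missing = [pid for pid in ps.ids if pid not in by_id]
    if missing:
        raise ValidationError(f"indices missing for providers {missing[:3]}...")
    d = np.array([by_id[pid] for pid in ps.ids])
    w = ps.weights
    mean = float(w @ d)
    total = float(w @ (d - mean) ** 2)
    if total <= 0:
        return VarianceShares(np.nan, np.nan, 0.0, defined=False)
    between = 0.0
    for g in ps.group_ids():
        members = np.flatnonzero(ps.groups == g)
        wg = w[members].sum()
        gm = float(w[members] @ d[members] / wg)
        between += wg * (gm - mean) ** 2
    between_share = between / total
    return VarianceShares(1.0 - between_share, between_share, total)


@dataclass(frozen=True)
class RankAgreement:
    """Kendall's tau-a with a normal-approximation confidence interval."""

    tau_a: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    level: float = 0.95


def rank_agreement(x: Sequence[float], y: Sequence[float], level: float = 0.95) -> RankAgreement:
    """Kendall's tau-a between two aligned rankings.

    tau_a = (concordant - discordant) / (n(n-1)/2), with tied pairs counted
    in the denominator but in neither tally, so tau_a reads directly as how
    much more likely the two measures are to agree than differ over which of
    a random pair ranks higher.  The confidence interval uses a leave-one-out
    jackknife standard error and normal quantiles.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"rankings must be equal-length vectors; got {x.shape} and {y.shape}")
    n = x.size
    if n < 2:
        raise ValidationError("rank agreement needs at least two items")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    s = sx * sy  # +1 concordant, -1 discordant, 0 tied
    n_pairs = n * (n - 1) / 2.0
    total = s.sum() / 2.0  # each unordered pair counted once
    tau = float(total / n_pairs)
    if n < 3:
        return RankAgreement(tau, np.nan, np.nan, np.nan, n, level)
    # leave-one-out: dropping i removes row/column i from the pair sums
    row = s.sum(axis=1)  # sum over ordered pairs involving i (twice each unordered)
    pairs_loo = (n - 1) * (n - 2) / 2.0
    tau_loo = (total - row) / pairs_loo
    se = float(np.sqrt((n - 1) / n * np.sum((tau_loo - tau_loo.mean()) ** 2)))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return RankAgreement(tau, se, tau - z * se, tau + z * se, n, level)
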