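"""Provider quality profiles: domain types, validation, I/O and aggregation.

A provider's *quality profile* is its discrete distribution of patients over
the ordered categories of a quality indicator (e.g. the five overall-experience
responses of a national GP patient survey).  A :class:`ProviderSet` collects
the profiles of all providers serving a population on a common
:class:`QualityScale`, together with registration weights and a mapping of
providers to higher-level groups (e.g. general practices to commissioning
areas).  All indices in :mod:`ordqual.indices` operate on these containers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: proportions whose sum deviates from 1 by more than this trigger a warning
#: when renormalized on read (published survey tables are rounded).
RENORM_WARN_TOL = 1e-6


@dataclass(frozen=True)
class QualityScale:
    """An ordered measurement scale with ``Q >= 2`` levels.

    Parameters
    ----------
    kind:
        ``"ordinal"`` for labelled categories or ``"cardinal-discretized"``
        for ascending numeric support points obtained by rounding scores.
    levels:
        Strictly ordered category labels (ordinal) or strictly increasing
        numeric support points (cardinal-discretized).
    """

    kind: str
    levels: tuple

    def __post_init__(self):
        if self.kind not in ("ordinal", "cardinal-discretized"):
            raise ValidationError(f"unknown scale kind {self.kind!r}")
        levels = tuple(self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 2:
            raise ValidationError("a quality scale needs at least two levels")
        if len(set(levels)) != len(levels):
            raise ValidationError("scale levels contain duplicates")
        if self.kind == "cardinal-discretized":
            vals = np.asarray(levels, dtype=float)
            if not np.all(np.diff(vals) > 0):
                raise ValidationError("numeric levels must be strictly increasing")

    @property
    def Q(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class QualityProfile:
    """One provider's distribution over the quality categories.

    ``mass[q]`` is the proportion of the provider's patients at level ``q``;
    ``weight`` is the provider's share of total registrations; ``n_responses``
    is the survey sample size behind the proportions, when known.
    """

    provider_id: str
    mass: np.ndarray
    weight: float
    n_responses: Optional[int] = None
    scale: Optional[QualityScale] = None

    def __post_init__(self):
        mass = np.asarray(self.mass, dtype=float)
        if mass.ndim != 1 or mass.size < 2:
            raise ValidationError(f"profile {self.provider_id}: mass must be a 1-d vector of length >= 2")
        if np.any(mass < 0) or np.any(mass > 1):
            bad = int(np.argmax((mass < 0) | (mass > 1)))
            raise ValidationError(
                f"profile {self.provider_id}: proportion {mass[bad]!r} at category index {bad} outside [0, 1]"
            )
        total = mass.sum()
        if total <= 0:
            raise ValidationError(f"profile {self.provider_id}: proportions sum to zero")
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"profile {self.provider_id}: proportions sum to {total!r}; renormalize before constructing"
            )
        object.__setattr__(self, "mass", mass / total)
        if self.weight < 0:
            raise ValidationError(f"profile {self.provider_id}: negative weight {self.weight!r}")
        if self.n_responses is not None and self.n_responses <= 0:
            raise ValidationError(f"profile {self.provider_id}: n_responses must be positive")
        if self.scale is not None and self.scale.Q != mass.size:
            raise ValidationError(f"profile {self.provider_id}: mass length {mass.size} != scale Q {self.scale.Q}")

    @property
    def Q(self) -> int:
        return self.mass.size

    def cumulative(self) -> np.ndarray:
        """Cumulative proportions F(q) = P(quality <= level q)."""
        return np.cumsum(self.mass)


class ProviderSet:
    """Profiles of ``K`` providers on one scale, with weights and groups.

    Internally array-backed: ``mass`` is the ``K x Q`` matrix of profiles,
    ``weights`` the registration shares (normalized to sum to one), ``groups``
    the provider -> group assignment.  Each provider belongs to exactly one
    group.
    """

    def __init__(
        self,
        scale: QualityScale,
        ids: Sequence[str],
        mass: np.ndarray,
        weights: np.ndarray,
        groups: Sequence[str],
        n_responses: Optional[Sequence] = None,
    ):
        self.scale = scale
        self.ids = list(map(str, ids))
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate provider ids")
        mass = np.asarray(mass, dtype=float)
        if mass.shape != (len(self.ids), scale.Q):
            raise ValidationError(f"mass matrix shape {mass.shape} != ({len(self.ids)}, {scale.Q})")
        if np.any(mass < -1e-12):
            raise ValidationError("negative proportions in mass matrix")
        rowsum = mass.sum(axis=1)
        if np.any(rowsum <= 0):
            raise ValidationError("provider with all-zero profile")
        if np.any(np.abs(rowsum - 1.0) > 1e-9):
            raise ValidationError("profiles must sum to 1; use read_provider_set for renormalization")
        self.mass = np.clip(mass, 0.0, None) / rowsum[:, None]
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(self.ids),):
            raise ValidationError("weights length mismatch")
        if np.any(weights < 0):
            raise ValidationError("negative registration weight")
        total = weights.sum()
        if total <= 0:
            raise ValidationError("all registration weights are zero")
        self.weights = weights / total
        self.groups = np.asarray(list(map(str, groups)))
        if self.groups.shape != (len(self.ids),):
            raise ValidationError("groups length mismatch")
        if n_responses is None:
            self.n_responses = None
        else:
            arr = np.asarray(n_responses, dtype=float)
            if arr.shape != (len(self.ids),):
                raise ValidationError("n_responses length mismatch")
            self.n_responses = arr

    # -- container protocol -------------------------------------------------

    @property
    def K(self) -> int:
        return len(self.ids)

    @property
    def Q(self) -> int:
        return self.scale.Q

    def __len__(self) -> int:
        return self.K

    def index_of(self, provider_id: str) -> int:
        try:
            return self.ids.index(str(provider_id))
        except ValueError:
            raise KeyError(provider_id) from None

    def profile(self, provider_id: str) -> QualityProfile:
        i = self.index_of(provider_id)
        n = None if self.n_responses is None or not np.isfinite(self.n_responses[i]) else int(self.n_responses[i])
        return QualityProfile(self.ids[i], self.mass[i].copy(), float(self.weights[i]), n, self.scale)

    @property
    def profiles(self) -> Mapping[str, QualityProfile]:
        return {pid: self.profile(pid) for pid in self.ids}

    def group_ids(self) -> list:
        """Distinct groups in order of first appearance."""
        seen: dict = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def group_weights(self) -> pd.Series:
        """Registration share of each group (sums to one)."""
        s = pd.Series(self.weights).groupby(pd.Series(self.groups)).sum()
        return s.reindex(self.group_ids())

    def subset(self, indices: Sequence[int], renormalize: bool = True) -> "ProviderSet":
        idx = np.asarray(indices, dtype=int)
        w = self.weights[idx]
        return ProviderSet(
            self.scale,
            [self.ids[i] for i in idx],
            self.mass[idx],
            w if renormalize else w,  # constructor always renormalizes
            self.groups[idx],
            None if self.n_responses is None else self.n_responses[idx],
        )

    def population_profile(self) -> np.ndarray:
        """Registration-weighted national profile."""
        return self.weights @ self.mass

    def cumulative(self) -> np.ndarray:
        """K x Q matrix of cumulative proportions."""
        return np.cumsum(self.mass, axis=1)

    def to_long(self) -> pd.DataFrame:
        """Canonical long-format table (one row per provider x category)."""
        rows = []
        for i, pid in enumerate(self.ids):
            for q, level in enumerate(self.scale.levels):
                rows.append(
                    {
                        "provider_id": pid,
                        "group_id": self.groups[i],
                        "category": level,
                        "proportion": self.mass[i, q],
                        "weight": self.weights[i],
                        "n_responses": (
                            self.n_responses[i] if self.n_responses is not None else np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows)


DEFAULT_SCHEMA = {
    "format": "long",
    "provider_id": "provider_id",
    "group_id": "group_id",
    "category": "category",
    "proportion": "proportion",
    "weight": "weight",
    "n_responses": "n_responses",
}


def read_provider_set(path, schema: Optional[dict] = None, *, scale: QualityScale) -> ProviderSet:
    """Read a delimited text table of provider profiles.

    ``schema`` maps logical names to column names; ``format`` is ``"long"``
    (one row per provider x category, the canonical interchange format) or
    ``"wide"`` (one row per provider with one column per category label).
    Category order comes from ``scale``, never from file order.  Weights are
    renormalized to sum to one; per-provider proportions are renormalized with
    a warning when the input sum deviates from 1 by more than ``1e-6``.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    fmt = schema.get("format", "long")
    id_col, grp_col, w_col = schema["provider_id"], schema["group_id"], schema["weight"]
    n_col = schema.get("n_responses")

    if fmt == "long":
        required = [id_col, grp_col, schema["category"], schema["proportion"], w_col]
    elif fmt == "wide":
        required = [id_col, grp_col, w_col] + [str(lv) for lv in scale.levels]
    else:
        raise SchemaError(f"unknown table format {fmt!r}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")

    if fmt == "wide":
        df = df.melt(
            id_vars=[c for c in [id_col, grp_col, w_col, n_col] if c and c in df.columns],
            value_vars=[str(lv) for lv in scale.levels],
            var_name=schema["category"],
            value_name=schema["proportion"],
        )

    cat_col, prop_col = schema["category"], schema["proportion"]
    df[id_col] = df[id_col].astype(str)
    known = {str(lv): q for q, lv in enumerate(scale.levels)}
    unknown = set(df[cat_col].astype(str)) - set(known)
    if unknown:
        raise SchemaError(f"categories {sorted(unknown)} not in scale levels {list(scale.levels)}")

    neg = df[df[prop_col] < 0]
    if len(neg):
        r = neg.iloc[0]
        raise ValidationError(
            f"negative proportion {r[prop_col]!r} for provider {r[id_col]!r}, category {r[cat_col]!r}"
        )
    if (df[w_col] < 0).any():
        bad = df.loc[df[w_col] < 0, id_col].iloc[0]
        raise ValidationError(f"negative weight for provider {bad!r}")

    multi = df.groupby(id_col)[grp_col].nunique()
    if (multi > 1).any():
        raise ValidationError(f"provider {multi.idxmax()!r} appears in more than one group")

    ids, mass_rows, weights, groups, n_resp = [], [], [], [], []
    have_n = bool(n_col) and n_col in df.columns
    for pid, sub in df.groupby(id_col, sort=False):
        vec = np.zeros(scale.Q)
        got = sub.groupby(sub[cat_col].astype(str))[prop_col].sum()
        for label, value in got.items():
            vec[known[label]] = value
        total = vec.sum()
        if total <= 0:
            raise ValidationError(f"provider {pid!r}: proportions sum to zero")
        if abs(total - 1.0) > RENORM_WARN_TOL:
            warnings.warn(
                f"provider {pid!r}: proportions sum to {total:.6g}; renormalizing",
                UserWarning,
                stacklevel=2,
            )
        ids.append(pid)
        mass_rows.append(vec / total)
        weights.append(sub[w_col].iloc[0])
        groups.append(sub[grp_col].iloc[0])
        if have_n:
            n_resp.append(sub[n_col].iloc[0])

    zero_w = [pid for pid, w in zip(ids, weights) if w == 0]
    if zero_w:
        logger.info("providers with zero registration weight retained: %s", zero_w)
    return ProviderSet(
        scale, ids, np.vstack(mass_rows), np.asarray(weights, dtype=float), groups,
        np.asarray(n_resp, dtype=float) if have_n else None,
    )


def write_provider_set(ps: ProviderSet, path) -> None:
    """Write a provider set as the canonical long CSV."""
    ps.to_long().to_csv(path, index=False)


def aggregate_to_groups(ps: ProviderSet) -> ProviderSet:
    """Aggregate provider profiles to their groups.

    Each group's profile is the registration-weighted average of its members'
    profiles with weights renormalized within the group (so missing members
    do not bias the group profile); the group weight is the sum of member
    weights.  The returned set has one 'provider' per group, each in its own
    singleton group, so all indices apply unchanged at group level.
    """
    gids = ps.group_ids()
    mass = np.empty((len(gids), ps.Q))
    gw = np.empty(len(gids))
    for j, g in enumerate(gids):
        members = np.flatnonzero(ps.groups == g)
        if members.size == 0:  # unreachable with array-backed groups
            raise ValidationError(f"group {g!r} is empty")
        w = ps.weights[members]
        total = w.sum()
        if total <= 0:
            raise ValidationError(f"group {g!r} has zero total registration weight")
        mass[j] = (w / total) @ ps.mass[members]
        gw[j] = total
    return ProviderSet(ps.scale, gids, mass, gw, gids)


def collapse_categories(ps: ProviderSet, blocks: Sequence[Sequence[int]]) -> ProviderSet:
    """Collapse adjacent categories into coarser ordered blocks.

    ``blocks`` partitions the category indices ``0..Q-1`` into at least two
    contiguous, ordered runs; e.g. ``[[0, 1, 2], [3, 4]]`` dichotomizes a
    five-category scale at the conventional good/not-good cut.  Block masses
    are the sums of their constituents' masses.
    """
    flat = [q for b in blocks for q in b]
    if len(blocks) < 2:
        raise ValidationError("collapsing to fewer than two categories is not allowed")
    if any(len(b) == 0 for b in blocks):
        raise ValidationError("empty block in category partition")
    if flat != list(range(ps.Q)):
        raise ValidationError(
            f"blocks {list(map(list, blocks))} are not a contiguous ordered partition of 0..{ps.Q - 1}"
        )
    new_levels = []
    for b in blocks:
        labels = [str(ps.scale.levels[q]) for q in b]
        new_levels.append(labels[0] if len(labels) == 1 else "+".join(labels))
    new_scale = QualityScale("ordinal", tuple(new_levels))
    new_mass = np.column_stack([ps.mass[:, list(b)].sum(axis=1) for b in blocks])
    return ProviderSet(new_scale, ps.ids, new_mass, ps.weights, ps.groups, ps.n_responses)
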