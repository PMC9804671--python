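"""Clustered bootstrap standard errors for all indices.

Uncertainty in the indices comes from treating the observed providers as a
sample; the resampling respects the organizational structure by drawing
providers with replacement *within their group*, keeping each group's
provider count fixed.  Registration weights and composition rows travel with
the resampled providers, weights are renormalized to sum to one, and the
full statistic — including any distribution-regression refit — is recomputed
on every replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from .errors import OrdqualError, ValidationError
from .indices import between_group_lottery, lottery_index, within_group_lottery
from .profiles import ProviderSet
from .standardization import CompositionMatrix

logger = logging.getLogger(__name__)

__all__ = ["BootstrapConfig", "BootstrapResult", "bootstrap_se", "resample_within_groups"]

Statistic = Callable[[ProviderSet, Optional[CompositionMatrix]], float]

#: named statistics accepted by :func:`bootstrap_se`
STATISTICS: dict[str, Statistic] = {
    "lottery": lambda ps, X: lottery_index(ps).L,
    "within_lottery": lambda ps, X: within_group_lottery(ps).average,
    "between_lottery": lambda ps, X: between_group_lottery(ps).L,
}


@dataclass(frozen=True)
class BootstrapConfig:
    """Replication count, seed, and the statistic to bootstrap.

    The default of 200 replications gives a reasonably stable standard
    error; 50 is a common published choice and remains available.
    """

    replications: int = 200
    seed: int = 0
    statistic: Union[str, Statistic] = "between_lottery"
    max_dropped_fraction: float = 0.2

    def __post_init__(self):
        if self.replications < 1:
            raise ValidationError("replications must be >= 1")


@dataclass(frozen=True)
class BootstrapResult:
    value: float  # statistic on the original sample
    se: float
    replicates: np.ndarray
    n_dropped: int


def resample_within_groups(
    ps: ProviderSet,
    rng: np.random.Generator,
    X: Optional[CompositionMatrix] = None,
) -> tuple[ProviderSet, Optional[CompositionMatrix]]:
    """One replicate: providers drawn with replacement within each group.

    Each group contributes exactly as many providers as it has.  Drawn
    providers keep their weight, profile, responses and composition row;
    duplicates get suffixed ids so the replicate is a valid provider set.
    Weights are renormalized by the set constructor.
    """
    take = []
    for g in ps.group_ids():
        members = np.flatnonzero(ps.groups == g)
        take.extend(rng.choice(members, size=members.size, replace=True))
    take = np.asarray(take)
    new_ids = [f"{ps.ids[i]}@{j}" for j, i in enumerate(take)]
    rs = ProviderSet(
        ps.scale,
        new_ids,
        ps.mass[take],
        ps.weights[take],
        ps.groups[take],
        None if ps.n_responses is None else ps.n_responses[take],
    )
    rX = None
    if X is not None:
        rX = X.reindex([ps.ids[i] for i in take], new_ids)
    return rs, rX


def bootstrap_se(
    ps: ProviderSet,
    X: Optional[CompositionMatrix],
    cfg: BootstrapConfig,
) -> BootstrapResult:
    """Clustered bootstrap standard error of an index.

    The statistic is a name from ``STATISTICS`` or any callable
    ``(ProviderSet, CompositionMatrix | None) -> float`` (which may refit a
    standardization model, making this a full-pipeline bootstrap).
    Replicates where the statistic is undefined are dropped with a logged
    count; more than ``max_dropped_fraction`` dropped is an error.
    """
    stat = STATISTICS[cfg.statistic] if isinstance(cfg.statistic, str) else cfg.statistic
    rng = np.random.default_rng(cfg.seed)
    point = float(stat(ps, X))
    draws = []
    dropped = 0
    for _ in range(cfg.replications):
        rs, rX = resample_within_groups(ps, rng, X)
        try:
            draws.append(float(stat(rs, rX)))
        except OrdqualError:
            dropped += 1
    if dropped:
        logger.info("dropped %d of %d bootstrap replicates", dropped, cfg.replications)
    if dropped > cfg.max_dropped_fraction * cfg.replications:
        raise ValidationError(
            f"{dropped}/{cfg.replications} bootstrap replicates undefined; "
            "the statistic is too unstable for this resampling design"
        )
    draws = np.asarray(draws)
    se = float(draws.std(ddof=1)) if draws.size > 1 else 0.0
    return BootstrapResult(point, se, draws, dropped)
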