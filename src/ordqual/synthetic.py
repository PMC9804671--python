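"""Ground-truth generator for multi-provider ordinal survey data.

Emulates the structure of a national GP patient survey: ``n_groups``
commissioning-area-like groups of general practices, each practice with a
registration weight, a socio-demographic composition (sex, age-band and
ethnicity shares, a long-term-condition share, a deprivation score) and an
ordered ``Q``-category quality profile.  True category probabilities come
from an ordered-threshold model on a standard-normal latent scale,

    P(category <= q) = Phi(tau_q - eta),    eta = beta'x + u_group + e_practice,

so the probit-link distribution regression is well specified and the linear
one is a working approximation.  Observed profiles add multinomial survey
noise of size ``n_responses`` (or are the exact probabilities when it is
None).  Every effect is recorded in a ground-truth object so recovery of
raw, standardized and residual indices can be tested against oracle values.

Default magnitudes are chosen to resemble published national survey
descriptives: ~35 practices per group, ~110 survey responses per practice,
five categories with national proportions near 2/4/11/38/45 percent, and
deprivation scores with mean around 22.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError
from .indices import between_group_lottery, within_group_lottery
from .profiles import ProviderSet, QualityScale
from .standardization import (
    GPPS_CONTINUOUS,
    GPPS_SHARE_BLOCKS,
    CompositionMatrix,
)

__all__ = ["SimulationConfig", "GroundTruth", "generate", "true_indices"]

#: thresholds placing a zero-effect practice at national-survey-like
#: cumulative proportions (2.1, 6.5, 17.1, 54.9 percent)
DEFAULT_THRESHOLDS = tuple(norm.ppf([0.021, 0.065, 0.171, 0.549]))

DEFAULT_LEVELS = ("very poor", "fairly poor", "neither", "fairly good", "very good")

#: block base shares on the national scale
_BASE_SHARES = {
    "sex": np.array([0.51, 0.49]),
    "age": np.array([0.13, 0.17, 0.16, 0.17, 0.15, 0.12, 0.07, 0.03]),
    "ethnicity": np.array([0.80, 0.095, 0.035, 0.02, 0.05]),
}

#: latent-scale main effects; keys are composition columns, unset columns are 0
DEFAULT_BETA = {
    "imd_score": -0.010,
    "eth_asian": -0.8,
    "ltc_share": -0.4,
    "age25_34": -0.4,
    "age35_44": -0.4,
    "age45_54": -0.3,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic survey population.

    ``group_concentration`` and ``provider_concentration`` are Dirichlet
    concentrations controlling how far group means stray from the national
    composition and providers from their group mean (lower = more
    segregation).  ``group_sd`` and ``practice_sd`` are the standard
    deviations of group and idiosyncratic practice effects on the latent
    scale; ``beta`` maps composition columns to latent-scale main effects.
    ``n_responses=None`` yields exact probability profiles (no survey noise).
    """

    n_groups: int = 10
    providers_per_group: int = 35
    registration_log_mean: float = np.log(7000.0)
    registration_log_sd: float = 0.5
    n_responses: Optional[int] = 110
    group_concentration: float = 300.0
    provider_concentration: float = 60.0
    ltc_base: float = 0.51
    imd_shape: float = 3.2
    imd_scale: float = 6.8
    imd_group_sd: float = 0.3  # sd of log group-level deprivation multiplier
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    group_sd: float = 0.08
    practice_sd: float = 0.25
    thresholds: tuple = DEFAULT_THRESHOLDS
    levels: tuple = DEFAULT_LEVELS
    seed: int = 0

    def __post_init__(self):
        taus = np.asarray(self.thresholds, dtype=float)
        if taus.ndim != 1 or taus.size < 1 or not np.all(np.diff(taus) > 0):
            raise ValidationError("thresholds must be a strictly increasing vector")
        if len(self.levels) != taus.size + 1:
            raise ValidationError(
                f"{len(self.levels)} category labels for {taus.size} thresholds; need Q = cutoffs + 1"
            )
        if self.group_sd < 0 or self.practice_sd < 0:
            raise ValidationError("effect standard deviations must be >= 0")
        if self.n_groups < 1 or self.providers_per_group < 1:
            raise ValidationError("need at least one group and one provider per group")

    @property
    def Q(self) -> int:
        return len(self.levels)


@dataclass
class GroundTruth:
    """Everything the generator knew: for recovery tests only."""

    config: SimulationConfig
    ids: list
    groups: np.ndarray
    weights: np.ndarray
    composition: pd.DataFrame
    eta_composition: np.ndarray
    eta_group: np.ndarray
    eta_noise: np.ndarray
    true_probs: np.ndarray
    scale: QualityScale

    @property
    def eta(self) -> np.ndarray:
        return self.eta_composition + self.eta_group + self.eta_noise


def _category_probs(eta: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Ordered-probit category probabilities for latent locations ``eta``."""
    F = norm.cdf(thresholds[None, :] - eta[:, None])
    full = np.hstack([np.zeros((eta.size, 1)), F, np.ones((eta.size, 1))])
    return np.diff(full, axis=1)


def _draw_composition(cfg: SimulationConfig, rng: np.random.Generator, groups: np.ndarray) -> pd.DataFrame:
    n = groups.size
    gids = list(dict.fromkeys(groups))
    cols = {}
    for block, base in _BASE_SHARES.items():
        names = GPPS_SHARE_BLOCKS[block]
        group_means = {g: rng.dirichlet(base * cfg.group_concentration) for g in gids}
        draws = np.vstack(
            [rng.dirichlet(np.maximum(group_means[g], 1e-6) * cfg.provider_concentration) for g in groups]
        )
        for j, name in enumerate(names):
            cols[name] = draws[:, j]
    # long-term-condition share: beta around a group-level mean
    g_ltc = {
        g: rng.beta(cfg.ltc_base * cfg.group_concentration,
                    (1 - cfg.ltc_base) * cfg.group_concentration)
        for g in gids
    }
    cols["ltc_share"] = np.array(
        [rng.beta(g_ltc[g] * cfg.provider_concentration,
                  (1 - g_ltc[g]) * cfg.provider_concentration) for g in groups]
    )
    # deprivation: gamma with a group-level multiplier (areas differ systematically)
    g_imd = {g: np.exp(rng.normal(0.0, cfg.imd_group_sd)) for g in gids}
    cols["imd_score"] = np.array(
        [rng.gamma(cfg.imd_shape, cfg.imd_scale * g_imd[g]) for g in groups]
    )
    return pd.DataFrame(cols)


def generate(cfg: SimulationConfig) -> tuple[ProviderSet, CompositionMatrix, GroundTruth]:
    """Draw one synthetic population; fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    gids = [f"G{j + 1:03d}" for j in range(cfg.n_groups)]
    groups = np.repeat(gids, cfg.providers_per_group)
    n = groups.size
    ids = [f"P{i + 1:05d}" for i in range(n)]

    registrations = rng.lognormal(cfg.registration_log_mean, cfg.registration_log_sd, size=n)
    weights = registrations / registrations.sum()

    comp = _draw_composition(cfg, rng, groups)
    comp.index = pd.Index(ids)

    beta = pd.Series(0.0, index=comp.columns)
    unknown = set(cfg.beta) - set(comp.columns)
    if unknown:
        raise ValidationError(f"beta refers to unknown composition columns {sorted(unknown)}")
    for k, v in cfg.beta.items():
        beta[k] = v
    eta_comp = comp.to_numpy() @ beta.to_numpy()
    # centre the compositional effect so thresholds keep their national meaning
    eta_comp = eta_comp - float(weights @ eta_comp)

    u = rng.normal(0.0, cfg.group_sd, size=cfg.n_groups)
    eta_group = np.repeat(u, cfg.providers_per_group)
    eta_noise = rng.normal(0.0, cfg.practice_sd, size=n)

    taus = np.asarray(cfg.thresholds, dtype=float)
    true_probs = _category_probs(eta_comp + eta_group + eta_noise, taus)

    if cfg.n_responses is None:
        mass = true_probs
        n_resp = None
    else:
        counts = np.vstack([rng.multinomial(cfg.n_responses, p) for p in true_probs])
        mass = counts / cfg.n_responses
        n_resp = np.full(n, float(cfg.n_responses))

    scale = QualityScale("ordinal", cfg.levels)
    ps = ProviderSet(scale, ids, mass, weights, groups, n_resp)
    comp_table = comp.copy()
    comp_table["group_id"] = groups
    X = CompositionMatrix(comp_table, dict(GPPS_SHARE_BLOCKS), list(GPPS_CONTINUOUS))
    gt = GroundTruth(
        cfg, ids, groups, weights.copy(), comp, eta_comp, eta_group, eta_noise, true_probs, scale
    )
    return ps, X, gt


def _indices_from_probs(gt: GroundTruth, probs: np.ndarray) -> dict:
    ps = ProviderSet(gt.scale, gt.ids, probs, gt.weights, gt.groups)
    out = {"between": between_group_lottery(ps).L}
    if gt.config.providers_per_group >= 2:
        out["within_average"] = within_group_lottery(ps).average
    return out


def true_indices(gt: GroundTruth) -> dict:
    """Oracle raw/standardized/residual lottery indices on true probabilities.

    The standardized truth zeroes the group effects and idiosyncratic
    practice noise, leaving only the compositional part of the latent
    location — the counterfactual the indirect standardization is meant to
    recover.  Residual = raw - standardized, per index.
    """
    taus = np.asarray(gt.config.thresholds, dtype=float)
    raw = _indices_from_probs(gt, gt.true_probs)
    std_probs = _category_probs(gt.eta_composition, taus)
    std = _indices_from_probs(gt, std_probs)
    return {
        "raw": raw,
        "standardized": std,
        "residual": {k: raw[k] - std[k] for k in raw},
    }
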