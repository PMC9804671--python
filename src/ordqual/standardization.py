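"""Indirect standardization of quality profiles via distribution regression.

A distribution regression characterizes the full conditional distribution of
an ordered outcome by one binary-outcome regression per cumulative cutoff:
for cutoffs q = 1..Q-1 the dependent variable is the proportion of a
provider's patients reporting quality no better than q.  Covariates are the
socio-demographic composition of each provider's patient list (sex, age band,
ethnicity, long-term-condition and deprivation main effects) plus group
intercept dummies.  Counterfactual ("indirectly standardized") profiles are
the profiles expected if quality conditional on composition were the same
everywhere: predictions keep each provider's own composition but replace its
group effect by the population-share-weighted average of group effects.
Predicted cumulative proportions are censored to the unit interval, forced
monotone across cutoffs, and rescaled so their weighted mean matches the
sample mean.

Two model variants are supported: a linear probability distribution
regression model (LPDRM, weighted least squares with registration weights)
and a generalized linear one (GLDRM, probit link with binomial variance and
n equal to the number of survey responses).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError
from .indices import (
    between_group_lottery,
    lottery_index,
    within_group_lottery,
)
from .profiles import ProviderSet

logger = logging.getLogger(__name__)

__all__ = [
    "CompositionMatrix",
    "DistributionRegressionModel",
    "StandardizedProfiles",
    "fit_distribution_regression",
    "predict_standardized",
    "standardized_and_residual_indices",
    "GPPS_SHARE_BLOCKS",
]

#: share blocks of a GP-patient-survey style composition table
GPPS_SHARE_BLOCKS = {
    "sex": ["female", "male"],
    "age": ["age16_24", "age25_34", "age35_44", "age45_54",
            "age55_64", "age65_74", "age75_84", "age85plus"],
    "ethnicity": ["eth_white", "eth_asian", "eth_black", "eth_mixed", "eth_other"],
}

#: continuous / single-share covariates of the same table
GPPS_CONTINUOUS = ["ltc_share", "imd_score"]


@dataclass
class CompositionMatrix:
    """Per-provider socio-demographic composition used as regressors.

    ``data`` is indexed by provider id; ``share_blocks`` names the column
    groups that are compositional shares (each block sums to one per
    provider); ``continuous`` lists remaining covariates (a long-term
    condition share, a deprivation score).  ``group_col`` holds the group id.
    """

    data: pd.DataFrame
    share_blocks: dict = field(default_factory=lambda: dict(GPPS_SHARE_BLOCKS))
    continuous: list = field(default_factory=lambda: list(GPPS_CONTINUOUS))
    group_col: str = "group_id"

    def __post_init__(self):
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        needed = [c for cols in self.share_blocks.values() for c in cols]
        needed += self.continuous + [self.group_col]
        missing = [c for c in needed if c not in self.data.columns]
        if missing:
            raise ValidationError(f"composition table missing columns {missing}")
        for name, cols in self.share_blocks.items():
            block = self.data[cols].to_numpy(dtype=float)
            if np.any(block < -1e-9) or np.any(block > 1 + 1e-9):
                raise ValidationError(f"share block {name!r} has values outside [0, 1]")
            sums = block.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                bad = self.data.index[int(np.argmax(np.abs(sums - 1.0)))]
                raise ValidationError(f"share block {name!r} does not sum to 1 for provider {bad!r}")

    @property
    def covariate_columns(self) -> list:
        """Regressor columns after dropping one reference per share block."""
        cols = []
        for block_cols in self.share_blocks.values():
            cols.extend(block_cols[1:])  # first column of each block is the reference
        cols.extend(self.continuous)
        return cols

    def groups_for(self, ids: Sequence[str]) -> pd.Series:
        return self.data.loc[[str(i) for i in ids], self.group_col].astype(str)

    def reindex(self, old_ids: Sequence[str], new_ids: Sequence[str]) -> "CompositionMatrix":
        """Row-select (with repetition) and relabel: used by the bootstrap."""
        sub = self.data.loc[[str(i) for i in old_ids]].copy()
        sub.index = pd.Index([str(i) for i in new_ids])
        return CompositionMatrix(sub, self.share_blocks, self.continuous, self.group_col)


@dataclass
class DistributionRegressionModel:
    """Fitted per-cutoff coefficients of a distribution regression.

    ``coef`` has one column per cutoff q = 1..Q-1 and one row per design
    column (constant, covariates, non-reference group dummies).  The training
    sample's weights and mean cumulative proportions are retained for the
    rescaling step at prediction time.
    """

    link: str  # 'lpdrm' (identity) or 'gldrm' (probit-binomial)
    coef: pd.DataFrame
    covariates: list
    group_levels: list  # first entry is the absorbed reference group
    train_set: "ProviderSet"
    sample_cum_mean: np.ndarray  # weighted mean of F(q) over the sample
    sample_mass_mean: np.ndarray  # weighted mean category masses (for 'mass' rescale)

    @property
    def n_cutoffs(self) -> int:
        return self.coef.shape[1]


def _design(X: CompositionMatrix, ids: Sequence[str], group_levels: list) -> pd.DataFrame:
    ids = [str(i) for i in ids]
    missing = [i for i in ids if i not in X.data.index]
    if missing:
        raise ValidationError(f"composition rows missing for providers {missing[:5]}")
    D = X.data.loc[ids, X.covariate_columns].astype(float).copy()
    g = X.groups_for(ids)
    for lvl in group_levels[1:]:
        D[f"group[{lvl}]"] = (g == lvl).astype(float).to_numpy()
    D.insert(0, "const", 1.0)
    return D


def _check_collinear(D: pd.DataFrame) -> None:
    M = D.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # identify offending columns by incremental rank
        offenders, kept = [], []
        for j, name in enumerate(D.columns):
            trial = M[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                offenders.append(name)
        raise ValidationError(f"collinear design columns: {offenders}")


def fit_distribution_regression(
    ps: ProviderSet,
    X: CompositionMatrix,
    link: str = "lpdrm",
) -> DistributionRegressionModel:
    """Fit one cumulative-proportion regression per cutoff q = 1..Q-1.

    LPDRM: weighted least squares with registration weights.  GLDRM: probit
    link, binomial variance with n equal to each provider's number of survey
    responses (n = 1 with a warning where absent, as for indicators that are
    a single rating or score per provider).
    """
    if link not in ("lpdrm", "gldrm"):
        raise ValidationError(f"unknown link {link!r}; expected 'lpdrm' or 'gldrm'")
    group_levels = ps.group_ids()
    D = _design(X, ps.ids, group_levels)
    # covariates with no variation are absorbed by the intercept, not errors
    constant = [
        c for c in D.columns
        if c != "const" and not c.startswith("group[") and D[c].nunique() == 1
    ]
    if constant:
        logger.info("dropping constant covariate column(s) %s", constant)
        D = D.drop(columns=constant)
    _check_collinear(D)
    F = ps.cumulative()[:, :-1]  # K x (Q-1); F(Q) = 1 always

    if link == "gldrm":
        if ps.n_responses is None or np.any(~np.isfinite(ps.n_responses)):
            warnings.warn(
                "n_responses absent for some providers; using binomial n = 1",
                UserWarning,
                stacklevel=2,
            )
            n = np.ones(ps.K) if ps.n_responses is None else np.where(
                np.isfinite(ps.n_responses), ps.n_responses, 1.0
            )
        else:
            n = ps.n_responses.astype(float)

    coefs = {}
    for q in range(F.shape[1]):
        y = F[:, q]
        if link == "lpdrm":
            res = sm.WLS(y, D, weights=ps.weights).fit()
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # perfect 0/1 proportions are legitimate here
                res = sm.GLM(
                    y, D, family=sm.families.Binomial(link=sm.families.links.Probit()),
                    var_weights=n,
                ).fit()
        coefs[q + 1] = res.params
    coef = pd.DataFrame(coefs)
    coef.index = D.columns
    w = ps.weights
    return DistributionRegressionModel(
        link=link,
        coef=coef,
        covariates=list(X.covariate_columns),
        group_levels=group_levels,
        train_set=ps,
        sample_cum_mean=w @ F,
        sample_mass_mean=w @ ps.mass,
    )


@dataclass
class StandardizedProfiles:
    """Counterfactual profiles plus the adjustments applied to get them.

    ``provider_set`` carries the standardized profiles on the original scale
    with the original weights and groups; ``scaling_factors`` are the
    per-cutoff multiplicative rescales; ``n_censored`` counts predictions
    clamped to [0, 1]; ``n_monotone_fixed`` counts second-pass monotonicity
    repairs after rescaling.
    """

    provider_set: ProviderSet
    scaling_factors: np.ndarray
    n_censored: int
    n_monotone_fixed: int
    rescale: str = "cumulative"


def predict_standardized(
    model: DistributionRegressionModel,
    X: CompositionMatrix,
    population_group_shares: Optional[pd.Series] = None,
    rescale: str = "cumulative",
) -> StandardizedProfiles:
    """Counterfactual profiles at neutralized group effects.

    Each provider keeps its own composition; its group dummies are replaced
    by the population group shares, i.e. the group effect becomes the
    population-share-weighted average of the estimated group effects.
    Predicted cumulative proportions are censored to [0, 1], made monotone by
    a cumulative maximum across cutoffs, and rescaled per cutoff so that the
    weighted mean prediction matches the weighted sample mean (``rescale=
    'cumulative'`` matches mean cumulative proportions, the default;
    ``'mass'`` matches mean category masses instead).
    """
    if rescale not in ("cumulative", "mass"):
        raise ValidationError(f"unknown rescale mode {rescale!r}")
    ps = model.train_set
    if population_group_shares is None:
        shares = ps.group_weights()
    else:
        shares = pd.Series(population_group_shares, dtype=float)
    shares = shares.reindex(model.group_levels)
    if shares.isna().any():
        raise ValidationError("population_group_shares must cover every training group")
    if abs(shares.sum() - 1.0) > 1e-8:
        raise ValidationError("population group shares must sum to 1")

    D = _design(X, ps.ids, model.group_levels)
    for lvl in model.group_levels[1:]:
        D[f"group[{lvl}]"] = float(shares[lvl])
    D = D[list(model.coef.index)]  # columns the fit actually kept
    eta = D.to_numpy(dtype=float) @ model.coef.to_numpy(dtype=float)  # K x (Q-1)

    if model.link == "lpdrm":
        F_hat = eta
    else:
        from scipy.stats import norm

        F_hat = norm.cdf(eta)

    n_censored = int(np.sum((F_hat < 0) | (F_hat > 1)))
    if n_censored:
        logger.info("censored %d counterfactual cumulative proportions to [0, 1]", n_censored)
    F_hat = np.clip(F_hat, 0.0, 1.0)
    F_hat = np.maximum.accumulate(F_hat, axis=1)

    w = ps.weights
    n_monotone_fixed = 0
    if rescale == "cumulative":
        pred_mean = w @ F_hat
        with np.errstate(divide="ignore", invalid="ignore"):
            factors = np.where(pred_mean > 0, model.sample_cum_mean / pred_mean, 1.0)
        F_hat = np.clip(F_hat * factors, 0.0, 1.0)
        fixed = np.maximum.accumulate(F_hat, axis=1)
        n_monotone_fixed = int(np.sum(fixed > F_hat + 1e-15))
        if n_monotone_fixed:
            logger.info("%d predictions adjusted in second monotonicity pass", n_monotone_fixed)
        F_hat = fixed
        mass = np.diff(np.hstack([np.zeros((len(w), 1)), F_hat, np.ones((len(w), 1))]), axis=1)
    else:
        mass = np.diff(np.hstack([np.zeros((len(w), 1)), F_hat, np.ones((len(w), 1))]), axis=1)
        pred_mean = w @ mass
        with np.errstate(divide="ignore", invalid="ignore"):
            factors = np.where(pred_mean > 0, model.sample_mass_mean / pred_mean, 1.0)
        mass = mass * factors
        mass /= mass.sum(axis=1, keepdims=True)

    mass = np.clip(mass, 0.0, None)
    mass /= mass.sum(axis=1, keepdims=True)
    out = ProviderSet(ps.scale, ps.ids, mass, ps.weights, ps.groups, ps.n_responses)
    return StandardizedProfiles(out, factors, n_censored, n_monotone_fixed, rescale)


def standardized_and_residual_indices(
    ps: ProviderSet,
    X: CompositionMatrix,
    link: str = "lpdrm",
    level: str = "both",
    rescale: str = "cumulative",
    population_group_shares: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Raw, indirectly standardized and residual lottery indices.

    Returns one row per reported index (the registration-weighted average of
    within-group indices and/or the between-group index) with columns
    ``raw``, ``standardized`` and ``residual = raw - standardized``; the
    residual is the part of the variation not explained by composition.
    """
    if level not in ("within", "between", "both"):
        raise ValidationError(f"unknown level {level!r}")
    model = fit_distribution_regression(ps, X, link)
    std = predict_standardized(model, X, population_group_shares, rescale)
    rows = {}
    if level in ("within", "both"):
        raw = within_group_lottery(ps).average
        stdv = within_group_lottery(std.provider_set).average
        rows["within_group_average"] = (raw, stdv)
    if level in ("between", "both"):
        raw = between_group_lottery(ps).L
        stdv = between_group_lottery(std.provider_set).L
        rows["between_group"] = (raw, stdv)
    table = pd.DataFrame(
        {
            "raw": {k: v[0] for k, v in rows.items()},
            "standardized": {k: v[1] for k, v in rows.items()},
        }
    )
    table["residual"] = table["raw"] - table["standardized"]
    table.insert(0, "link", link)
    return table
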