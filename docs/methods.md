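# Methods

## The statistical-preference framework

Each individual in a population is a patient of exactly one of K ≥ 2
providers; provider k holds registration share p_k and has a quality
profile a_k(q) over Q ordered categories. All measures derive from
independent random draws of one patient from each of two providers:

    Δ_kk′ = P(Q_k′ > Q_k) − P(Q_k > Q_k′)

is the pairwise quality difference. With cumulative proportions
F_k(q) = Σ_{r≤q} a_k(r) and F_k(0) = 0,

    P(Q_k > Q_k′) = Σ_q a_k(q) · F_k′(q−1),
    P(Q_k = Q_k′) = Σ_q a_k(q) · a_k′(q),

computed by exact cumulative sums (never sampling). Internally each Δ is
also evaluated through the equivalent form
Δ = 1 − 2[P(Q_k > Q_k′) + ½·P(Q_k = Q_k′)] and the two must agree to
1e−12; likewise |Δ| is cross-checked against the choice-value form
2·max{P(k′>k), P(k>k′)} − [P(k′>k) + P(k>k′)]. Assumptions: independent
patient lists, and profiles treated as the true category distributions of
each provider.

The comparative quality index Δ_k = Σ_k′ p_k′ [P(Q_k > Q_k′) − P(Q_k′ > Q_k)]
has registration-weighted mean zero and |Δ_k| ≤ 1 − p_k. The lottery index

    L = Σ_k Σ_k′ p_k p_k′ |Δ_kk′| / (1 − Σ_k p_k²)

lies in [0, 1]; the normalizer is the chance two random patients have
different providers, so L is a mean absolute difference over *distinct*
pairs. Within-group indices renormalize weights inside each group; the
cross-group average weights groups by registration share by default (the
patient-weighted convention used everywhere else; equal weighting is
available as an option). Singleton groups have no within-group variation
to measure and are excluded from the average with a warning. Between-group
indices apply L to group-aggregated profiles (weighted averages of member
profiles with weights renormalized within the group, so missing members do
not bias the aggregate).

The variance of provider-level Δ_k decomposes into between-group (variance
of patient-weighted group means) and within-group parts; shares are
reported relative to the patient-weighted total and flagged undefined when
the total variance is zero.

Rank agreement between two index vectors uses Kendall's τ_a,
(concordant − discordant)/(n(n−1)/2): tied pairs stay in the denominator,
so τ_a reads directly as how much more likely two measures are to agree
than disagree about a random pair. The confidence interval uses a
leave-one-out jackknife standard error with normal quantiles; no further
inference on τ_a is offered.

## Cardinal indicators

Cardinal scores are rounded half-away-from-zero at a stated number of
decimals (the convention of published score tables) and the distinct
rounded values become an ordered scale; Δ and L then follow as above, to
any required accuracy. If all scores round to a single value, one zero-mass
level is padded so the scale stays well-formed and every index is exactly
zero.

For two weighted samples the pairwise difference also satisfies a Gini
identity: Δ_ab = sign(μ_b − μ_a) · G_YL / G_P, where G_P = π_a π_b |μ_b − μ_a| / μ
is the conventional (Pyatt) between-group Gini built from group means, and
G_YL = 2 cov(μ_g, F̄)/μ is the Yitzhaki–Lerman variant built from mean
mid-ranks in the pooled distribution. The identity follows from
F̄_b − F̄_a = Δ_ab/2, which holds for any group shares π. The Gini route is
a verification oracle, not the default path: the test suite pins it to the
profile computation to 1e−9 on random weighted instances. When the two
group means coincide both Ginis vanish while Δ need not (e.g. {0,0,3} vs
{1,1,1}); the ratio is then genuinely undefined and the function raises
unless the pooled mean ranks also coincide (in which case Δ = 0 exactly
and 0 is returned).

## Indirect standardization

For cutoffs q = 1..Q−1 the dependent variable is the provider-level
cumulative proportion F_k(q); regressors are main effects of the patient
list's composition — sex, age-band and ethnicity shares (one reference
category per block absorbed), a long-term-condition share and a continuous
deprivation score — plus group intercept dummies (reference group
absorbed). No interaction terms: the data are provider-level shares, so
interactions are not identified. Two fitters:

- **LPDRM** (base case): weighted least squares per cutoff with
  registration weights. Registration weighting matches the framework's
  patient-weighting of every index.
- **GLDRM** (robustness): probit-link binomial quasi-likelihood with
  variance weight n = the provider's number of survey responses; n = 1
  with a warning where responses are unknown (a single rating or score per
  provider carries no binomial replication).

Covariate columns with no variation in the estimation sample are absorbed
into the intercept and dropped with a log message; remaining exact linear
dependence is an error naming the offending columns.

Counterfactual prediction keeps each provider's own composition and
replaces its group dummy values with the population group shares, i.e. the
group effect becomes the population-share-weighted average of estimated
group effects. Predicted cumulative proportions are then

1. censored to [0, 1] (count logged),
2. made monotone across cutoffs by cumulative maximum (censoring alone
   cannot guarantee non-negative category masses),
3. rescaled multiplicatively per cutoff so the registration-weighted mean
   prediction matches the weighted sample mean of F(q), with a second
   censor/monotone pass if rescaling disturbs either property (count
   logged).

Differencing adjacent cumulative values gives counterfactual masses, which
are valid distributions by construction. The rescale default matches means
of *cumulative proportions*; matching mean *category masses* (followed by
per-provider renormalization) is available as `rescale="mass"` — the two
coincide in the no-censoring limit and differ only through boundary
adjustments.

Reported tables contain raw, standardized and residual = raw − standardized
indices; the bookkeeping identity is exact by construction. Interpretation
note: the counterfactual profiles are noise-free regression predictions.
Where idiosyncratic provider noise is large it smooths raw *group-level*
aggregate profiles, so the standardized between-group index can slightly
exceed the raw one (a negative between-group residual) even when the model
explains all systematic variation; the within-group residual is the
component that captures idiosyncratic noise.

## Clustered bootstrap

Standard errors for any index resample providers with replacement within
their group, preserving each group's provider count, carrying weights,
response counts and composition rows, and renormalizing weights per
replicate. The statistic — including any distribution-regression refit —
is recomputed on every replicate (full-pipeline bootstrap); the SE is the
replicate standard deviation. Replicates where the statistic is undefined
(e.g. a resampled group degenerates) are dropped with a logged count; more
than 20% dropped aborts. Default 200 replications; 50 remains a common
published choice and is available. All draws come from a single
numpy Generator seeded explicitly.

## Synthetic-data generator

The generator emulates a national patient-survey structure: `n_groups`
commissioning-area-like groups × `providers_per_group` practices (defaults
10 × 35, near the ~35 practices per area of English primary care);
registrations lognormal (median ≈ 7000 adult patients); composition drawn
hierarchically — group-level block means from a Dirichlet around national
shares, provider shares from a Dirichlet around their group mean, giving
realistic between-area segregation; a Beta long-term-condition share and a
Gamma deprivation score with a lognormal group multiplier. True category
probabilities follow an ordered-threshold model on a standard-normal
latent scale, P(≤ q) = Φ(τ_q − η) with η = β′x + u_group + e_practice;
default thresholds place a zero-effect practice at five-category national
proportions of 2.1/4.4/10.6/37.8/45.1 percent. The probit latent matches
the GLDRM link, so GLDRM is well specified and LPDRM is a working
approximation — the intended base-case/robustness pairing. Observed
profiles are multinomial draws of `n_responses` (default 110, the order of
a national survey's per-practice sample); `n_responses=None` returns exact
probabilities.

Default effect sizes (deprivation −0.010 per score point; ethnic-minority,
long-term-condition and working-age shares between −0.3 and −0.8 per unit
share; group SD 0.08; practice SD 0.25) were chosen once to produce
index magnitudes of the order seen in national practice-survey data.

What the generator does *not* emulate: survey non-response and its
weighting corrections, small-cell suppression, interactions between
socio-demographic factors, spatial correlation of deprivation, or temporal
dependence. Passing recovery tests therefore show the pipeline is correct
under main-effects compositional confounding with independent noise — not
that real survey data meet those assumptions.

Recovery oracles (`true_indices`) evaluate the indices on the true
category probabilities; the standardized truth zeroes group effects and
practice noise, keeping only the compositional part of the latent
location.

## Problem sizes and numerical conventions

Simulation-based tests use 3–5 groups × 8–40 providers with 100–10 000
responses, sizes at which the properties under test (consistency, RMSE
halving, residual-index recovery within bootstrap error) are already
well-resolved; the recovery acceptance check uses 5 × 40 with n = 200 and
a 50-replication clustered bootstrap. Profile sums are validated to 1e−9
and renormalized silently only within 1e−6 (published tables are rounded);
internal algebraic identities are enforced at 1e−12. Zero-weight providers
are retained and contribute nothing. Long CSV (one row per
provider × category) is the canonical interchange format; wide tables are
accepted on read only, and category order always comes from the scale
configuration, never from file order.

## Known limitations

- Provider-level (ecological) regression: individual-level heterogeneity
  and interactions are out of reach by design.
- The LPDRM can predict outside [0, 1]; censoring plus rescaling is a
  pragmatic repair, not a model fix — the GLDRM link avoids it.
- The within-group average's weighting (registration vs equal) is a
  genuine convention choice; both are exposed.
- τ_a inference is asymptotic (jackknife-normal); exact small-n inference
  is not provided.
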