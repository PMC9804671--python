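# ordqual

Statistical-preference comparison of healthcare provider quality for ordinal
and cardinal data: pairwise probability-of-superiority differences,
comparative quality indices, lottery indices of variation,
distribution-regression indirect standardization, and clustered bootstrap
standard errors.

## Who this is for

Health-services researchers and analysts comparing providers (general
practices, hospitals, commissioning areas) on quality indicators that are
often *ordinal* — multicategory patient-experience responses, inspection
ratings — where means and coefficients of variation are artifacts of an
arbitrary scoring scheme. The same machinery applies unchanged to cardinal
scores (e.g. clinical-achievement percentages) after rounding to a stated
precision, so ordinal and cardinal indicators can be assessed on a common
footing.

## The measures

Let each of K providers have a quality profile a_k(q) over ordered
categories q = 1..Q, with registration share p_k. For independent random
patients of providers k and k′, the **pairwise quality difference** is

    Δ_kk′ = P(Q_k′ > Q_k) − P(Q_k > Q_k′)  ∈ [−1, 1],

the difference in chances that the second patient fares strictly better
rather than strictly worse. It is invariant to any monotone relabelling of
the categories and ranks *every* pair (unlike first-order stochastic
dominance). From it:

- **Comparative quality index** Δ_k = Σ_k′ p_k′ (P(Q_k > Q_k′) − P(Q_k′ > Q_k)):
  provider k against the whole population; Σ_k p_k Δ_k = 0 by construction
  and |Δ_k| ≤ 1 − p_k.
- **Lottery index** L = Σ_k Σ_k′ p_k p_k′ |Δ_kk′| / (1 − Σ_k p_k²): the
  patient-weighted mean absolute pairwise difference; 0 when all profiles
  are equivalent, 1 under complete separation of quality supports. L/2 is
  the mean gain in winning chances from choosing the better provider of a
  random pair. Computed within groups, between groups, or pooled.
- **Indirect standardization**: one regression per cumulative cutoff
  F_k(q) (a linear-probability LPDRM or probit-binomial GLDRM) on the
  provider's socio-demographic composition plus group dummies; predictions
  at each provider's own composition with neutralized group effects give
  counterfactual profiles, hence standardized indices and
  residual = raw − standardized.
- **Clustered bootstrap**: providers resampled with replacement within
  their group, the whole pipeline recomputed per replicate.

A two-group between-group Gini identity (Yitzhaki–Lerman over Pyatt) gives
the cardinal Δ in closed form and serves as an independent cross-check of
the profile computation.

## Worked example

Two practices rate their care poor/OK/good: A = 40/10/50 %, B = 30/30/40 %,
equal registrations.

```python
from ordqual import datasets, lottery_index, pairwise_comparison

ps = datasets.two_practice_example()
cmp = pairwise_comparison(ps.profile("B"), ps.profile("A"))
print(f"P(A better) = {cmp.p_better:.2f}, P(B better) = {cmp.p_worse:.2f}, "
      f"P(tie) = {cmp.p_tie:.2f}")
print(f"lottery index L = {lottery_index(ps).L:.4f}")
```

prints

```
P(A better) = 0.33, P(B better) = 0.32, P(tie) = 0.35
lottery index L = 0.0100
```

A random patient of A beats one of B 33% of the time, loses 32% and ties
35%, so A's profile is better by one percentage point — even though scoring
the categories 1/2/3 gives both practices the same mean of 2.1. The same
numbers come from the command line:

```sh
ordqual lottery --within        # L = 0.0100 on the bundled example
```

The full pipeline on synthetic survey data:

```sh
ordqual simulate --seed 5 --out sim/
ordqual indices --profiles sim/profiles.csv --scale sim/scale.yaml --level group --out indices.csv
ordqual report --profiles sim/profiles.csv --composition sim/composition.csv \
               --scale sim/scale.yaml --out report.csv
```

`report.csv` contains raw, indirectly standardized and residual lottery
indices (within-group average and between-group) per regression link.

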