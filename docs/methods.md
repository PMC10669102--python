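# Methods

This note documents the models, the numerical choices, and the design
decisions behind `shortform`, and states what the synthetic-data tests do
and do not demonstrate.

## The measurement model

All analyses assume a two-factor congeneric model for a 36-item bank:
avoidance and anxiety are latent standard-normal factors with correlation
φ, and each item's continuous response is

    y_i = λ_ai·F_a + λ_xi·F_x + δ_i·e_i,   Var(y_i) = 1,

with δ_i chosen so the total variance is 1 (an error is raised if a row of
loadings leaves no room for a positive uniqueness). Near-duplicate "twin"
items share residual correlation (default 0.30 — strong enough to make
redundancy visible, weak enough to keep the residual matrix well
conditioned). Observed 7-point responses arise by cutting y_i at six
ordered thresholds; category c corresponds to the interval (t_{c−1}, t_c].

Default thresholds are −1.5, −0.9, −0.3, 0.3, 0.9, 1.5 for every item:
symmetric, equally spaced, yielding a mean category near 4 and mild tail
compression. Published item means are not generated from a threshold model
in the source instrument, so skewed items (per-item thresholds) are
configurable but not the default. Reverse-keyed items are emitted on the
observed (reversed) scale, so scoring and analysis must recode them — this
keeps the recoding path honest in every test.

The ten short-form items carry their published rotated loadings (including
the small cross-loadings, e.g. −0.21 for the last anxiety item). The 26
remaining items have no published loadings; the fixture assigns
deterministic synthetic values — 0.40–0.48 for the eleven ambiguous-wording
items (making them the weak indicators that stepwise elimination sheds
first) and 0.55–0.75 for the rest. The assignment of short-form positions
to long-form item ids (ascending ids within construct, alternating
presentation) is likewise a package convention; the source does not print
the mapping.

Missingness is MCAR only. Informative missingness, non-normal factors, and
IRT-style graded response generation are out of scope.

### What the generator does not emulate

Real attachment data show skewed item distributions, heteroscedastic
residuals, and sample heterogeneity (students vs. clinical samples). The
synthetic tests therefore demonstrate *algorithmic* correctness (recovery,
oracle agreement, closed-form convergence), not robustness of the published
short form to population variation.

## Maximum-likelihood CFA

The fitter minimizes the normal-theory discrepancy
F_ML = ln|Σ(θ)| + tr(S·Σ⁻¹) − ln|S| − p over free loadings, free residual
variances, and free factor covariances, with factor variances fixed to 1.
This identification matches df = 5 for a 5-indicator subscale
(15 moments − 10 parameters) and df = 34 for the 10-item two-factor model.

Numerical choices:

* Congeneric models are scale invariant, so the fit is performed on the
  correlation matrix; estimates come out standardized and χ² is identical
  to the covariance-matrix fit.
* L-BFGS-B with analytic gradients (dF = tr(G dΣ) with
  G = Σ⁻¹(Σ−S)Σ⁻¹), start values λ = 0.7, θ = 0.51, ψ = 0, ftol 1e−14 /
  gtol 1e−9. A non-PD Σ during line search returns a large penalty value.
* χ² = (n−1)·F_ML. This convention reproduces the published RMSEA values
  at two decimals from the published χ², df, and n.
* Non-convergence and Heywood cases (θ < 0) are flagged on the fit object,
  not raised: optimization loops treat such subsets as rejected (criterion
  total 0).
* Saturated models (df = 0) report RMSEA 0 with a degenerate CI; the
  misfit-per-df notion is undefined there.
* RMSEA CI bounds solve noncentral-χ² tail equations
  (cdf(χ²; df, λ) = 0.95 / 0.05) by bracketed root finding, then transform
  by √(λ/(df(n−1))).
* Factor signs are normalized so each factor's loading sum is nonnegative.

EFA uses ML extraction and rotation from statsmodels behind the package's
interface; varimax is the default because the two attachment scales are
(near-)orthogonal, with oblique rotations available by name. The rotation
behind the published loading table is not named in the source; the
recovery tests resolve the permutation/sign indeterminacy by aligning to
the generating pattern, and tolerate the ≈3% attenuation that 7-category
discretization imposes on Pearson correlations.

## Reliability and scoring

ω comes from the unidimensional CFA of a scale ((Σλ)²/((Σλ)²+Σθ)); α is
computed independently from item/total variances on listwise-complete rows.
They are deliberately not derived from one another. Short-form scoring
recodes positions 1, 3, 7, 9 (x → 8−x), averages odd positions for
avoidance and even for anxiety, and requires at least 4 of 5 answered
items per scale. The long form requires 15 of 18 by analogy; that
threshold is a package default, not a published rule, and is configurable.

## The optimization criterion

Each of four raw indices is mapped through a logistic
g(x) = 1/(1+exp(−s·d)), d = x−cutoff (higher-better) or cutoff−x
(lower-better), with cutoffs CFI 0.95, RMSEA 0.05, ω 0.70, long-scale
correlation 0.80, |opposite-scale correlation| 0.10. The fit component is
the unweighted mean of the CFI and RMSEA logistics ("a composite score");
the total is the weighted sum of the four components (default weights 1,
range 0–4). The slope s (default 100) is this package's parameterization
of the steep penalty near the cutoff; the literature the procedure derives
from does not pin the weighting term down numerically, so s is exposed in
configuration rather than asserted as canonical. Independence uses |r|:
both signs of dependence are undesirable.

## Ant colony search

Per-item (node-based) pheromone, τ_init = 1. Each of 80 ants draws 5
distinct items with probability proportional to τ (sequential draws
without replacement). After an iteration, τ ← 0.9·τ, the iteration-best
subset's items receive a deposit of 0.1 × its criterion total, and τ is
floored at 0.01 so no item becomes unreachable. The run stops after 50
iterations without improvement of the global best; 15 restarts with
derived seeds, ties broken toward the lexicographically smallest id set.
The update rule (iteration-best deposit, multiplicative evaporation,
floor) follows the ACO-for-item-selection literature; all constants are
config-exposed. Evaluations are cached by subset, which makes the
15-restart search cheap once the enumeration oracle has run.

Content rules (twin pairs, worry-stem overload, banned items) are applied
to candidate solutions *after* optimization, as a filter — inadmissible
solutions are dropped, not prevented from being sampled.

SCOFA (stepwise CFA) refits the unidimensional model after removing the
lowest-loading item (ties toward the smaller id) until 3 items remain,
recording AIC (χ²−2df scale; BIC logged too) at each step; the suggested
length is the pool size with minimal AIC. On clean near-congeneric
synthetic data the full pool often fits well, so the AIC minimum can sit
at the full length — the informative output there is the elimination
order, which sheds the weak ambiguous-wording items first. A step that
fails to converge is flagged and the drop decision falls back on the
previous step's loadings.

## Problem sizes used in tests and the acceptance script

Exhaustive enumeration runs on an 18-item planted pool
(C(18,5) = 8568 subsets, n = 500); parameter recovery on n = 5000 Likert
responses; closed-form reliability on n = 100 000 continuous responses;
covariance-contract checks on n = 50 000. These sizes keep every
statistical tolerance comfortably above sampling error while the full
suite runs in about a minute.

## Known limitations

* Estimation is normal-theory ML on Pearson covariances of Likert
  responses treated as continuous; no categorical (polychoric/WLSMV)
  estimator is provided, so loadings on discretized data are attenuated by
  a few percent relative to the generating values.
* No FIML: missing data are handled by listwise deletion before moments
  (pairwise-complete for criterion correlations).
* Criterion correlations computed on *scale scores* are attenuated
  relative to factor-level targets by measurement error; the generator's
  contract is stated (and verified) at the factor level via the exported
  true factor scores.
* No multiple-testing correction in the validity tables; stars are the
  conventional unadjusted thresholds.
* The search optimizes subscales separately; simultaneous multi-construct
  optimization and edge-based pheromone models are out of scope.
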