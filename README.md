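# shortform

Construction and validation of psychometric short forms, built around the
pipeline that produced the **ECR-G-10** — the 10-item short form of the
German Experiences in Close Relationships scale, which measures the two
adult-attachment dimensions *avoidance* and *anxiety* with five 7-point
Likert items each.

The package is for psychometricians and applied researchers who need to
abbreviate a multi-item scale in a defensible way: not by picking the
highest-loading items, but by searching the space of candidate item subsets
for the one that jointly satisfies model fit, reliability, criterion
validity, and subscale independence, and then checking that the chosen
solution replicates.

## What it does

* **Item banking** (`shortform.bank`) — item metadata (construct, reverse
  keying, partner-wording class, worry stems, twin items), content-based
  pre-selection of the candidate pool, and post-hoc admissibility rules for
  candidate solutions (no near-duplicate twin pairs, no stem overload, no
  banned items).
* **Synthetic data** (`shortform.simulate`) — Likert response matrices from
  a two-factor congeneric model: item *i* is generated as
  `y_i = λ_ai·F_a + λ_xi·F_x + δ_i·e_i` with unit variance, then cut at
  ordered thresholds into categories 1–7; reverse-keyed items are emitted
  reversed, twins share residual correlation, and entries go missing
  completely at random. External criterion variables with specified factor
  correlations can be generated alongside.
* **Factor analysis** (`shortform.factor`) — maximum-likelihood CFA for
  congeneric measurement models (factor variances fixed at 1), minimizing
  `F_ML = ln|Σ(θ)| + tr(S·Σ(θ)⁻¹) − ln|S| − p` with analytic gradients;
  `χ² = (n−1)·F_ML`, CFI against the independence baseline, RMSEA with a
  noncentral-χ² 90% CI, and AIC/BIC for stepwise comparisons. ML EFA with
  varimax (or oblique) rotation and eigenvalue/variance summaries.
* **Reliability & scoring** (`shortform.reliability`) — McDonald's
  ω = (Σλ)²/((Σλ)²+Σθ) from CFA estimates, Cronbach's α, corrected
  item-total correlations, and scale scoring with reverse-key recoding and
  minimum-answered rules (≥4 of 5 items for the short form).
* **Abbreviation** (`shortform.abbreviate`) — the composite optimization
  criterion (four logit-transformed components: fit, reliability,
  convergence with the long scale, independence from the opposite scale),
  ant colony optimization over item subsets (80 ants, evaporation 0.9,
  stop after 50 improvement-free iterations, 15 restarts), stepwise CFA
  elimination (SCOFA), and an exhaustive-enumeration oracle.
* **Validation** (`shortform.validate`) — external-criterion correlation
  tables with significance stars and cross-sample replication reports for a
  fixed solution.

The shipped `shortform.ecr` module carries the ECR-G-36 item bank, the
published 10-item solution (avoidance items 7, 15, 25, 27, 35; anxiety
items 8, 18, 20, 24, 30), its published item statistics, and a synthetic
population model with the matching factorial structure.

## Worked example

Evaluate the published avoidance solution on a simulated development-sized
sample (n = 788) drawn from the shipped population model:

```python
import shortform as sf
from shortform import ecr

bank = ecr.build_ecr_bank()
model = ecr.default_population_model()
study = sf.simulate_study(model, n=788, seed=3)

evaluator = sf.SubsetEvaluator(study.responses, bank, "avoidance")
value = evaluator(ecr.AVOIDANCE_SOLUTION)
print(f"items {ecr.AVOIDANCE_SOLUTION}")
print(f"CFI={value.cfi:.3f}  RMSEA={value.rmsea:.3f}  omega={value.omega:.2f}")
print(f"r(long)={value.r_long:.2f}  r(opposite)={value.r_opposite:.2f}")
print(f"criterion total = {value.total:.3f}")
```

prints

```
items (7, 15, 25, 27, 35)
CFI=0.996  RMSEA=0.037  omega=0.83
r(long)=0.92  r(opposite)=0.02
criterion total = 3.885
```

All four cutoffs are met (CFI > 0.95, RMSEA < 0.05, ω > 0.70, correlation
with the 18-item avoidance scale > 0.80, |correlation| with the anxiety
scale < 0.10), so each logit component is close to 1 and the total
approaches its maximum of 4.

The same machinery is available from the shell:

```sh
shortform simulate --n 788 --seed 3 --out responses.csv
shortform abbreviate --input responses.csv --construct avoidance \
    --seed 1 --out best.json
shortform score --input responses.csv --form long --out scores.csv
```

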