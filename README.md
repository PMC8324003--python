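# aitrlearn

Set-valued individualized treatment recommendations by angle-based
outcome-weighted learning.

## The problem

Conventional individualized treatment rules (ITRs) map a patient's
covariates **x** to the *single* treatment with the best expected outcome.
When several treatments are practically indistinguishable, committing to
one of them is statistically fragile (the top-ranked arm is an artifact of
estimation noise) and clinically unhelpful (it hides alternatives the
patient might prefer on cost, side-effect or lifestyle grounds).

`aitrlearn` learns *near-optimal* recommendation sets instead.  With
`μ_j(x) = E[Y | X = x, A = j]` the conditional mean outcome of treatment
`j` (outcomes positive, **smaller is better**) and a clinician-chosen
near-optimality constant `c ≥ 1`, the target is the oracle set

    φ*(x) = { j : μ_j(x) / μ_(1)(x) ≤ c },

every treatment within a factor `c` of the best.  The package estimates
φ* from randomized or observational data `(x_i, a_i, y_i)` inside the
outcome-weighted learning framework: finding a good rule is a weighted
classification problem with weights `w_i = y_i / p(a_i | x_i)`, solved
over a `(k−1)`-dimensional decision function `f` whose *angle margins*
`⟨W_j, f(x)⟩` (inner products with the vertices `W_1..W_k` of a regular
simplex) score the k treatments.

Two estimators are provided:

- **one-step** — minimizes the IPW-weighted *bent hinge* loss
  `ℓ(u) = (1+u)₊ + (c−1)u₊`.  The extra slope `c−1` on `u > 0` shrinks the
  margins of all near-optimal treatments to exactly zero at the population
  optimum, so `φ̂(x) = { j : ⟨W_j, f̂(x)⟩ ≥ δ·M(x) }` (threshold `δ ≈ 0`,
  scale `M(x)` = magnitude of the smallest margin) is consistent for φ*.
  Solved by exact coordinate ascent on the box-constrained dual.
- **two-step** — minimizes a differentiable loss, then estimates the mean
  *ratios* from loss-derivative ratios,
  `μ_j/μ_(1) ≈ ℓ′(⟨W_(1), f̂⟩) / ℓ′(⟨W_j, f̂⟩)`, and thresholds them at `c`.

A regression **plugin** baseline (per-arm kernel ridge), IPW evaluation
criteria, two-stage cross-validated tuning (ridge penalty λ by the value
of the induced single-valued rule, then δ by the cardinality-penalized
weighted outcome), the oracle rules, and the simulation designs used for
benchmarking are all included.  Intended users: biostatisticians and
methods researchers working on precision-medicine policy learning.

## Worked example

```python
import numpy as np
from aitrlearn import AITRModel, KernelSpec, DGPSpec, draw_dataset

# a synthetic 3-arm randomized trial: one quadratic-bowl arm, two flat arms
train, _ = draw_dataset(DGPSpec(example_id=1, p=2), 500, seed=7)

model = AITRModel(train, c=1.2, method="one_step",
                  kernel=KernelSpec("polynomial"))
res = model.fit_tuned(lambda_grid=5.0 ** np.arange(-6, 3), seed=7)
print(res.summary())
```

```
Near-optimal treatment recommendation results
=============================================
method:            one_step
loss:              bent_hinge
kernel:            polynomial
n / p / k:         500 / 2 / 3
near-optimality c: 1.2
lambda:            6.4e-05
delta:             0.05
final objective:   7.04171
solver iterations: 2000 (cap reached)
IPW value (ITR):   2.0992
weighted outcome:  2.0597
set sizes:         |phi|=1: 329, |phi|=2: 171
```

`IPW value` is the self-normalized inverse-probability estimate of the
mean outcome if everyone followed the single best-margin treatment
(smaller is better; the oracle value for this design is 2.08).  The
`weighted outcome` generalizes it to sets, dividing each recommended
set's pooled outcome by `1 + (|φ|−1)c` so that enlarging a set only pays
off when the added arms are genuinely near-optimal.  Here about a third
of subjects get a two-treatment recommendation.

```python
Xnew = np.array([[0.0, 0.0], [0.9, 0.9], [-0.9, 0.3]])
print(res.recommend(Xnew).to_lists())
# [[1], [2], [2]]
```

At the origin arm 1 is uniquely best (`μ = (1, 3, 3)`); at (0.9, 0.9) the
bowl arm is poor and arm 2 wins.

The same pipeline is available from the shell:

```bash
aitrlearn simulate --example 1 --n 500 --p 5 --seed 7 --out trial.csv
aitrlearn tune --data trial.csv --method one-step --kernel polynomial \
    --c 1.2 --out model.json
aitrlearn recommend --model model.json --data trial.csv --out recs.csv
aitrlearn evaluate --recommendations recs.csv --data trial.csv --out report.json
```

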