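# Methods

This note documents the statistical model, the estimators, the numerics,
and the design choices behind `aitrlearn`, together with what the
synthetic benchmarks do and do not demonstrate.

## Setting and target of estimation

Data are i.i.d. triples `(X, A, Y)`: covariates `X ∈ R^p`, a treatment
`A ∈ {1, …, k}`, and a bounded positive outcome `Y` with *smaller
preferred*.  Identification rests on the usual causal assumptions: the
potential outcomes `Y*(j)` are independent of `A` given `X`
(no unmeasured confounding), `Y = Σ_j Y*(j) 1[A = j]` (consistency), and
`p(A = j | X) > 0` (positivity).  Under these, the value of a rule `d` —
the mean outcome if the population followed it — is
`E[ 1[A = d(X)] Y / p(A|X) ]`, which is estimable by inverse probability
weighting.

With `μ_j(x) = E[Y | X = x, A = j]`, the estimand is the set-valued rule

    φ*(x) = { j : μ_j(x) / μ_(1)(x) ≤ c },    c ≥ 1,

where `μ_(1)` is the smallest conditional mean.  `c` is a *clinical*
constant, not a tuning parameter: it encodes how close "indistinguishably
good" is, and at `c = 1` the rule degenerates to the classical
single-best ITR.  The ratio form is why outcomes must be positive;
`transform_outcome` (an OLS-centered exponential transform
`y = exp((y_raw − m̂(x))/τ)`, default `τ = 5`) maps a real-valued endpoint
onto this scale.  On the raw scale, the multiplicative band `c`
corresponds to the additive band `τ·log c` — e.g. `5·log(1.2) ≈ 0.9`.

## Angle-based decision functions

Treatment `j` is encoded as the vertex `W_j` of a regular simplex in
`R^{k−1}`: `W_1 = (k−1)^{−1/2} 1`, and for `j ≥ 2`
`W_j = −(1+√k)(k−1)^{−3/2} 1 + √(k/(k−1)) e_{j−1}`.  The vertices are
unit vectors with constant pairwise inner product `−1/(k−1)` and zero
sum, so the k angle margins `⟨W_j, f(x)⟩` of any decision value
`f(x) ∈ R^{k−1}` sum to zero — in particular the smallest margin is never
positive, which the one-step rule's normalization relies on.

All estimators minimize the regularized outcome-weighted empirical risk

    (1/n) Σ_i w_i · ℓ(⟨W_{a_i}, f(x_i)⟩) + λ J(f),    w_i = y_i / p(a_i|x_i),

over a linear class (`f_j(x) = x^T β_j` with a prepended constant,
`J = Σ_j ‖β_j‖²`) or an RKHS class
(`f_j(x) = Σ_i K(x_i, x) α_ij + α_0j`,
`J = Σ_j α_j^T K α_j + α_0j²`).  Penalizing the intercepts keeps the dual
a pure box problem (no equality constraint); the induced rules are
unaffected in practice.  Because the objective is 1-homogeneous in
`(w, λ)` jointly, doubling all outcomes and λ leaves the minimizer
unchanged — a property the tests exercise.

Losses are *increasing* convex functions (the mirror image of the usual
classification orientation, since small outcomes are good and the weight
multiplies the loss of the *received* treatment):

| family | ℓ(u) | used by |
|---|---|---|
| hinge | `(1+u)₊` | one-step, `c = 1` |
| bent hinge | `(1+u)₊ + (c−1)u₊` | one-step |
| squared | `(1+u)²` | two-step (default) |
| exponential | `e^u` | two-step |
| bent squared / bent exponential | smooth part `+ (c−1)u₊` | ADMM path |

Two caveats are deliberate.  The squared loss is only non-decreasing
right of `u = −1` (it is a parabola in `1+u`); its derivative `2(1+u)`
can vanish, so the two-step ratio estimator floors the denominator at
`1e−6` and returns an infinite-ratio sentinel if even the best margin's
derivative is dead.  The exponential loss has a strictly positive
derivative everywhere and is the theoretically clean two-step choice; the
squared loss remains the default because it is the standard benchmark
configuration.

## The two estimators

**Two-step.**  Fit `f̂` under a differentiable loss, order the margins,
and estimate mean ratios by derivative ratios
`μ̂_j/μ̂_(1) = ℓ′(⟨W_(1), f̂⟩)/ℓ′(⟨W_j, f̂⟩)` (a population identity for the
exact minimizer); recommend `{ j : ratio ≤ c }`.  The argmax-margin
treatment always has ratio exactly 1, so sets are never empty.

**One-step.**  Fit `f̂` under the bent loss.  At the population optimum
the margins separate three groups exactly: positive for the best
treatment, *zero* for every other near-optimal treatment, negative for
the rest — the bent slope acts like a lasso penalty on positive margins.
The recommendation thresholds margins at `δ·M(x)` where
`M(x) = |smallest margin|`; `δ = 0` is the canonical rule, and tuning δ
in a small band around zero absorbs finite-sample and scale noise.  An
empty set (possible only for `δ > 1` or numerical noise) falls back to
the argmax singleton with a logged warning.

**Plugin baseline.**  Per-arm kernel ridge regression of `y` on `x` with
the same kernel options, thresholded at `c` — the regress-and-compare
baseline the classification methods are judged against.

## Solvers

*Dual coordinate ascent (hinge / bent hinge).*  The Lagrange dual has one
box `0 ≤ α_i ≤ w_i` per subject, plus `0 ≤ γ_i ≤ w_i` for the bent part,
and the primal is recovered as
`β_j = −(1/(2nλ)) Σ_i (α_i + (c−1)γ_i) W_{a_i,j} x̃_i`.  Each coordinate
has a closed-form clipped Newton step driven by the current margin
`u_i` (the gradient is proportional to `1 + u_i` for α and to `u_i` for
γ), maintained incrementally in O(n) per update.  Sweeps visit the
coordinates in a freshly shuffled order each epoch (cyclic order can
zig-zag for thousands of epochs on ill-conditioned instances); iteration
stops when the largest coordinate change in an epoch falls below `1e−6`,
when the duality gap — computable in O(n) from the maintained margins —
certifies the objective to `1e−9` relative, or at an epoch cap (2000 by
default, automatically raised for small n on a fixed flop budget so tiny
ill-conditioned problems still converge).  Zero-weight subjects have
degenerate boxes and stay inactive.  Kernel learning reuses the same
routine with the gram matrix plus an all-ones intercept feature in place
of `x̃ x̃^T`.  The stored `objective_trace` is the *negated dual*
objective: it decreases monotonically by construction and converges to
the primal optimum by strong duality (the recovered primal objective
itself is not monotone along dual ascent).

*ADMM (bent smooth losses).*  For losses with a differentiable smooth
part the objective splits as smooth + positive-part; ADMM alternates a
quasi-Newton solve of the smooth block, an *exact* prox of the bent block
(a small box-constrained dual solved by the same coordinate-ascent
scheme — quasi-Newton on the kinked block stalls and was measurably
inaccurate), and a multiplier update with fixed step `ρ = 1`.  At
`c = 1` the bent block vanishes and the problem is solved directly by
L-BFGS.  The recorded objective converges to the optimum but is not
monotone — ADMM's infeasible split iterate typically undershoots and
approaches the optimum from below; tests therefore assert convergence to
an independent oracle rather than descent.  Kernel mode runs on a
Cholesky feature map of the gram matrix (jitter `1e−8`), which reproduces
the RKHS penalty exactly, then converts back to representer coefficients.

*Kernels.*  Gaussian `exp(−‖x−x′‖²/(2σ²))` with σ defaulting to the
median pairwise training distance; polynomial `(1 + ⟨x, x′⟩/p)²` by
default, the inner product scaled by the dimension so the kernel stays
O(1) as p grows.

All solver routes are validated against independent oracles on small
instances: an SLSQP solve of the slack (QP) reformulation, an exact
linear solve for the squared loss, a linear program for the pointwise
bent-hinge population problem, and BFGS for the exponential one.  The
agreement contract is `1e−4` relative in objective.

## Evaluation and tuning

The value of a single-valued rule and the weighted outcome of a
set-valued rule are estimated by self-normalized IPW ratios (see the
module docstring of `evaluate` for the exact forms); for singleton sets
they coincide exactly.  The weighted-outcome criterion divides a set's
pooled mean by `1 + (|φ|−1)c`, so adding a treatment helps if and only if
its mean is within the factor `c` of the best — its population minimizer
`φ⁺` (computed here by brute force over all `2^k − 1` subsets, ties
broken by smaller cardinality then lexicographic order) agrees with φ*
on where a single treatment suffices and never recommends more
treatments, which justifies using it as a model-selection criterion even
though it differs from φ* off the singleton region for `k ≥ 3`.

Tuning is two-stage with 5-fold cross-validation throughout: λ minimizes
the CV value of the induced single-valued rule (grid points whose IPW
denominator is empty are infeasible and skipped; ties go to the smaller
λ), then, for the one-step method, δ minimizes the CV weighted outcome
over 25 equally spaced values in `[−0.3, 0.3]` on the same fold fits
(ties go to the δ nearest zero).  Propensities, when not supplied, come
from multinomial logistic regression, floored at 0.01 to bound the
weights; solver weights additionally clip outcomes below `1e−6`, with
the number of clipped values logged.

## Synthetic designs

Covariates are uniform on `[−1, 1]^p` and treatments uniformly
randomized (`p(A|X) = 1/k`); outcomes are `μ_A(X) + ε`,
`ε ~ N(0, 1/2)` — read as *variance* one-half (sd ≈ 0.707), recorded as a
config field since the sd-½ reading cannot be excluded.  Three designs
(formulas in the `simulate` module docstring): a quadratic-bowl-vs-flat
3-arm design whose oracle regions split roughly 70/25/5 percent at
`c = 1.2`; a 4-arm cosine design with two everywhere-dominated arms that
still enter the near-optimal set on part of the space; and a clipped
3-arm design that deliberately violates the no-proportional-ties margin
condition the one-step consistency argument assumes, to probe robustness.
Potential outcomes are drawn with independent per-arm noise by default
(needed so per-region best/worst-case "performance intervals" are
nondegenerate); a shared-noise switch exists.

What the benchmarks show: the oracle geometry (region fractions,
Bayes-rule values) is reproduced to Monte-Carlo precision, and the tuned
one-step pipeline at n = 1000 with a polynomial kernel attains a mean
test-set weighted outcome of about 2.20 on design 1 over 10 replications
(oracle 2.05) — the replication count and sample size were chosen to keep
the study desk-scale.  What they do not show: robustness to estimated
(mis)specified propensities, confounded treatment assignment,
non-Gaussian or heteroscedastic outcomes, or covariate distributions with
structure — the designs are deliberately clean randomized trials.

## Known limitations

- The IPW criteria inherit the large weight variance of outcome-weighted
  learning; augmented/doubly robust variants are out of scope.
- The two-step ratio estimator is only as good as `f̂`; off the optimum
  its sets have no sandwich guarantee and the formula is applied verbatim.
- Interval estimates (confidence statements) for values and weighted
  outcomes are not provided.
- `k = 1` is rejected (no decision problem), and treatment labels must be
  consecutive integers from 1.
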