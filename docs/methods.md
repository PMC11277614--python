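# Methods

## Models

The package fits binary person × item response data whose item difficulty is
decomposed over a binary item × feature incidence matrix **Q** (J items × K
features). Four nested models are supported.

**LLTM.** The linear logistic test model is a Rasch-type model whose item
difficulty is a linear combination of feature difficulties,
β = Qη:

P(y_ij = 1) = σ(θ_i − Σ_k q_jk η_k),  σ(z) = 1 / (1 + e^(−z)).

**Constrained 2PL.** Adds one slope per item:
P = σ(α_j (θ_i − Σ_k q_jk η_k)), α_j ≥ 0.

**MLTM-D.** The multicomponent latent trait model for diagnosis groups
features into M components (latent traits). Each feature k that loads on
component m carries a difficulty η_mk, composing the component-level item
difficulty b_jm = Σ_k q_jk η_mk over component-m features. The J × M binary
C matrix marks which components an item requires (C_jm = 1 iff some feature
of item j loads on m), and success requires mastering all of them —
probabilities multiply (non-compensatory):

P(y_ij = 1) = Π_m σ(θ_im − b_jm)^{C_jm}.

High ability on one component cannot offset low ability on another, and a
component absent from an item (C_jm = 0) cannot influence it — the kernel
excludes inactive components from the product entirely, so the value is
bit-identical under any change of their abilities. With M = 1 the model is
exactly the LLTM.

**GMLTM-D.** The generalized model adds component-wise discrimination and a
guessing floor in the three-parameter style:

P(y_ij = 1) = c_j + (1 − c_j) Π_m σ(α_jm (θ_im − b_jm))^{C_jm}.

Discrimination is treated as a property of the feature combination, not of
the item: items whose feature pattern *restricted to component m* is
identical share a single α. The discrimination partition is computed from Q
and the assignment; group order is canonical (component, then the restricted
pattern sorted as a bit string in Q column order), which makes parameter
indexing reproducible across runs. With α ≡ 1 and c ≡ 0 the model reduces
to the MLTM-D; the suite asserts the full reduction chain to 1e−12.

Items with an all-zero Q row are rejected at validation: the empty product
would force P = 1 regardless of ability. C-matrix overrides are additive
only (a derived 1 can never be removed, which would contradict the C
definition), and an added cell must be supported by the feature →
component incidence; the intended way to express cross-loading is to list a
feature under several components in the assignment, which creates an η slot
in each and re-derives C.

## Priors and estimation

Priors (all overridable): θ_im ~ N(0, 1), η_mk ~ N(0, 1), α ~ N(0, 1)
truncated to [0, ∞) (half-normal), c_j ~ Beta(3, 20). Ability components
are a priori independent; θ's scale is fixed by its prior, so no further
identification constraint is imposed. Guessing stays on (0, 1) through the
beta prior directly.

The posterior is sampled with the package's own No-U-Turn HMC sampler
(doubling trajectories with slice sampling, dual-averaging step-size
adaptation to a 0.8 target acceptance, diagonal mass matrix estimated in
expanding warmup windows, divergence detection at an energy error of 1000).
Gradients of the log posterior are analytic; a finite-difference test pins
them for all four model kinds. Constrained parameters are sampled on
unconstrained scales — α as log α and c as logit c, each with its Jacobian
correction. Correctness of the whole chain is checked by sampling with an
all-missing response matrix, which must (and does) reproduce all four
priors to Kolmogorov–Smirnov precision.

Defaults are 4 chains × 1000 warmup × 1000 sampling iterations; one seed
fully determines the draws (chains use independently spawned substreams).
The likelihood unit is the single person-item response; missing cells drop
out of the likelihood (ignorable missingness). Convergence reporting uses
arviz split R-hat and bulk ESS per parameter, aggregated per block.

## Model checking

* **Prior predictive check** — item marginal success proportions simulated
  under parameter draws from the priors.
* **Posterior predictive marginals** — for each selected posterior draw a
  full replicate response matrix is simulated (abilities taken from the
  draw, so parameter uncertainty propagates fully rather than being fixed
  at the EAP); each item's replicate proportions are summarized as EAP and
  central 2.5–97.5% interval next to the observed proportion.
* **Discordance rate** — share of items whose observed proportion falls
  strictly outside its interval.
* **Interval bias** — mean over items of the exceedance beyond the nearest
  interval endpoint (0 for items inside). This definition is explicit
  because the quantity is conventionally reported without a formula; it
  reproduces the expected ordering across models.
* **SRMR** — root mean square of residuals pooled over the J marginal
  proportions and the J(J−1)/2 inter-item Pearson correlations
  (the residual-correlation convention for binary IRT data), comparing
  observed statistics with posterior-predictive means. Items with zero
  observed variance are excluded from the correlation part with a logged
  warning.
* **WAIC** — from the pointwise (per response cell) log-likelihood:
  lppd = Σ log mean_s exp(ll), p_waic = Σ var_s(ll) with the *sample*
  variance, waic = −2(lppd − p_waic). arviz (which uses the population
  variance) serves as an independent cross-check in the tests, with the
  ddof difference accounted for exactly.
* **Component ICCs** — per-component curves σ(α_jm(θ − b_jm)) over a grid
  plus the joint curve along the diagonal θ_1 = θ_2; the joint curve's left
  asymptote is c_j and each component curve crosses 0.5 at b_jm.

## Synthetic data and the canonical fixture

The simulator draws y_ij ~ Bernoulli(p_ij) under any of the four kernels,
with abilities supplied or drawn N(0, 1). The canonical fixture emulates
the 27-item figural analogies study: its published 27 × 5 Q matrix over
five composition rules (principal-figure rotation, trapezium rotation,
whole-figure reflection, line subtraction, point movement), the global
(rules 1–3) / local (rules 4–5) component assignment, and the published
generalized-model EAP point estimates as ground truth — η = (0.29, 0.77,
0.39 | 0.87, −0.79), seven group discriminations between 1.42 and 2.66,
and per-item guessing between 0.02 and 0.57. Point estimates (not draws)
are used as truth to give a single canonical, citable parameter set. The
default fixture size is the study's 383 persons.

The generator reproduces the model's own independence assumptions only: no
local item dependence, no speededness, no respondent heterogeneity beyond
θ. Passing recovery tests therefore demonstrates correctness of the
estimator under the model, not robustness to violations real data may
carry.

## Validation design and problem sizes

The recovery harness (simulate → fit → score, replicated from one master
seed with spawned substreams) reports bias, RMSE, 95% interval coverage
and EAP–truth correlation per parameter block. The package's desk-scale
validation design, chosen once:

* recovery of the generalized model at N = 500, 4 chains × (500 + 800);
* model comparison at N = 200 over 5 replications, each fitting GMLTM-D,
  MLTM-D and LLTM with 2 chains × (150 + 120), scored by majority vote on
  WAIC, SRMR and discordance orderings.

A caveat established with an independent quadrature oracle (posterior over
θ by numerical integration with the true item parameters known): the local
component of this instrument supports an EAP–truth rank correlation of only
≈ 0.59 regardless of estimator quality, because just 17 of 27 items load
it, 11 of them easy (b = −0.79) under a guessing floor. Mean posterior
variance of θ_local is ≈ 0.58 versus ≈ 0.28 for the global component. The
sampler's θ interval coverage is nominal (≈ 95%), i.e. estimation is
calibrated; the ceiling is informational, a property of the instrument.

## Numerical choices

* Logistics are evaluated through the log-sum-exp-safe branch; component
  products accumulate in log space and exponentiate once. Public kernels
  floor the exponentiation at the smallest positive float so extreme
  abilities (|z| ≥ 700) return a strictly positive, finite probability.
* Inside the sampler, probabilities are floored at 1e−300 before ratios so
  gradients stay finite; unconstrained α and c are clipped at ±40 on the
  log/logit scale before exponentiation.
* Quantile summaries use the central 2.5/97.5% empirical quantiles of the
  pooled chains; ties in model comparison are broken by model name.
* The `pointwise_loglik` array is computed lazily from the stored draws
  (it evaluates the same kernel as the probability functions, asserted to
  1e−10 in the tests).

## Known limitations

Polytomous responses, compensatory MIRT, correlated ability priors,
maximum-likelihood/EM estimation and LOO-CV are out of scope. The
interval-bias and SRMR definitions are explicit package choices among the
conventions in use; alternative residual sets (covariances, tetrachorics)
would change the absolute values but not the orderings the tests assert.
Sampler performance degrades for very weakly identified posteriors (e.g.
guessing parameters at tiny N); the convergence report should be consulted
before interpreting any fit.
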