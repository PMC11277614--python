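# gmltmd

Bayesian estimation and checking of **multicomponent latent trait models**
for binary test data whose items are built from a feature (Q) matrix —
the LLTM, a constrained 2PL, the non-compensatory MLTM-D, and its
three-parameter generalization, the GMLTM-D.

These models are used to study *response processes*: instead of one
difficulty per item, item difficulty is decomposed over the composition
rules the item contains (β = Qη), and rules are grouped into latent
components (e.g. global vs local perceptual features of figural analogy
items). The generalized model is

P(y_ij = 1) = c_j + (1 − c_j) · Π_m σ(α_jm (θ_im − b_jm))^{C_jm},
b_jm = Σ_k q_jk η_mk,

with person abilities θ, feature difficulties η, discriminations α shared
by items with identical feature patterns within a component, guessing
floors c, and the binary C matrix selecting which components an item
requires (non-compensatory: the probabilities of mastering each required
component multiply). With α ≡ 1, c ≡ 0 it is the MLTM-D; with M = 1 the
MLTM-D is the LLTM.

The package provides:

* validated Q / component structures, composed item parameters, and the
  discrimination-sharing partition (`gmltmd.structures`);
* exact probability kernels for all four models (`gmltmd.kernels`);
* NUTS-based posterior sampling with analytic gradients, convergence
  diagnostics and EAP/interval summaries (`gmltmd.inference`);
* prior/posterior predictive checks, discordance rate, interval bias,
  SRMR, WAIC and model comparison, component ICC curves
  (`gmltmd.evaluation`);
* a seeded simulator, the canonical 27-item figural-analogies fixture and
  a parameter-recovery harness (`gmltmd.simulate`);
* CSV/YAML I/O and a `gmltmd` command-line interface (`gmltmd.io`,
  `gmltmd.cli`).

See `docs/methods.md` for the full model and design notes.

## Worked example

Fit the generalized model to data simulated from the canonical fixture
(the 27-item figural analogies test, five composition rules, global/local
components) and inspect the feature difficulties:

```python
import gmltmd as g

q, cs, truth, y = g.study_fixture(seed=1, n_persons=383)
fit = g.fit_model(y, q, cs, "gmltmd",
                  cfg=g.SamplerConfig(chains=2, warmup=400, samples=400, seed=1))
print(g.check_convergence(fit)[["block", "max_rhat", "passed"]])
print(fit.summaries.query("parameter.str.startswith('eta')"))
```

Output from this exact run:

```
   block  max_rhat  passed
   theta  1.017131   False
     eta  1.013950   False
   alpha  1.018896   False
guessing  1.010319   False
parameter       eap      q2.5     q97.5
   eta[0]  0.335455  0.180995  0.482917
   eta[1]  0.902083  0.732209  1.063550
   eta[2]  0.536498  0.358976  0.734321
   eta[3]  0.910247  0.530859  1.316508
   eta[4] -0.709107 -0.930961 -0.497984
```

Every 95% interval covers its generating value (0.29, 0.77, 0.39, 0.87,
−0.79): trapezium rotation and line subtraction are the hardest rules,
point movement makes items easier. At this deliberately short two-chain
demo budget the worst split R-hats sit just above the 1.01 threshold —
use the 4 × 1000 default for production fits. Composed item difficulties
follow the linear identity b = Qη — item 11 (rules 2+3 globally, 4+5
locally) has b_global = 0.77 + 0.39 = 1.16 and b_local = 0.87 − 0.79 =
0.08.

Posterior predictive checking and model comparison:

```python
ps = g.posterior_predictive_marginals(fit, y, n_replicates=500, seed=1)
print(g.discordance_rate(ps))          # share of items outside their interval
fits = [fit] + [g.fit_model(y, q, cs, k, cfg=fit.config) for k in ("mltmd", "lltm")]
print(g.compare_models(fits, y).table[["model", "waic", "srmr", "discordance"]])
```

prints `0.0` (every observed item proportion inside its interval under the
true model) and

```
 model         waic     srmr  discordance
gmltmd 10473.184284 0.047416     0.000000
 mltmd 10899.931478 0.059392     0.407407
  lltm 11045.092667 0.064310     0.518519
```

— the generalized model ranks first on WAIC, SRMR and discordance, with
the misspecified MLTM-D and LLTM trailing, as expected on data carrying
varying discriminations and guessing.

The same pipeline runs from the shell:

```sh
gmltmd fixture --out data --seed 1
gmltmd fit --responses data/responses.csv --q-matrix data/q_matrix.csv \
           --assignment data/assignment.csv --model gmltmd --out out
gmltmd ppc --fit-dir out --responses data/responses.csv --out out/ppc.csv
```

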