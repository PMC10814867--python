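# ziber — zero-inflated Bernoulli regression for imbalanced binary outcomes

Binary outcomes in epidemiology, credit risk and rare-disease screening are
often dominated by zeros, and not all zeros are alike: some observations are
*structural* zeros that can never experience the event, while the rest are
ordinary Bernoulli draws that happened to come up zero. Pooling the two
sources biases a plain logistic regression and cripples classifiers built
on it. `ziber` models the two sources explicitly and fits the model by an
EM algorithm whose inner steps are nothing more exotic than weighted
logistic regressions.

## The model

For observation *i* with outcome `y_i ∈ {0, 1}`, event-model covariates
`x_i` (leading 1 for the intercept) and inflation covariates `z_i`:

```
logit(p_i)     = x_i' β        event probability in the Bernoulli component
logit(δ_i)     = z_i' θ        probability of being a structural zero
π_i            = (1 − δ_i) p_i  marginal event probability
y_i            ~ Bernoulli(π_i)
```

The observed-data log-likelihood is `Σ_i [y_i log π_i + (1−y_i) log(1−π_i)]`.
Introducing the latent structural-zero indicator `w_i` splits the
complete-data log-likelihood into two concave logistic terms, giving the EM
iteration:

* **E-step** — `w_i = 0` if `y_i = 1`, else
  `w_i = δ_i / (1 − p_i (1 − δ_i))` (the Bayes posterior of being a
  structural zero);
* **M-step** — update `θ` by a logistic regression of the fractional
  response `w` on `Z`, and `β` by a logistic regression of `y` on `X` with
  case weights `1 − w`; both solved by Newton–Raphson/IRLS.

The loop stops when every coefficient moves by less than `1e-5` between
iterations, or after 50 iterations (both configurable). For classification,
a cut point is chosen by a global grid search (step 0.01) minimising the
training misclassification rate; an observation is labelled positive when
its fitted probability is at or above the cut.

## Worked example

```python
from ziber import ZIBer, SimulationConfig, simulate_dataset

sim = simulate_dataset(SimulationConfig(n=5000, seed=42))
res = ZIBer.from_dataset(sim.data).fit()
res.find_cut()
print(res.summary())
```

```
Zero-Inflated Bernoulli Regression (EM)
==============================================
No. observations:     5000    converged: False
EM iterations:          50    log-likelihood: -782.1791
----------------------------------------------
Event model (logit p)         coef
  intercept                    -1.4657
  x2                            0.7020
  x3                           -1.6394
Zero-inflation model (logit delta)
  intercept                    -1.8771
  z2                            2.1605
----------------------------------------------
cut point: 0.67   train accuracy: 0.9572
train sensitivity: 0.0000   train specificity: 1.0000
==============================================
```

The sample was generated with β = (−1, 1, −2) and θ = (−1, 2); about 68% of
observations are structural zeros and only ~4% experience the event. After
the 50-iteration cap the coefficients are still drifting along the weakly
identified ridge between the two components (hence `converged: False`) —
the fitted marginal probabilities π̂ are nevertheless already stable. Pass
`EMControls(max_iter=3000, accelerate=True)` to `fit()` to run the
accelerated EM to full convergence, which recovers the generating
coefficients closely at large n. The training metrics show the imbalance
problem in miniature: at ~4% prevalence the error-minimising cut point
concedes the minority class almost entirely.

The same workflow is available from the shell:

```sh
ziber simulate --n 5000 --seed 42 --out sample.csv
ziber fit sample.csv --outcome y --x-cols x2,x3 --z-cols z2 --out model.json
ziber predict model.json sample.csv --out labels.csv
ziber study study.yaml --summary-out summary.json --records-out reps.csv
```

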