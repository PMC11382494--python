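# hetsynth

Synthetic clinical cohort data that preserves heterogeneity.

When a cohort table cannot be shared — data-protection rules, federated
analysis platforms, in-silico trial design — a generative model can stand in
for it. But clinical cohorts are heterogeneous: margins are skewed or
bimodal (unknown sub-groups such as disease severity), and known sub-groups
(study region, exposure arm) shift whole blocks of covariates. A vanilla
latent-Gaussian generator smooths all of that away.

`hetsynth` addresses both kinds of heterogeneity around a small mixed-type
variational autoencoder (VAE):

* **Unknown sub-groups — pre-transformations.** Each awkward continuous
  margin is mapped toward unimodal near-normality *before* training and
  mapped back after generation:
  * Box-Cox power transform `f(x) = ((x + λ₂)^λ₁ − 1)/λ₁` for skewness,
    with λ₁ fitted by gradient ascent on the profile log-likelihood
    `L(λ₁) = −(N/2)·log(σ² + ε) + (λ₁ − 1)·Σ log(xᵢ + λ₂ + ε)`;
  * a signed-power transform `f(x) = sgn(u)|u|^ρ`, `u = (x + α)/β²`,
    `ρ = 1 + pow² ≥ 1` for bimodality, fitted by minimizing a *1-sigma
    criterion* `|Q₀.₈₄ − Q₀.₅ − σ| + |Q₀.₅ − Q₀.₁₆ − σ|` (zero for a normal
    sample), with α initialized at the density valley found by a
    KDE bandwidth-ladder search;
  * an empirical-CDF → inverse-normal quantile transform as a
    non-parametric baseline (inverse clipped to the training range).
* **Mixed-type VAE.** Encoder and decoder are small tanh MLPs; the decoder
  trunk feeds Normal heads (μ_D, σ_D) for continuous columns and Bernoulli
  heads (π_D) for binary columns. The per-row loss is the exact sum of the
  two negative log-likelihoods plus the closed-form KL divergence
  `D_KL(q_φ(z|x) ‖ N(0, I))`. Early fusion (concatenated input) and late
  fusion (separate encoders per type, posteriors averaged) are supported.
* **Known sub-groups — propensity-weighted prior sampling.** A logistic
  regression on the original covariates (p-value variable selection at
  α = 0.05) estimates `p(g = 1 | x)`. The 2-D latent embedding is tiled
  into cells of side d; each cell gets the mean propensity p̄ of its member
  points and an IPTW-style weight — `1/p̄` or `1/(1 − p̄)` inside a δ-band
  around 0.5 for "overlap" sampling, or `1/p̄` below `0.5 + δ` for
  one-group sampling — normalized to `Σ w̄ = 1`. Prior draws are accepted
  with probability proportional to their cell weight and decoded.
* **Utility metrics.** The pMSE statistic `ψ = (1/N) Σ (ŷᵢ − c)²` from a
  CART real-vs-synthetic classifier (min leaf 20, max depth 25), its
  permutation null mean ψ̄ (100 permutations) and `ψ_ratio = ψ/ψ̄`, with a
  10-fold cross-validated harness. Ratios near 1 mean the classifier does
  no better on true labels than on shuffled ones — high-utility synthetic
  data.

## Worked example

```python
import hetsynth as hs

# a study-style simulated cohort: 2,500 rows, 21 variables (12 binary),
# skewed margins and one bimodal variable linked to the exposure E
# (N(0,1) for E=0, N(4,1) for E=1)
table = hs.generate_cohort(hs.paper_like_spec(n=2500, seed=7))

pipe = hs.TransformPipeline.fit(table, hs.default_assignment("paper"))
t01 = pipe.forward(table)
model = hs.train_vae(t01, hs.VAEConfig(epochs=150, seed=11), pipeline=pipe)
syn = hs.generate(model, 2500, seed=21)          # prior sampling + back-transform

v = hs.kde_valley_init(syn.data["x_bimodal"].to_numpy())
print("recovered modes:", [round(m, 2) for m in v.modes])

res = hs.evaluate(table.features(), syn.data[table.feature_columns],
                  hs.UtilityConfig(seed=5))
print(f"psi={res.psi:.4f}  psi_bar={res.psi_bar:.4f}  psi_ratio={res.psi_ratio:.2f}")
```

Output:

```
recovered modes: [0.13, 4.67]
psi=0.0610  psi_bar=0.0549  psi_ratio=1.11
```

The synthetic bimodal margin recovers both density modes near the true
component means 0 and 4 (the same VAE *without* pre-transformations
produces a unimodal margin), and ψ_ratio ≈ 1.1 says the CART classifier
barely distinguishes synthetic from original rows.

A command-line interface mirrors the library:

```bash
hetsynth simulate-fixture --preset two-region --seed 1 --output cohort.csv
hetsynth train --data cohort.csv --config cohort.yaml --seed 2 --output model.json
hetsynth propensity-sample --data cohort.csv --config cohort.yaml \
    --model model.json --n 2000 --delta 0.1 --seed 3 --output synthetic.csv
hetsynth visualize-latent --data cohort.csv --config cohort.yaml \
    --model model.json --output latent.png
```

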