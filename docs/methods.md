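# Methods

## Problem setting

A cohort table mixes continuous and binary variables. Heterogeneity enters
in two ways: *unknown* sub-group structure that is visible only in marginal
shapes (skewness, bimodality), and *known* sub-groups carried by a label
(region, exposure). The package generates synthetic rows from a latent-
Gaussian model while (a) reproducing awkward margins through invertible
pre-transformations and (b) controlling known sub-group content through
propensity-weighted sampling of the latent prior.

## Pre-transformations

Each continuous column is assigned one transform (`none`, `boxcox`,
`bimodal`, `quantile`); binary columns always pass through. After the
per-column transform, all continuous columns are min-max scaled to [0, 1]
(the scale the VAE trains on); the inverse un-scales and inverts in reverse
order. Decoder outputs outside [0, 1] are clipped before un-scaling (a
Gaussian decoder has unbounded support) and the clip count is logged.

### Box-Cox

Forward `((x+λ₂)^λ₁ − 1)/λ₁`, log branch for |λ₁| < 1e−4 (numerical
continuity at zero); inverse `(λ₁y + 1)^(1/λ₁) − λ₂`. The shift is fixed
deterministically before fitting: `λ₂ = max(0, −min x) + 1e−6·range(x)` —
reproducible and minimal. λ₁ maximizes the profile log-likelihood
`−(N/2)log(Var f(x) + ε) + (λ₁−1) Σ log(xᵢ+λ₂+ε)` with ε = 1e−8, by Adam
(lr 1e−2, cap 2000 iterations) on the analytic gradient from λ₁ = 1. On
seeded samples the fitted λ₁ agrees with a 0.001-step grid search of the
same objective to well under 0.05 (tested); note that for data with small
coefficient of variation the likelihood in λ₁ is genuinely flat, so the
*optimum* itself (not the optimizer) carries sampling noise there.

### Signed-power transform for bimodality

Forward `sgn(u)|u|^ρ` with `u = (x+α)/β²` and `ρ = 1 + pow²`; inverse
`β²·sgn(y)|y|^(1/ρ) − α` (signed root, real-valued for negative input).
The fitting criterion is the 1-sigma criterion
`|Q₀.₈₄ − Q₀.₅ − σ| + |Q₀.₅ − Q₀.₁₆ − σ|` with type-7 (linear
interpolation) quantiles and sd with ddof = 1, used consistently
everywhere. Three fitting decisions were genuinely open and are resolved
as follows:

* **Scale degeneracy.** The criterion is positively homogeneous of degree
  1, and the signed power is homogeneous in u, so β² is a pure output-scale
  convention: an optimizer can drive the raw criterion to zero by inflating
  β² without changing the distribution's shape (which is what the min-max
  stage sees). The optimizer therefore minimizes the scale-invariant form
  criterion(f)/sd(f); afterwards β² is set so the outermost density peak
  sits at |u| = 1/1.1 — strictly inside (−1, 1), the region the power
  compresses.
* **Stationary start.** `ρ = 1 + pow²` makes pow = 0 an exact stationary
  point (dρ/dpow = 0), so the search starts at pow = 0.1 (ρ = 1.01,
  near-identity); the improvement guard still compares against the pow = 0
  initialization and returns it (flagged) if the search cannot do better.
* **Optimizer.** The criterion is piecewise linear in the parameters
  through the sample quantiles, so a central-difference subgradient feeds
  Adam (lr 1e−2, cap 2000).

α is initialized at −valley so the density valley maps to 0 (the sign is a
convention; it is covered by a test on the exposure-linked 0/4 mixture).
The valley comes from a KDE bandwidth ladder: bandwidths grow geometrically
from 0.05·sd to 2·sd in 30 steps, the density is evaluated on a 512-point
grid, and the first bandwidth with at most five local maxima is inspected.
Peaks below 10% of the density maximum are ignored and the valley must dip
at least 10% below the lower of the two retained peaks — both guards keep
kernel ripples in the tails of a unimodal sample from masquerading as
modes. A sample that never shows a qualifying valley returns its median
with a `found=False` flag, and the transform assignment heuristic then
treats the column as unimodal.

### Quantile-normal baseline

Empirical CDF with plotting positions (i − 0.5)/n, interior-clipped to
avoid ±∞, then the standard-normal quantile. The inverse interpolates the
stored sorted training sample; inputs outside the training range are
clipped to it, counted and logged. This transform is deliberately kept as
a baseline: it reproduces margins well but memorizes the training sample's
order statistics, which is the wrong trade-off when disclosure risk
matters.

## Mixed-type VAE

Encoder and decoder are tanh MLPs with hidden widths (32, 16) and a 2-D
latent space by default — a deliberately small model, since a larger one
would memorize the cohort and defeat the privacy purpose of prior
sampling. The encoder emits a diagonal-Gaussian posterior (mean and
log-variance); the decoder trunk feeds three linear heads: μ_D (identity),
σ_D (softplus + 1e−4 floor, so σ_D > 0 always) and π_D (logistic, so
π_D ∈ (0, 1)). The per-row loss is exactly

    loss(x) = Σ_binary −log Bernoulli(x; π_D) + Σ_cont −log N(x; μ_D, σ_D)
              + D_KL(q(z|x) ‖ N(0, I)),

with the KL in closed form `½ Σ (μ² + σ² − log σ² − 1)`. Training is Adam
(lr 1e−3), batch size 64, 200 epochs by default, one reparameterization
sample per row per step; all of it config-exposed. With late fusion, two
encoders (continuous-only and binary-only) each emit posterior parameters
and both means and log-variances are averaged — the simplest symmetric
combination; the variance rule is an interpretation, since only "averaging
the latent space" is determined by the design. Everything is plain numpy
with hand-written backpropagation; gradients were cross-checked against
the loss primitives (the decomposition test) and training is bit-
reproducible per seed on a platform.

Generation defaults to prior sampling (privacy mode: training rows touch
the output only through the decoder weights); posterior sampling is
available behind a flag. A k-fold refit helper records train and heldout
reconstruction-loss traces to verify that heldout loss tracks training
without divergence.

## Propensity-weighted prior sampling

The propensity model is a two-stage logistic regression on the *original*
(untransformed) covariates: a full fit, retention of variables with Wald
p < 0.05, and a refit on the retained set. Complete separation or an
unstable ML fit falls back to an L2-penalized fit (flagged); if nothing
passes the cutoff an intercept-only model is returned with a warning.

The latent bounding box of the embedded training points is tiled with
square cells of side d (default: ~20 cells along the larger axis; the
box-tiling reading of the printed bin bounds is the standard half-open one,
since the literal bounds do not tile the range). Each cell's p̄ is the mean
propensity of its member points — the mean, not a sum over total n, since
an empty-cell "propensity" of zero would be an artifact; empty cells are
*undefined* and get weight 0, as do prior draws outside the box
(conservative: no evidence about group membership there). Overlap weights:
0 outside the δ-band around 0.5, else 1/p̄ above 0.5 and 1/(1−p̄) below,
2 at exactly 0.5 (continuity). One-group weights: 0 above 0.5 + δ, else
1/p̄ capped at 100 (bounded influence of near-empty extreme cells).
δ defaults to 0.1, with {0.05, 0.1, 0.2} the documented ladder — larger δ
admits individuals more typical of one group.

Acceptance uses probability w/max(w) rather than the normalized w̄
directly: the two are proportional, so the accepted latent distribution is
identical, but normalization over hundreds of cells would make literal
Bernoulli(w̄) acceptance impractically slow. The sampler aborts if the
acceptance rate after a 5,000-draw probe is below 1e−4 ("admissible region
too small; increase δ"). For latent dimension > 2 the grid lives on the
first two principal components of the embedded training points; prior
draws are projected with the same PCA.

## Utility metrics

ψ stacks original and synthetic tables with a membership label, fits a
CART classifier (Gini impurity; probability estimates are leaf class
proportions; min leaf 20, max depth 25) and averages (ŷ − c)². The
permutation null shuffles labels only (rows fixed), 100 times from a
seeded stream, giving ψ̄ and ψ_ratio = ψ/ψ̄. The cross-validation harness
uses 10 folds; per fold the generator is refitted on the training part and
the synthetic sample matches the heldout size, keeping c = 0.5. Classifier
features exclude group-label and outcome columns by default — utility here
measures covariate fidelity. The fold summary reports both the mean of the
per-fold permutation means ψ̄ and the fold-mean of ψ, since the two are
easy to conflate.

## Synthetic cohort generators

`paper_like_spec` emulates a breast-cancer-style simulated cohort: n =
2,500; 21 variables of which 12 are binary (exposure and outcome
included); an imbalanced exposure E with prevalence 0.3 (chosen once as a
realistic imbalance; it makes the bimodal margin asymmetric); four
lognormal columns with |sample skewness| > 1 at n = 2,500; one bimodal
column drawn as N(0, 1) for E = 0 and N(4, 1) for E = 1 — modes close
enough to overlap; binary covariates with exposure-linked log-odds shifts;
and a logistic outcome on exposure and selected covariates.
`TwoRegionSpec` emulates a two-region stroke-trial table: age mean-shifted
by 8 years between regions, blood pressure identically distributed, a
bimodal admission-delay variable, and region-dependent binary rates.

What the generators do *not* emulate: the dependence structure of any
particular published simulation design, measurement error, missingness
patterns, or heavy-tailed outliers. Passing tests therefore demonstrate
that the machinery behaves as specified under the stated shape features —
skewness, exposure-linked bimodality, region shifts — not that it handles
every real cohort.

## Problem sizes and numerical choices

Tests and the acceptance script run at the design's native scale (n =
2,500 cohorts, 2,668 for the two-region table) with 150 training epochs
for headline runs and 10–40 epochs for smoke paths; the numpy model trains
in seconds at this size. Round-trip tolerances are 1e−6 (1e−8 achieved);
sgn(0) = 0 throughout; Bernoulli probabilities are clamped to
[1e−7, 1 − 1e−7] at the likelihood; Box-Cox inverse offers a clip-or-fail
policy for out-of-support decoder output (generation clips and logs).
Fitted pipelines and models serialize to a version-stamped JSON archive
(text, endianness-safe); loading a mismatched version fails explicitly.

## Known limitations

Only two-mode bimodality is handled (no ≥3-mode transform) and only the
Box-Cox power family (no Yeo-Johnson). The propensity model is not
optimized beyond p-value selection. There is no formal disclosure-risk
quantification; prior sampling plus a small model is a heuristic privacy
argument, not a guarantee. ψ-based utility depends on the CART
hyperparameters; the defaults follow the evaluation design and are
config-exposed.
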