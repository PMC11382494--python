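"""Mixed-type variational autoencoder for tabular cohort data.

Encoder and decoder are small multi-layer perceptrons (each layer a linear
map followed by a tanh activation).  The encoder emits a diagonal-Gaussian
posterior ``q(z|x) = N(mu, diag(sigma^2))`` over a low-dimensional latent
``z`` with a standard-normal prior.  The decoder shares a trunk whose last
hidden layer feeds three heads:

* ``mu_D`` and ``sigma_D`` — per-column Normal parameters for the
  (pipeline-transformed, [0,1]-scaled) continuous variables,
* ``pi_D`` — per-column Bernoulli probabilities for the binary variables.

The per-row training loss is the negative Bernoulli log-likelihood summed
over binary columns, plus the negative Normal log-likelihood summed over
continuous columns, plus the closed-form KL divergence between the
posterior and the prior.  Optimization is stochastic gradient descent
(Adam) with one reparameterization sample per row per step.  Both *early
fusion* (binary and continuous concatenated into one encoder) and *late
fusion* (two encoders whose posterior parameters are averaged) are
supported.

Everything is plain numpy with explicit backpropagation: the model is tiny
by design — a deliberately simple architecture with a 2-D latent space to
avoid overfitting (and hence memorization) of the training cohort.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CohortTable
from .pretransforms import TransformPipeline

logger = logging.getLogger(__name__)

LOG_2PI = math.log(2.0 * math.pi)
PROB_FLOOR = 1e-7  # clamp for Bernoulli probabilities at the likelihood


# ---------------------------------------------------------------------------
# Loss building blocks
# ---------------------------------------------------------------------------

def kl_diag_gaussian(mu: np.ndarray, logvar: np.ndarray) -> float | np.ndarray:
    """Closed-form KL( N(mu, diag(exp(logvar))) || N(0, I) ).

    For 2-D input (rows = observations) returns one value per row.
    """
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    per_dim = 0.5 * (mu ** 2 + np.exp(logvar) - logvar - 1.0)
    kl = per_dim.sum(axis=-1)
    return float(kl) if kl.ndim == 0 else kl


def reconstruction_loss(x_cont: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                        x_bin: np.ndarray, pi: np.ndarray) -> float | np.ndarray:
    """Negative log-density of a row under the mixed Normal/Bernoulli decoder.

    Bernoulli probabilities exactly 0 or 1 are clamped to
    ``[PROB_FLOOR, 1 - PROB_FLOOR]`` (and the clamp logged) so a mismatching
    observation yields a large finite penalty rather than infinity.
    """
    x_cont = np.atleast_1d(np.asarray(x_cont, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    x_bin = np.atleast_1d(np.asarray(x_bin, dtype=float))
    pi = np.atleast_1d(np.asarray(pi, dtype=float))
    if np.any(sigma <= 0):
        raise ValueError("sigma_D must be strictly positive")
    n_clamped = int(np.sum((pi <= 0) | (pi >= 1)))
    if n_clamped:
        logger.info("clamped %d Bernoulli probability(ies) away from {0,1}", n_clamped)
    pi = np.clip(pi, PROB_FLOOR, 1.0 - PROB_FLOOR)
    normal_nll = 0.5 * LOG_2PI + np.log(sigma) + (x_cont - mu) ** 2 / (2.0 * sigma ** 2)
    bern_nll = -(x_bin * np.log(pi) + (1.0 - x_bin) * np.log(1.0 - pi))
    total = normal_nll.sum(axis=-1) + bern_nll.sum(axis=-1)
    return float(total) if total.ndim == 0 else total


# ---------------------------------------------------------------------------
# MLP plumbing
# ---------------------------------------------------------------------------

def _init_linear(rng: np.random.Generator, n_in: int, n_out: int) -> list[np.ndarray]:
    limit = math.sqrt(6.0 / (n_in + n_out))
    W = rng.uniform(-limit, limit, size=(n_in, n_out))
    b = np.zeros(n_out)
    return [W, b]


class _Trunk:
    """Stack of tanh layers with cached activations for backprop."""

    def __init__(self, rng: np.random.Generator, n_in: int, widths: Sequence[int]):
        self.layers = []
        prev = n_in
        for w in widths:
            self.layers.append(_init_linear(rng, prev, w))
            prev = w
        self.n_out = prev

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer]

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        h = x
        cache = [x]
        for W, b in self.layers:
            h = np.tanh(h @ W + b)
            cache.append(h)
        return h, cache

    def backward(self, dh: np.ndarray, cache: list[np.ndarray]
                 ) -> tuple[np.ndarray, list[np.ndarray]]:
        grads: list[np.ndarray] = []
        for i in range(len(self.layers) - 1, -1, -1):
            W, _ = self.layers[i]
            h_out, h_in = cache[i + 1], cache[i]
            da = dh * (1.0 - h_out ** 2)
            grads.append(da.sum(axis=0))        # db
            grads.append(h_in.T @ da)           # dW
            dh = da @ W.T
        grads.reverse()
        return dh, grads


class _Head:
    """Single linear output layer."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W, self.b = _init_linear(rng, n_in, n_out)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def forward(self, h: np.ndarray) -> np.ndarray:
        return h @ self.W + self.b

    def backward(self, dout: np.ndarray, h: np.ndarray
                 ) -> tuple[np.ndarray, list[np.ndarray]]:
        return dout @ self.W.T, [h.T @ dout, dout.sum(axis=0)]


class _Encoder:
    def __init__(self, rng: np.random.Generator, n_in: int, widths: Sequence[int],
                 latent_dim: int):
        self.trunk = _Trunk(rng, n_in, widths)
        self.head_mu = _Head(rng, self.trunk.n_out, latent_dim)
        self.head_lv = _Head(rng, self.trunk.n_out, latent_dim)

    @property
    def params(self) -> list[np.ndarray]:
        return self.trunk.params + self.head_mu.params + self.head_lv.params

    def forward(self, x: np.ndarray):
        h, cache = self.trunk.forward(x)
        return self.head_mu.forward(h), self.head_lv.forward(h), (h, cache)

    def backward(self, dmu: np.ndarray, dlv: np.ndarray, ctx) -> list[np.ndarray]:
        h, cache = ctx
        dh1, g_mu = self.head_mu.backward(dmu, h)
        dh2, g_lv = self.head_lv.backward(dlv, h)
        _, g_trunk = self.trunk.backward(dh1 + dh2, cache)
        return g_trunk + g_mu + g_lv


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


# ---------------------------------------------------------------------------
# Configuration and model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VAEConfig:
    """Training configuration; every field is exposed to the config file."""
    latent_dim: int = 2
    hidden: tuple[int, ...] = (32, 16)
    fusion: str = "early"
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    sigma_floor: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if any(w <= 0 for w in self.hidden):
            raise ValueError("hidden widths must be positive")
        if self.fusion not in ("early", "late"):
            raise ValueError("fusion must be 'early' or 'late'")
        self.hidden = tuple(self.hidden)


class TrainedVAE:
    """A trained mixed-type VAE plus bookkeeping.

    Attributes of note: ``loss_trace`` (per-epoch mean total loss),
    ``recon_trace`` (per-epoch mean reconstruction loss), ``pipeline`` (an
    optionally attached :class:`TransformPipeline` used to back-transform
    generated rows).
    """

    def __init__(self, config: VAEConfig, cont_cols: list[str], bin_cols: list[str]):
        self.config = config
        self.cont_cols = cont_cols
        self.bin_cols = bin_cols
        self.pipeline: TransformPipeline | None = None
        self.loss_trace: list[float] = []
        self.recon_trace: list[float] = []
        rng = np.random.default_rng(config.seed)
        pc, pb = len(cont_cols), len(bin_cols)
        dec_widths = tuple(reversed(config.hidden))
        if config.fusion == "early":
            self.enc = _Encoder(rng, pc + pb, config.hidden, config.latent_dim)
            self.enc_b = None
        else:
            self.enc = _Encoder(rng, pc, config.hidden, config.latent_dim)
            self.enc_b = _Encoder(rng, pb, config.hidden, config.latent_dim)
        self.dec_trunk = _Trunk(rng, config.latent_dim, dec_widths)
        self.head_mu = _Head(rng, self.dec_trunk.n_out, pc)
        self.head_sr = _Head(rng, self.dec_trunk.n_out, pc)
        self.head_pi = _Head(rng, self.dec_trunk.n_out, pb)

    # -- parameter access ---------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        ps = self.enc.params
        if self.enc_b is not None:
            ps = ps + self.enc_b.params
        return ps + self.dec_trunk.params + self.head_mu.params \
            + self.head_sr.params + self.head_pi.params

    # -- encoder ------------------------------------------------------------
    def _posterior(self, xc: np.ndarray, xb: np.ndarray):
        if self.enc_b is None:
            mu, lv, ctx = self.enc.forward(np.hstack([xc, xb]))
            return mu, lv, (ctx, None)
        mu_c, lv_c, ctx_c = self.enc.forward(xc)
        mu_b, lv_b, ctx_b = self.enc_b.forward(xb)
        # late fusion: average the two posteriors' parameters
        return 0.5 * (mu_c + mu_b), 0.5 * (lv_c + lv_b), (ctx_c, ctx_b)

    def _posterior_backward(self, dmu, dlv, ctx) -> list[np.ndarray]:
        ctx_c, ctx_b = ctx
        if self.enc_b is None:
            return self.enc.backward(dmu, dlv, ctx_c)
        g_c = self.enc.backward(0.5 * dmu, 0.5 * dlv, ctx_c)
        g_b = self.enc_b.backward(0.5 * dmu, 0.5 * dlv, ctx_b)
        return g_c + g_b

    # -- decoder ------------------------------------------------------------
    def _decode_raw(self, z: np.ndarray):
        h, cache = self.dec_trunk.forward(z)
        mu = self.head_mu.forward(h)
        sraw = self.head_sr.forward(h)
        sigma = _softplus(sraw) + self.config.sigma_floor
        logits = self.head_pi.forward(h)
        return mu, sigma, sraw, logits, (h, cache)

    def decoder_outputs(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mu_D, sigma_D, pi_D) for latent points ``z``."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.config.latent_dim:
            raise ValueError(f"z must have {self.config.latent_dim} columns")
        mu, sigma, _, logits, _ = self._decode_raw(z)
        return mu, sigma, _sigmoid(logits)

    # -- serialization ------------------------------------------------------
    def state(self) -> dict:
        return {
            "config": dataclasses.asdict(self.config),
            "cont_cols": self.cont_cols,
            "bin_cols": self.bin_cols,
            "weights": [p.copy() for p in self.params],
            "loss_trace": list(self.loss_trace),
            "recon_trace": list(self.recon_trace),
            "pipeline": self.pipeline.state() if self.pipeline is not None else None,
        }

    @classmethod
    def from_state(cls, state: dict) -> "TrainedVAE":
        cfg = VAEConfig(**{**state["config"],
                           "hidden": tuple(state["config"]["hidden"])})
        model = cls(cfg, list(state["cont_cols"]), list(state["bin_cols"]))
        for p, w in zip(model.params, state["weights"]):
            p[...] = np.asarray(w, dtype=float)
        model.loss_trace = [float(v) for v in state["loss_trace"]]
        model.recon_trace = [float(v) for v in state["recon_trace"]]
        if state.get("pipeline") is not None:
            model.pipeline = TransformPipeline.from_state(state["pipeline"])
        return model


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _split_features(table01: CohortTable, cont_cols, bin_cols):
    xc = table01.data[cont_cols].to_numpy(dtype=float)
    xb = table01.data[bin_cols].to_numpy(dtype=float)
    return xc, xb


def _batch_loss_and_grads(model: TrainedVAE, xc: np.ndarray, xb: np.ndarray,
                          eps: np.ndarray) -> tuple[float, float, list[np.ndarray]]:
    """Mean per-row loss on a batch and gradients w.r.t. all parameters."""
    B = xc.shape[0]
    mu_q, lv_q, enc_ctx = model._posterior(xc, xb)
    std = np.exp(0.5 * lv_q)
    z = mu_q + eps * std

    mu_d, sigma, sraw, logits, dec_ctx = model._decode_raw(z)
    pi = _sigmoid(logits)

    # losses (mean over batch)
    normal_nll = 0.5 * LOG_2PI + np.log(sigma) + (xc - mu_d) ** 2 / (2 * sigma ** 2)
    bern_nll = np.maximum(logits, 0) - logits * xb + np.log1p(np.exp(-np.abs(logits)))
    kl = 0.5 * (mu_q ** 2 + np.exp(lv_q) - lv_q - 1.0)
    recon = float(normal_nll.sum() + bern_nll.sum()) / B
    loss = recon + float(kl.sum()) / B

    # --- backward ---
    dmu_d = (mu_d - xc) / sigma ** 2 / B
    dsigma = (1.0 / sigma - (xc - mu_d) ** 2 / sigma ** 3) / B
    dsraw = dsigma * _sigmoid(sraw)
    dlogits = (pi - xb) / B

    h, cache = dec_ctx
    dh1, g_mu = model.head_mu.backward(dmu_d, h)
    dh2, g_sr = model.head_sr.backward(dsraw, h)
    dh3, g_pi = model.head_pi.backward(dlogits, h)
    dz, g_dec = model.dec_trunk.backward(dh1 + dh2 + dh3, cache)

    dmu_q = dz + mu_q / B
    dlv_q = dz * eps * 0.5 * std + 0.5 * (np.exp(lv_q) - 1.0) / B
    g_enc = model._posterior_backward(dmu_q, dlv_q, enc_ctx)

    return loss, recon, g_enc + g_dec + g_mu + g_sr + g_pi


def train_vae(table01: CohortTable, config: VAEConfig,
              pipeline: TransformPipeline | None = None,
              heldout01: CohortTable | None = None) -> TrainedVAE:
    """Train the mixed-type VAE on a pipeline-transformed table.

    ``table01`` must already have continuous columns in [0, 1] and no
    missing values.  With ``heldout01`` given, the heldout reconstruction
    loss is evaluated each epoch and stored as ``model.heldout_recon_trace``.
    Training is fully deterministic given ``config.seed``.
    """
    cont_cols = table01.continuous_columns
    bin_cols = table01.binary_columns
    xc, xb = _split_features(table01, cont_cols, bin_cols)
    if np.any(~np.isfinite(xc)) or np.any(~np.isfinite(xb)):
        raise ValueError("training table contains non-finite values")

    model = TrainedVAE(config, cont_cols, bin_cols)
    model.pipeline = pipeline
    opt = _Adam(model.params, config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = xc.shape[0]
    model.heldout_recon_trace = []

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_recon = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            eps = rng.standard_normal((len(idx), config.latent_dim))
            loss, recon, grads = _batch_loss_and_grads(model, xc[idx], xb[idx], eps)
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}")
            opt.step(grads)
            epoch_loss += loss
            epoch_recon += recon
            n_batches += 1
        model.loss_trace.append(epoch_loss / n_batches)
        model.recon_trace.append(epoch_recon / n_batches)
        if heldout01 is not None:
            model.heldout_recon_trace.append(
                evaluate_reconstruction(model, heldout01))
    return model


def evaluate_reconstruction(model: TrainedVAE, table01: CohortTable) -> float:
    """Mean per-row reconstruction loss at the posterior mean (no noise)."""
    xc, xb = _split_features(table01, model.cont_cols, model.bin_cols)
    mu_q, _, _ = model._posterior(xc, xb)
    mu_d, sigma, pi = model.decoder_outputs(mu_q)
    losses = reconstruction_loss(xc, mu_d, sigma, xb, pi)
    return float(np.mean(losses))


def crossval_reconstruction(table01: CohortTable, config: VAEConfig,
                            k: int = 10, seed: int = 0) -> dict:
    """k-fold refit recording train and heldout reconstruction traces.

    Returns per-fold traces plus their across-fold mean and standard
    deviation per epoch — the robustness diagnostic showing that heldout
    reconstruction tracks training without divergence.
    """
    from sklearn.model_selection import KFold

    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    train_traces, heldout_traces = [], []
    for fold, (tr, te) in enumerate(kf.split(np.arange(table01.n_rows))):
        cfg = dataclasses.replace(config, seed=config.seed + fold)
        model = train_vae(table01.subset(tr), cfg, heldout01=table01.subset(te))
        train_traces.append(model.recon_trace)
        heldout_traces.append(model.heldout_recon_trace)
    tt = np.asarray(train_traces)
    ht = np.asarray(heldout_traces)
    return {
        "train_traces": tt, "heldout_traces": ht,
        "train_mean": tt.mean(axis=0), "train_sd": tt.std(axis=0),
        "heldout_mean": ht.mean(axis=0), "heldout_sd": ht.std(axis=0),
    }


# ---------------------------------------------------------------------------
# Encoding / sampling / generation
# ---------------------------------------------------------------------------

def encode(model: TrainedVAE, table01: CohortTable) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic posterior means and log-variances, one row per input."""
    xc, xb = _split_features(table01, model.cont_cols, model.bin_cols)
    mu, lv, _ = model._posterior(xc, xb)
    return mu, lv


def sample_posterior(model: TrainedVAE, table01: CohortTable, seed: int,
                     noise_scale: float = 1.0) -> np.ndarray:
    """Reparameterized posterior samples; ``noise_scale=0`` gives the means."""
    mu, lv = encode(model, table01)
    rng = np.random.default_rng(seed)
    return mu + noise_scale * rng.standard_normal(mu.shape) * np.exp(0.5 * lv)


def sample_prior(n: int, latent_dim: int, seed: int) -> np.ndarray:
    """i.i.d. standard-normal latent points, shape (n, latent_dim)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, latent_dim))


def decode_and_sample(model: TrainedVAE, z: np.ndarray, seed: int,
                      noiseless: bool = False) -> CohortTable:
    """Decode latent points into a synthetic (still-transformed) table.

    Continuous columns are drawn from the per-row Normal heads and binary
    columns from the Bernoulli heads.  With ``noiseless=True`` the decoder
    means ``mu_D`` and probabilities ``pi_D`` are returned directly as a
    plain DataFrame (the binary columns then hold probabilities, not draws).
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    mu, sigma, pi = model.decoder_outputs(z)
    if noiseless:
        return pd.DataFrame(np.hstack([mu, pi]),
                            columns=model.cont_cols + model.bin_cols)
    rng = np.random.default_rng(seed)
    xc = rng.normal(mu, sigma)
    xb = (rng.uniform(size=pi.shape) < pi).astype(float)
    df = pd.DataFrame(np.hstack([xc, xb]), columns=model.cont_cols + model.bin_cols)
    df[model.bin_cols] = df[model.bin_cols].astype(int)
    roles = {c: "continuous" for c in model.cont_cols}
    roles.update({c: "binary" for c in model.bin_cols})
    return CohortTable(df, roles)


def generate(model: TrainedVAE, n: int, seed: int, mode: str = "prior",
             table01: CohortTable | None = None) -> CohortTable:
    """Generate ``n`` synthetic rows on the original data scale.

    ``mode='prior'`` (default, the privacy-preserving route) samples latent
    points from N(0, I); ``mode='posterior'`` samples the posterior of the
    provided ``table01`` rows.  The attached pipeline back-transforms the
    decoded output.
    """
    if model.pipeline is None:
        raise ValueError("model has no attached TransformPipeline")
    if mode == "prior":
        z = sample_prior(n, model.config.latent_dim, seed)
    elif mode == "posterior":
        if table01 is None:
            raise ValueError("posterior mode needs the source table")
        z = sample_posterior(model, table01, seed)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
        z = z[rng.choice(len(z), size=n, replace=n > len(z))]
    else:
        raise ValueError("mode must be 'prior' or 'posterior'")
    table01_syn = decode_and_sample(model, z, seed=seed + 1)
    return model.pipeline.inverse(table01_syn)
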