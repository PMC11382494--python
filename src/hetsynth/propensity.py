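"""Propensity-score-guided weighted sampling from the latent prior.

Known sub-group structure (e.g. study region or exposure cohort) is handled
outside the generative model: a logistic regression on the *original*
covariates estimates the propensity ``p(g=1 | x)`` of belonging to sub-group
one.  The 2-D latent embedding of the training data is tiled into a grid of
square cells of side ``d``; each cell gets the mean propensity of its member
points, an inverse-probability weight targeting a sampling scenario
("overlap": individuals common to both sub-groups; "group": individuals
characteristic of group g=0), and a normalized weight.  Synthetic data is
then produced by rejection sampling the standard-normal prior — a latent
draw is accepted with probability proportional to its cell weight — and
decoding the accepted points.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .io import CohortTable
from .vae import TrainedVAE, decode_and_sample, encode

logger = logging.getLogger(__name__)

OUTSIDE = -1  # sentinel cell index for points beyond the training bounds
GROUP_WEIGHT_CAP = 100.0  # bound on 1/p_bar for near-zero cell propensities


# ---------------------------------------------------------------------------
# Propensity model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PropensityModel:
    """Two-stage logistic propensity model with p-value variable selection."""
    selected: list[str]
    coef: np.ndarray           # intercept first, then selected-variable coefs
    pvalues: dict[str, float]  # selection-stage p-values of all candidates
    alpha: float
    penalized: bool = False
    intercept_only: bool = False

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.selected].to_numpy(dtype=float) if self.selected else \
            np.empty((len(df), 0))
        eta = self.coef[0] + X @ self.coef[1:]
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        return np.clip(p, 1e-7, 1 - 1e-7)


def _sm_logit(y: np.ndarray, X: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(disp=0)


def fit_propensity(table: CohortTable, group: np.ndarray | str | None = None,
                   alpha: float = 0.05,
                   candidates: Sequence[str] | None = None) -> PropensityModel:
    """Fit the sub-group membership model p(g=1 | x) on original covariates.

    Stage 1 fits a full logistic regression of the group label on all
    candidate covariates and retains those with Wald p-value < ``alpha``;
    stage 2 refits on the retained set.  Complete separation (or any
    maximum-likelihood failure) falls back to an L2-penalized fit with all
    candidates retained, flagged on the result.  If no variable passes the
    cutoff, an intercept-only model is returned with a warning.
    """
    if group is None:
        group = table.group_column
        if group is None:
            raise ValueError("table has no group column and none was given")
    if isinstance(group, str):
        y = table.data[group].to_numpy(dtype=float)
    else:
        y = np.asarray(group, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("group labels must be binary with both classes present")

    cols = list(candidates) if candidates is not None else table.feature_columns
    X = table.data[cols].to_numpy(dtype=float)

    penalized = False
    try:
        full = _sm_logit(y, X)
        if not full.mle_retvals.get("converged", True) or \
                np.any(~np.isfinite(full.bse)):
            raise np.linalg.LinAlgError("unstable full fit")
        pvals = {c: float(p) for c, p in zip(cols, full.pvalues[1:])}
    except Exception as exc:  # separation / singularity
        logger.warning("full logistic fit failed (%s); penalized fallback", exc)
        penalized = True
        pvals = {c: float("nan") for c in cols}

    if penalized:
        clf = LogisticRegression(penalty="l2", C=1.0, max_iter=1000)
        clf.fit(X, y)
        coef = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        return PropensityModel(cols, coef, pvals, alpha, penalized=True)

    selected = [c for c in cols if pvals[c] < alpha]
    if not selected:
        logger.warning("no variable passed p < %.3g; intercept-only model", alpha)
        p1 = float(np.mean(y))
        coef = np.array([np.log(p1 / (1 - p1))])
        return PropensityModel([], coef, pvals, alpha, intercept_only=True)

    Xs = table.data[selected].to_numpy(dtype=float)
    try:
        refit = _sm_logit(y, Xs)
        if not refit.mle_retvals.get("converged", True):
            raise np.linalg.LinAlgError("unstable refit")
        coef = np.asarray(refit.params, dtype=float)
    except Exception as exc:
        logger.warning("refit failed (%s); penalized fallback on selected", exc)
        clf = LogisticRegression(penalty="l2", C=1.0, max_iter=1000)
        clf.fit(Xs, y)
        coef = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        penalized = True
    return PropensityModel(selected, coef, pvals, alpha, penalized=penalized)


# ---------------------------------------------------------------------------
# Latent grid
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GridSpec:
    """Square tiling of the 2-D latent bounding box with cell side ``d``."""
    d: float
    mins: np.ndarray  # shape (2,)
    maxs: np.ndarray  # shape (2,)

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if self.d <= 0:
            raise ValueError("cell size d must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        n = np.ceil((self.maxs - self.mins) / self.d).astype(int)
        return int(max(n[0], 1)), int(max(n[1], 1))


def grid_from_points(z: np.ndarray, d: float | None = None,
                     resolution: int = 20) -> GridSpec:
    """Bounding-box grid over embedded points; default d gives ~resolution
    cells along the larger axis."""
    z = np.asarray(z, dtype=float)
    mins, maxs = z.min(axis=0), z.max(axis=0)
    if d is None:
        d = float(np.max(maxs - mins)) / resolution
    return GridSpec(float(d), mins, maxs)


def assign_cells(z: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Half-open binning of 2-D points into (i, j) cell indices (0-based).

    Points exactly on the upper bound map into the last cell; points outside
    the bounding box get the sentinel index ``OUTSIDE`` in both coordinates.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    n1, n2 = spec.shape
    idx = np.floor((z - spec.mins) / spec.d).astype(int)
    idx[:, 0] = np.minimum(idx[:, 0], n1 - 1)
    idx[:, 1] = np.minimum(idx[:, 1], n2 - 1)
    outside = np.any((z < spec.mins) | (z > spec.maxs), axis=1)
    idx[outside] = OUTSIDE
    return idx


def average_ps_per_cell(cells: np.ndarray, ps: np.ndarray, spec: GridSpec
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell mean propensity of member points.

    Returns ``(p_bar, counts)`` arrays of the grid shape; empty cells hold
    NaN in ``p_bar`` (undefined, distinct from a propensity of 0).
    """
    ps = np.asarray(ps, dtype=float)
    if np.any((ps <= 0) | (ps >= 1)):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    n1, n2 = spec.shape
    counts = np.zeros((n1, n2))
    sums = np.zeros((n1, n2))
    inside = cells[:, 0] != OUTSIDE
    np.add.at(counts, (cells[inside, 0], cells[inside, 1]), 1.0)
    np.add.at(sums, (cells[inside, 0], cells[inside, 1]), ps[inside])
    with np.errstate(invalid="ignore"):
        p_bar = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return p_bar, counts


def overlap_weights(p_bar: np.ndarray, delta: float) -> np.ndarray:
    """IPTW-style weights favoring cells common to both sub-groups.

    w = 0 where |p_bar - 0.5| > delta, 1/p_bar where p_bar > 0.5,
    1/(1 - p_bar) where p_bar < 0.5 and 2 at exactly 0.5 (continuity).
    Empty (undefined) cells get 0.
    """
    if not 0 < delta < 0.5:
        raise ValueError("delta must lie in (0, 0.5)")
    p = np.asarray(p_bar, dtype=float)
    w = np.zeros_like(p)
    defined = np.isfinite(p)
    band = defined & (np.abs(p - 0.5) <= delta)
    hi = band & (p > 0.5)
    lo = band & (p < 0.5)
    mid = band & (p == 0.5)
    w[hi] = 1.0 / p[hi]
    w[lo] = 1.0 / (1.0 - p[lo])
    w[mid] = 2.0
    return w


def group_weights(p_bar: np.ndarray, delta: float,
                  cap: float = GROUP_WEIGHT_CAP) -> np.ndarray:
    """Weights favoring cells characteristic of sub-group g=0.

    w = 0 where p_bar > 0.5 + delta, else 1/p_bar (capped at ``cap`` for
    near-zero cell propensities); undefined cells get 0.
    """
    if not 0 < delta < 0.5:
        raise ValueError("delta must lie in (0, 0.5)")
    p = np.asarray(p_bar, dtype=float)
    w = np.zeros_like(p)
    keep = np.isfinite(p) & (p <= 0.5 + delta)
    w[keep] = np.minimum(1.0 / np.maximum(p[keep], 1.0 / cap), cap)
    return w


def normalize_weights(w: np.ndarray) -> np.ndarray:
    """Normalize cell weights to sum to one."""
    w = np.asarray(w, dtype=float)
    total = float(w.sum())
    if total <= 0:
        raise ValueError("no admissible region; increase delta")
    return w / total


@dataclasses.dataclass
class LatentGrid:
    """A fitted latent grid: tiling, counts, propensities and weights."""
    spec: GridSpec
    counts: np.ndarray
    p_bar: np.ndarray
    w: np.ndarray
    w_bar: np.ndarray
    mode: str
    delta: float
    pca: PCA | None = None  # set when latent_dim > 2

    @property
    def accept_prob(self) -> np.ndarray:
        """Per-cell acceptance probability w / max(w) (max acceptance rate;
        same target distribution as Bernoulli(w_bar) up to a constant)."""
        return self.w / self.w.max()


def build_latent_grid(model: TrainedVAE, table01: CohortTable,
                      propensity: np.ndarray, mode: str = "overlap",
                      delta: float = 0.1, d: float | None = None,
                      resolution: int = 20) -> LatentGrid:
    """Embed the training table, tile the latent plane and compute weights.

    For latent dimension > 2 the grid lives on the first two principal
    components of the embedded training points; the fitted PCA projects
    prior draws during sampling.
    """
    if mode not in ("overlap", "group"):
        raise ValueError("mode must be 'overlap' or 'group'")
    mu, _ = encode(model, table01)
    pca = None
    if mu.shape[1] > 2:
        pca = PCA(n_components=2, random_state=0).fit(mu)
        mu = pca.transform(mu)
    spec = grid_from_points(mu, d=d, resolution=resolution)
    cells = assign_cells(mu, spec)
    p_bar, counts = average_ps_per_cell(cells, propensity, spec)
    w = overlap_weights(p_bar, delta) if mode == "overlap" else \
        group_weights(p_bar, delta)
    w_bar = normalize_weights(w)
    return LatentGrid(spec, counts, p_bar, w, w_bar, mode, delta, pca)


# ---------------------------------------------------------------------------
# Weighted rejection sampling of the prior
# ---------------------------------------------------------------------------

def weighted_prior_sampling(model: TrainedVAE, grid: LatentGrid, n_target: int,
                            seed: int, acceptance_floor: float = 1e-4,
                            probe: int = 5000, max_batches: int = 10_000,
                            return_latent: bool = False):
    """Rejection-sample the prior through the weighted grid and decode.

    Latent draws outside the grid or in zero-weight cells are rejected;
    draws in cell (i, j) are accepted with probability w_ij / max(w).  The
    loop aborts if, after a probe batch, the running acceptance rate falls
    below ``acceptance_floor``.  Accepted points are decoded, sampled from
    the decoder heads and back-transformed by the attached pipeline.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    rng = np.random.default_rng(seed)
    accept_p = grid.accept_prob
    accepted: list[np.ndarray] = []
    n_drawn = n_acc = 0
    batch = max(1024, n_target)
    for _ in range(max_batches):
        z = rng.standard_normal((batch, model.config.latent_dim))
        z2 = grid.pca.transform(z) if grid.pca is not None else z
        cells = assign_cells(z2, grid.spec)
        inside = cells[:, 0] != OUTSIDE
        p = np.zeros(len(z))
        p[inside] = accept_p[cells[inside, 0], cells[inside, 1]]
        keep = rng.uniform(size=len(z)) < p
        accepted.append(z[keep])
        n_drawn += len(z)
        n_acc += int(keep.sum())
        if n_drawn >= probe and n_acc / n_drawn < acceptance_floor:
            raise RuntimeError(
                f"admissible region too small (acceptance {n_acc / n_drawn:.2e})")
        if n_acc >= n_target:
            break
    else:
        raise RuntimeError("weighted sampling failed to reach n_target")
    z_acc = np.vstack(accepted)[:n_target]
    rate = n_acc / n_drawn
    logger.info("weighted prior sampling acceptance rate %.4f", rate)
    table01 = decode_and_sample(model, z_acc, seed=seed + 1)
    out = model.pipeline.inverse(table01) if model.pipeline is not None else table01
    if return_latent:
        return out, z_acc, rate
    return out, rate


# ---------------------------------------------------------------------------
# Visualization
# ---------------------------------------------------------------------------

def latent_heatmap(model: TrainedVAE, table01: CohortTable, group: np.ndarray,
                   grid: LatentGrid, output: str, shade: str = "p_bar") -> None:
    """Scatter of the latent embedding colored by sub-group over a cell map.

    ``shade`` selects the cell background: the averaged propensity
    ``p_bar`` or the normalized weights ``w_bar`` (zero-weight cells are
    hatched grey in the weight variant).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mu, _ = encode(model, table01)
    if grid.pca is not None:
        mu = grid.pca.transform(mu)
    n1, n2 = grid.spec.shape
    x_edges = grid.spec.mins[0] + grid.spec.d * np.arange(n1 + 1)
    y_edges = grid.spec.mins[1] + grid.spec.d * np.arange(n2 + 1)
    values = grid.p_bar if shade == "p_bar" else grid.w_bar

    fig, ax = plt.subplots(figsize=(6, 5))
    mesh = ax.pcolormesh(x_edges, y_edges, values.T, cmap="coolwarm",
                         shading="flat")
    if shade != "p_bar":
        zero = (grid.w_bar.T == 0)
        ax.pcolormesh(x_edges, y_edges, np.where(zero, 1.0, np.nan),
                      cmap="Greys", vmin=0, vmax=2, shading="flat", alpha=0.6)
    fig.colorbar(mesh, ax=ax, label="mean propensity" if shade == "p_bar"
                 else "normalized weight")
    g = np.asarray(group)
    for val, color in ((0, "tab:blue"), (1, "tab:red")):
        sel = g == val
        ax.scatter(mu[sel, 0], mu[sel, 1], s=6, c=color, label=f"group {val}",
                   edgecolors="none", alpha=0.7)
    ax.set_xlabel("latent 1")
    ax.set_ylabel("latent 2")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(output, dpi=150)
    plt.close(fig)
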