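"""Invertible per-variable pre-transformations for skewed and bimodal margins.

A latent-Gaussian generative model with a Gaussian decoder reproduces
unimodal, roughly symmetric margins well, but smears out skewness and
bimodality.  Rather than modifying the latent prior, each awkward continuous
margin is mapped toward a unimodal near-normal shape *before* training, and
generated output is mapped back:

* **Box-Cox** power transform for skewed margins, with the power ``lambda1``
  fitted by maximizing a profile log-likelihood via gradient ascent and the
  shift ``lambda2`` fixed deterministically from the data.
* **Signed-power ("bimodal") transform** ``sgn(u)|u|^rho`` with
  ``u = (x + alpha) / beta_sq`` for two-mode margins.  With the two peaks
  shifted and scaled into (-1, 1), a power ``rho > 1`` pulls them together.
  Parameters minimize a *1-sigma criterion* — zero for a normal sample —
  starting from a KDE-based valley initialization.
* **Quantile-normal** transform (empirical CDF followed by the standard
  normal quantile function) as a non-parametric baseline; its inverse clips
  to the training range.

A :class:`TransformPipeline` applies one transform per continuous column,
followed by a shared min-max scaling of all continuous columns into [0, 1];
binary columns pass through untouched.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable, ConfigError

logger = logging.getLogger(__name__)

#: |lambda1| below this uses the logarithmic branch of the Box-Cox maps.
LOG_BRANCH_THRESHOLD = 1e-4
#: numerical-stability constant inside the Box-Cox profile likelihood
BOXCOX_EPSILON = 1e-8


class DomainError(ValueError):
    """Input outside the mathematical domain of a transform."""


def _adam_minimize(grad: Callable[[np.ndarray], np.ndarray],
                   x0: np.ndarray,
                   objective: Callable[[np.ndarray], float],
                   lr: float = 1e-2,
                   max_iter: int = 2000,
                   tol: float = 1e-9) -> tuple[np.ndarray, list[float], bool]:
    """Adam descent on a small parameter vector; returns best iterate seen."""
    x = x0.astype(float).copy()
    m = np.zeros_like(x)
    v = np.zeros_like(x)
    b1, b2, eps = 0.9, 0.999, 1e-8
    trace: list[float] = []
    best_x, best_f = x.copy(), objective(x)
    converged = False
    for t in range(1, max_iter + 1):
        g = grad(x)
        if not np.all(np.isfinite(g)):
            break
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mh = m / (1 - b1 ** t)
        vh = v / (1 - b2 ** t)
        step = lr * mh / (np.sqrt(vh) + eps)
        x = x - step
        f = objective(x)
        trace.append(f)
        if f < best_f:
            best_f, best_x = f, x.copy()
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    else:
        # ran out of iterations: treat as converged if the trace plateaued
        if len(trace) > 20 and abs(trace[-1] - trace[-20]) < 1e-10 * (1 + abs(trace[-1])):
            converged = True
    return best_x, trace, converged


# ---------------------------------------------------------------------------
# Box-Cox transform
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BoxCoxParams:
    """Fitted Box-Cox parameters.

    ``lambda1`` is the power, ``lambda2`` a shift making the data positive,
    ``epsilon`` a small stability constant in the profile likelihood.
    """
    lambda1: float
    lambda2: float
    epsilon: float = BOXCOX_EPSILON
    converged: bool = True
    fit_loss_trace: list[float] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def apply_boxcox(x: np.ndarray, params: BoxCoxParams) -> np.ndarray:
    """Forward Box-Cox map ((x+l2)^l1 - 1)/l1, or log(x+l2) for l1 ~ 0."""
    x = np.asarray(x, dtype=float)
    shifted = x + params.lambda2 + params.epsilon
    bad = np.flatnonzero(shifted <= 0)
    if bad.size:
        raise DomainError(
            f"shifted value non-positive at index {bad[0]} "
            f"(x={x[bad[0]]:.6g}, lambda2={params.lambda2:.6g})"
        )
    l1 = params.lambda1
    if abs(l1) < LOG_BRANCH_THRESHOLD:
        return np.log(shifted)
    return (np.power(shifted, l1) - 1.0) / l1


def invert_boxcox(y: np.ndarray, params: BoxCoxParams, clip: bool = False) -> np.ndarray:
    """Inverse Box-Cox map (l1*y + 1)^(1/l1) - l2, or exp(y) - l2 for l1 ~ 0.

    With ``clip=True``, out-of-support values ``l1*y + 1 <= 0`` are clipped
    to the support boundary instead of raising; the clip count is logged.
    """
    y = np.asarray(y, dtype=float)
    l1 = params.lambda1
    if abs(l1) < LOG_BRANCH_THRESHOLD:
        return np.exp(y) - params.lambda2 - params.epsilon
    base = l1 * y + 1.0
    bad = base <= 0
    if np.any(bad):
        if not clip:
            raise DomainError(
                f"{int(bad.sum())} value(s) outside the inverse Box-Cox support "
                f"(first at index {int(np.flatnonzero(bad)[0])})"
            )
        logger.info("inverse Box-Cox clipped %d out-of-support value(s)", int(bad.sum()))
        base = np.maximum(base, 1e-12)
    return np.power(base, 1.0 / l1) - params.lambda2 - params.epsilon


def boxcox_loglik(x: np.ndarray, lambda1: float, lambda2: float,
                  epsilon: float = BOXCOX_EPSILON) -> float:
    """Profile log-likelihood L(l1, l2 | x) of the Box-Cox power.

    L = -(N/2) log(Var(y) + eps) + (l1 - 1) * sum(log(x + l2 + eps)),
    with y the transformed sample.
    """
    x = np.asarray(x, dtype=float)
    p = BoxCoxParams(lambda1, lambda2, epsilon)
    y = apply_boxcox(x, p)
    var = float(np.var(y, ddof=1))
    logs = np.log(x + lambda2 + epsilon)
    return -0.5 * len(x) * math.log(var + epsilon) + (lambda1 - 1.0) * float(np.sum(logs))


def default_lambda2(x: np.ndarray) -> float:
    """Deterministic positivity shift: max(0, -min(x)) + 1e-6 * range(x)."""
    x = np.asarray(x, dtype=float)
    rng = float(np.ptp(x))
    return max(0.0, -float(np.min(x))) + 1e-6 * max(rng, 1.0)


def fit_boxcox(x: np.ndarray, lr: float = 1e-2, max_iter: int = 2000,
               epsilon: float = BOXCOX_EPSILON) -> BoxCoxParams:
    """Fit ``lambda1`` by gradient ascent on the profile log-likelihood.

    ``lambda2`` is fixed first from the data (no joint optimization); the
    power is then fitted with Adam from ``lambda1 = 1`` using the analytic
    gradient of the profile likelihood.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("fit_boxcox needs at least 2 distinct values")
    l2 = default_lambda2(x)
    s = x + l2 + epsilon
    logs = np.log(s)
    sum_logs = float(np.sum(logs))
    n = x.size

    def transformed(l1: float) -> np.ndarray:
        if abs(l1) < LOG_BRANCH_THRESHOLD:
            return logs
        return (np.power(s, l1) - 1.0) / l1

    def dtransformed(l1: float) -> np.ndarray:
        # d/dl1 of ((s^l1 - 1)/l1); limit at 0 is (log s)^2 / 2
        if abs(l1) < LOG_BRANCH_THRESHOLD:
            return 0.5 * logs * logs
        p = np.power(s, l1)
        return (p * (l1 * logs - 1.0) + 1.0) / (l1 * l1)

    def neg_loglik(theta: np.ndarray) -> float:
        return -boxcox_loglik(x, float(theta[0]), l2, epsilon)

    def grad(theta: np.ndarray) -> np.ndarray:
        l1 = float(theta[0])
        y = transformed(l1)
        dy = dtransformed(l1)
        ybar = y.mean()
        var = float(np.var(y, ddof=1))
        dvar = 2.0 / (n - 1) * float(np.sum((y - ybar) * dy))
        dL = -0.5 * n * dvar / (var + epsilon) + sum_logs
        return np.array([-dL])

    best, trace, converged = _adam_minimize(grad, np.array([1.0]), neg_loglik,
                                            lr=lr, max_iter=max_iter)
    if not converged:
        logger.warning("fit_boxcox did not fully converge; returning best iterate")
    return BoxCoxParams(float(best[0]), l2, epsilon, converged=converged,
                        fit_loss_trace=trace)


# ---------------------------------------------------------------------------
# 1-sigma criterion and signed-power (bimodal) transform
# ---------------------------------------------------------------------------

def sigma_criterion(x: np.ndarray) -> float:
    """Unimodality proxy |Q84 - Q50 - sd| + |Q50 - Q16 - sd|.

    Quantiles use linear interpolation between order statistics (the common
    "type 7" rule); zero in expectation for a normal sample.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("sigma_criterion needs at least 2 values")
    q16, q50, q84 = np.quantile(x, [0.16, 0.5, 0.84])
    sd = float(np.std(x, ddof=1))
    return abs(q84 - q50 - sd) + abs(q50 - q16 - sd)


@dataclasses.dataclass
class BimodalParams:
    """Fitted signed-power transform parameters.

    The power is parameterized as ``rho = 1 + pow**2`` so that any
    unconstrained optimizer variable ``pow`` yields ``rho >= 1`` (``pow = 0``
    leaves normal data unchanged).
    """
    alpha: float
    beta_sq: float
    pow: float
    converged: bool = True
    valley_found: bool = True
    criterion_trace: list[float] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.beta_sq <= 0:
            raise ValueError("beta_sq must be positive")

    @property
    def rho(self) -> float:
        return 1.0 + self.pow ** 2


def apply_bimodal(x: np.ndarray, params: BimodalParams) -> np.ndarray:
    """Signed-power map sgn(u)|u|^rho with u = (x + alpha) / beta_sq."""
    x = np.asarray(x, dtype=float)
    u = (x + params.alpha) / params.beta_sq
    return np.sign(u) * np.power(np.abs(u), params.rho)


def invert_bimodal(y: np.ndarray, params: BimodalParams) -> np.ndarray:
    """Inverse map beta_sq * sgn(y)|y|^(1/rho) - alpha (signed root)."""
    y = np.asarray(y, dtype=float)
    return params.beta_sq * np.sign(y) * np.power(np.abs(y), 1.0 / params.rho) - params.alpha


@dataclasses.dataclass
class ValleyInit:
    """Result of the KDE-based valley search."""
    valley: float
    found: bool
    bandwidth: float
    modes: list[float]


def kde_valley_init(x: np.ndarray, max_peaks: int = 5,
                    n_grid: int = 512, n_bandwidths: int = 30,
                    min_depth_frac: float = 0.10,
                    min_peak_frac: float = 0.10) -> ValleyInit:
    """Locate the valley between the two main modes of a density estimate.

    Starting from a very small kernel bandwidth, the bandwidth grows along a
    geometric ladder (0.05*sd to 2*sd in ``n_bandwidths`` steps) until the
    density shows at most ``max_peaks`` local maxima.  The two highest peaks
    of height at least ``min_peak_frac`` of the density maximum are kept and
    the deepest valley between them returned, provided the valley dips at
    least ``min_depth_frac`` below the lower of the two peaks.  The two
    height guards keep kernel ripples in the tails of a unimodal sample from
    masquerading as modes.  If no qualifying valley exists at any bandwidth
    the sample median is returned with ``found=False``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 20:
        raise ValueError("kde_valley_init needs at least 20 values")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return ValleyInit(float(np.median(x)), False, 0.0, [])
    grid = np.linspace(float(np.min(x)), float(np.max(x)), n_grid)
    bandwidths = np.geomspace(0.05 * sd, 2.0 * sd, n_bandwidths)
    for h in bandwidths:
        kde = stats.gaussian_kde(x, bw_method=h / sd)
        dens = kde(grid)
        interior = np.flatnonzero(
            (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
        ) + 1
        if interior.size > max_peaks:
            continue
        peaks = interior[dens[interior] >= min_peak_frac * dens.max()]
        if peaks.size < 2:
            continue
        order = peaks[np.argsort(dens[peaks])[::-1][:2]]
        lo, hi = sorted(order)
        valley_idx = lo + int(np.argmin(dens[lo:hi + 1]))
        lower_peak = min(dens[lo], dens[hi])
        depth = lower_peak - dens[valley_idx]
        if depth >= min_depth_frac * lower_peak:
            modes = sorted(float(grid[i]) for i in (lo, hi))
            return ValleyInit(float(grid[valley_idx]), True, float(h), modes)
    logger.info("kde_valley_init: no valley found; returning the median")
    return ValleyInit(float(np.median(x)), False, float(bandwidths[-1]), [])


def fit_bimodal(x: np.ndarray, lr: float = 1e-2, max_iter: int = 2000,
                max_peaks: int = 5) -> BimodalParams:
    """Fit (alpha, beta, pow) minimizing the 1-sigma criterion.

    Initialization: ``pow = 0``, ``beta^2 = 1`` (identity on normal data) and
    ``alpha = -valley`` from :func:`kde_valley_init`, so that the valley maps
    to 0 where the signed power compresses.

    The raw criterion is positively homogeneous of degree 1, so shrinking
    the output scale (inflating ``beta_sq``) lowers it without changing the
    distribution's *shape* — and because the signed power is homogeneous in
    ``u``, ``beta_sq`` is a pure output-scale convention (shape depends on
    ``alpha`` and ``rho`` alone).  The optimizer therefore minimizes the
    scale-invariant form criterion(f(x)) / sd(f(x)); afterwards ``beta_sq``
    is set so the two density peaks map strictly inside (-1, 1), the region
    the power compresses.

    The criterion is piecewise linear in the data through the quantiles, so
    a central-difference subgradient feeds an Adam loop.  If optimization
    cannot improve on the initialization, the initialization is returned
    with a warning flag.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 20:
        raise ValueError("fit_bimodal needs at least 20 values")
    sd_x = float(np.std(x, ddof=1))
    init = kde_valley_init(x, max_peaks=max_peaks)
    alpha0 = -init.valley

    def unpack(theta: np.ndarray) -> BimodalParams:
        a, b, p = map(float, theta)
        return BimodalParams(a, max(b * b, 1e-6), p, valley_found=init.found)

    def objective(theta: np.ndarray) -> float:
        y = apply_bimodal(x, unpack(theta))
        sd = float(np.std(y, ddof=1))
        if not np.isfinite(sd) or sd <= 0:
            return float("inf")
        return sigma_criterion(y) / sd

    def grad(theta: np.ndarray) -> np.ndarray:
        g = np.zeros_like(theta)
        steps = np.array([1e-4 * max(sd_x, 1.0), 1e-4, 1e-4])
        for i, h in enumerate(steps):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            g[i] = (objective(tp) - objective(tm)) / (2 * h)
        return g

    theta0 = np.array([alpha0, 1.0, 0.0])
    f0 = objective(theta0)
    # rho = 1 + pow^2 makes pow = 0 an exact stationary point (d rho/d pow
    # = 0), so the search starts from a small nudge; the guard below still
    # compares against the pow = 0 initialization.
    start = np.array([alpha0, 1.0, 0.1])
    best, trace, converged = _adam_minimize(grad, start, objective,
                                            lr=lr, max_iter=max_iter)
    params = unpack(best)
    if objective(best) > f0:
        logger.warning("fit_bimodal could not improve on initialization")
        params = unpack(theta0)
        params.converged = False
    else:
        params.converged = converged
    # scale convention: place the outermost density peak at |u| = 1/1.1
    if init.found:
        peak_u = max(abs(m + params.alpha) for m in init.modes)
        if peak_u > 0:
            params.beta_sq = 1.1 * peak_u
    params.criterion_trace = [f0] + trace
    return params


# ---------------------------------------------------------------------------
# Quantile-normal baseline transform
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class QuantileParams:
    """Empirical-CDF -> standard-normal transform fitted on a training sample."""
    sorted_training_values: np.ndarray
    clip_count: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.sorted_training_values, dtype=float)
        if np.any(np.diff(v) < 0):
            raise ValueError("training values must be sorted")
        self.sorted_training_values = v

    @property
    def n_quantiles(self) -> int:
        return len(self.sorted_training_values)


def fit_quantile_normal(x: np.ndarray) -> QuantileParams:
    """Store the sorted training sample as the empirical reference."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("fit_quantile_normal needs at least 2 values")
    return QuantileParams(np.sort(x))


def _plotting_positions(n: int) -> np.ndarray:
    return (np.arange(1, n + 1) - 0.5) / n


def apply_quantile_normal(x: np.ndarray, params: QuantileParams) -> np.ndarray:
    """Empirical CDF (with interior rank offsets) then the normal quantile.

    Values outside the training range are clipped to it first; the clip count
    accumulates on ``params`` and is logged.
    """
    x = np.asarray(x, dtype=float)
    ref = params.sorted_training_values
    out_of_range = int(np.sum((x < ref[0]) | (x > ref[-1])))
    if out_of_range:
        params.clip_count += out_of_range
        logger.info("quantile transform clipped %d out-of-range value(s)", out_of_range)
    xc = np.clip(x, ref[0], ref[-1])
    p = np.interp(xc, ref, _plotting_positions(len(ref)))
    p = np.clip(p, 0.5 / len(ref), 1 - 0.5 / len(ref))
    return stats.norm.ppf(p)


def invert_quantile_normal(y: np.ndarray, params: QuantileParams) -> np.ndarray:
    """Normal CDF then interpolated empirical quantiles (clipped to range)."""
    y = np.asarray(y, dtype=float)
    ref = params.sorted_training_values
    p = stats.norm.cdf(y)
    return np.interp(p, _plotting_positions(len(ref)), ref)


# ---------------------------------------------------------------------------
# Min-max scaling and the per-column pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ScaleParams:
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if not self.maximum > self.minimum:
            raise ValueError("maximum must exceed minimum for scaling")


TRANSFORM_KINDS = ("none", "boxcox", "bimodal", "quantile")


@dataclasses.dataclass
class ColumnStage:
    kind: str
    params: BoxCoxParams | BimodalParams | QuantileParams | None
    scale: ScaleParams | None = None


class TransformPipeline:
    """Ordered per-variable transforms, then min-max scaling to [0, 1].

    Binary columns pass through untouched in both directions.  Decoder
    outputs that leave [0, 1] before un-scaling are clipped (with the clip
    rate logged) since a Gaussian decoder has unbounded support.
    """

    def __init__(self, stages: dict[str, ColumnStage], binary_columns: list[str],
                 roles: dict[str, str]):
        self.stages = stages
        self.binary_columns = binary_columns
        self.roles = roles

    # -- fitting ------------------------------------------------------------
    @classmethod
    def fit(cls, table: CohortTable, assignment: Mapping[str, str],
            **fit_kwargs) -> "TransformPipeline":
        unknown = [c for c in assignment if c not in table.data.columns]
        if unknown:
            raise ConfigError(f"transform assignment references unknown columns: {unknown}")
        stages: dict[str, ColumnStage] = {}
        for col in table.continuous_columns:
            kind = assignment.get(col, "none")
            if kind not in TRANSFORM_KINDS:
                raise ConfigError(f"unknown transform {kind!r} for column {col!r}")
            x = table.data[col].to_numpy(dtype=float)
            if kind == "boxcox":
                params = fit_boxcox(x, **fit_kwargs.get("boxcox", {}))
                z = apply_boxcox(x, params)
            elif kind == "bimodal":
                params = fit_bimodal(x, **fit_kwargs.get("bimodal", {}))
                z = apply_bimodal(x, params)
            elif kind == "quantile":
                params = fit_quantile_normal(x)
                z = apply_quantile_normal(x, params)
            else:
                params = None
                z = x
            scale = ScaleParams(float(np.min(z)), float(np.max(z)))
            stages[col] = ColumnStage(kind, params, scale)
        return cls(stages, list(table.binary_columns), dict(table.roles))

    # -- application --------------------------------------------------------
    def _transform_column(self, col: str, x: np.ndarray) -> np.ndarray:
        st = self.stages[col]
        if st.kind == "boxcox":
            x = apply_boxcox(x, st.params)
        elif st.kind == "bimodal":
            x = apply_bimodal(x, st.params)
        elif st.kind == "quantile":
            x = apply_quantile_normal(x, st.params)
        return (x - st.scale.minimum) / (st.scale.maximum - st.scale.minimum)

    def _invert_column(self, col: str, y: np.ndarray) -> np.ndarray:
        st = self.stages[col]
        n_clip = int(np.sum((y < 0) | (y > 1)))
        if n_clip:
            logger.info("column %r: clipped %d decoder output(s) to [0,1]", col, n_clip)
            y = np.clip(y, 0.0, 1.0)
        x = y * (st.scale.maximum - st.scale.minimum) + st.scale.minimum
        if st.kind == "boxcox":
            x = invert_boxcox(x, st.params, clip=True)
        elif st.kind == "bimodal":
            x = invert_bimodal(x, st.params)
        elif st.kind == "quantile":
            x = invert_quantile_normal(x, st.params)
        return x

    def forward(self, table: CohortTable) -> CohortTable:
        """Transform + scale continuous columns; binary columns untouched."""
        df = table.data.copy()
        for col in self.stages:
            df[col] = self._transform_column(col, df[col].to_numpy(dtype=float))
        return CohortTable(df, dict(table.roles))

    def inverse(self, table: CohortTable) -> CohortTable:
        df = table.data.copy()
        for col in self.stages:
            df[col] = self._invert_column(col, df[col].to_numpy(dtype=float))
        return CohortTable(df, dict(table.roles))

    # -- serialization ------------------------------------------------------
    def state(self) -> dict:
        cols = {}
        for col, st in self.stages.items():
            entry: dict = {"kind": st.kind,
                           "scale": [st.scale.minimum, st.scale.maximum]}
            if st.kind == "boxcox":
                entry["params"] = {"lambda1": st.params.lambda1,
                                   "lambda2": st.params.lambda2,
                                   "epsilon": st.params.epsilon}
            elif st.kind == "bimodal":
                entry["params"] = {"alpha": st.params.alpha,
                                   "beta_sq": st.params.beta_sq,
                                   "pow": st.params.pow}
            elif st.kind == "quantile":
                entry["params"] = {
                    "sorted_training_values": st.params.sorted_training_values}
            cols[col] = entry
        return {"columns": cols, "binary_columns": self.binary_columns,
                "roles": self.roles}

    @classmethod
    def from_state(cls, state: dict) -> "TransformPipeline":
        stages: dict[str, ColumnStage] = {}
        for col, entry in state["columns"].items():
            kind = entry["kind"]
            params = None
            if kind == "boxcox":
                params = BoxCoxParams(**entry["params"])
            elif kind == "bimodal":
                params = BimodalParams(**entry["params"])
            elif kind == "quantile":
                params = QuantileParams(np.asarray(
                    entry["params"]["sorted_training_values"], dtype=float))
            scale = ScaleParams(*entry["scale"])
            stages[col] = ColumnStage(kind, params, scale)
        return cls(stages, list(state["binary_columns"]), dict(state["roles"]))


def suggest_assignment(table: CohortTable, skew_threshold: float = 0.5,
                       valley_depth_frac: float = 0.10) -> dict[str, str]:
    """Heuristic transform assignment per continuous column.

    A column is flagged ``bimodal`` if the KDE bandwidth ladder finds a
    two-peak structure with valley depth >= ``valley_depth_frac`` of the
    lower peak, else ``boxcox`` if |sample skewness| > ``skew_threshold``,
    else ``none``.  User configuration always overrides this suggestion.
    """
    out = {}
    for col in table.continuous_columns:
        x = table.data[col].to_numpy(dtype=float)
        init = kde_valley_init(x, min_depth_frac=valley_depth_frac)
        if init.found:
            out[col] = "bimodal"
        elif abs(float(stats.skew(x))) > skew_threshold:
            out[col] = "boxcox"
        else:
            out[col] = "none"
    return out
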