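"""pMSE utility metrics: psi, its permutation null and a CV harness.

The propensity-score mean-squared-error (pMSE) utility statistic asks how
well a classifier can tell synthetic rows from original ones.  Original and
synthetic tables are stacked with a membership label y (1 = synthetic); a
CART classifier predicts per-row probabilities y_hat of being synthetic, and

    psi = (1/N) * sum_i (y_hat_i - c)^2,     c = n_syn / N.

psi is 0 when the classifier cannot do better than the constant c
(indistinguishable tables) and reaches mean((y - c)^2) under perfect
separation.  Because CART overfits somewhat even under the null, psi is
calibrated against a permutation distribution: labels are shuffled, psi
recomputed per shuffle, their mean is psi_bar, and the headline figure is
psi_ratio = psi / psi_bar — near 1 for high-utility synthetic data.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class UtilityConfig:
    """CART and permutation settings for the pMSE metrics."""
    min_leaf: int = 20
    max_depth: int = 25
    n_permutations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_leaf < 1 or self.max_depth < 1 or self.n_permutations < 1:
            raise ValueError("min_leaf, max_depth and n_permutations must be >= 1")


@dataclasses.dataclass
class UtilityResult:
    psi: float
    psi_bar: float
    psi_ratio: float | None
    psi_perm: np.ndarray
    c: float
    n: int


def _stack(original: pd.DataFrame, synthetic: pd.DataFrame,
           feature_cols: Sequence[str] | None):
    if feature_cols is None:
        feature_cols = list(original.columns)
    missing = [c for c in feature_cols if c not in synthetic.columns]
    if missing or sorted(original.columns) != sorted(synthetic.columns):
        raise ValueError(
            f"original and synthetic tables must share columns (missing: {missing})")
    X = np.vstack([original[feature_cols].to_numpy(dtype=float),
                   synthetic[feature_cols].to_numpy(dtype=float)])
    y = np.concatenate([np.zeros(len(original)), np.ones(len(synthetic))])
    return X, y


def _fit_psi(X: np.ndarray, y: np.ndarray, config: UtilityConfig,
             random_state: int) -> tuple[float, np.ndarray]:
    c = float(y.mean())
    tree = DecisionTreeClassifier(min_samples_leaf=config.min_leaf,
                                  max_depth=config.max_depth,
                                  random_state=random_state)
    tree.fit(X, y)
    proba = tree.predict_proba(X)
    y_hat = proba[:, 1] if proba.shape[1] == 2 else np.full(len(y), c)
    return float(np.mean((y_hat - c) ** 2)), y_hat


def pmse(original: pd.DataFrame, synthetic: pd.DataFrame,
         config: UtilityConfig | None = None,
         feature_cols: Sequence[str] | None = None) -> tuple[float, dict]:
    """Compute psi for a pair of tables.

    ``feature_cols`` restricts the classifier's features (by default all
    shared columns; group-label and outcome columns should be excluded by
    the caller when utility is meant to measure covariate fidelity).
    Returns psi and a detail dict with c, y_hat and the fitted tree inputs.
    """
    config = config or UtilityConfig()
    X, y = _stack(original, synthetic, feature_cols)
    psi, y_hat = _fit_psi(X, y, config, random_state=config.seed)
    c = float(y.mean())
    return psi, {"c": c, "y_hat": y_hat, "n": len(y)}


def permutation_null(original: pd.DataFrame, synthetic: pd.DataFrame,
                     config: UtilityConfig | None = None,
                     feature_cols: Sequence[str] | None = None
                     ) -> tuple[float, np.ndarray]:
    """Mean psi over label permutations (the indistinguishability null).

    Rows stay fixed; only the synthetic/original labels are permuted, fresh
    per permutation from a seeded stream.  Returns (psi_bar, psi_perm).
    """
    config = config or UtilityConfig()
    X, y = _stack(original, synthetic, feature_cols)
    rng = np.random.default_rng(config.seed)
    psis = np.empty(config.n_permutations)
    for j in range(config.n_permutations):
        y_perm = rng.permutation(y)
        psis[j], _ = _fit_psi(X, y_perm, config, random_state=config.seed + j)
    return float(psis.mean()), psis


def psi_ratio(psi: float, psi_bar: float) -> float | None:
    """psi / psi_bar; None (undefined) when psi_bar is 0."""
    if psi_bar == 0:
        logger.warning("psi_bar is zero; psi_ratio undefined")
        return None
    return psi / psi_bar


def evaluate(original: pd.DataFrame, synthetic: pd.DataFrame,
             config: UtilityConfig | None = None,
             feature_cols: Sequence[str] | None = None) -> UtilityResult:
    """psi, psi_bar and psi_ratio for one original/synthetic pair."""
    config = config or UtilityConfig()
    psi, detail = pmse(original, synthetic, config, feature_cols)
    psi_bar, psi_perm = permutation_null(original, synthetic, config, feature_cols)
    return UtilityResult(psi, psi_bar, psi_ratio(psi, psi_bar), psi_perm,
                         detail["c"], detail["n"])


@dataclasses.dataclass
class CrossvalSummary:
    psi_mean: float
    psi_sd: float
    psi_bar_mean: float
    psi_bar_sd: float
    ratio_mean: float
    ratio_sd: float
    fold_results: list[UtilityResult]
    fold_info: list[dict]
    failed_folds: list[int]


def crossval_utility(table, generator: Callable, k: int = 10,
                     config: UtilityConfig | None = None,
                     feature_cols: Sequence[str] | None = None,
                     seed: int = 0) -> CrossvalSummary:
    """k-fold evaluation of a synthetic-data generator.

    ``generator(train_table, n, fold_seed)`` must return a DataFrame of
    ``n`` synthetic rows (optionally ``(df, info)`` with diagnostics such as
    reconstruction-loss traces, stored per fold).  Per fold the generator is
    fitted on the training part, a synthetic sample the size of the heldout
    part is drawn (keeping c = 0.5), and psi / psi_bar / psi_ratio are
    computed against the heldout originals.  A generator failure marks the
    fold failed; the summary covers completed folds with a warning.
    """
    from .io import CohortTable  # noqa: F401  (type only)

    config = config or UtilityConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    if feature_cols is None:
        feature_cols = table.feature_columns
    results: list[UtilityResult] = []
    infos: list[dict] = []
    failed: list[int] = []
    for fold, (tr, te) in enumerate(kf.split(np.arange(table.n_rows))):
        train, held = table.subset(tr), table.subset(te)
        try:
            out = generator(train, len(te), seed + 1000 + fold)
        except Exception as exc:
            logger.warning("generator failed in fold %d: %s", fold, exc)
            failed.append(fold)
            continue
        syn, info = out if isinstance(out, tuple) else (out, {})
        fold_cfg = dataclasses.replace(config, seed=config.seed + fold)
        res = evaluate(held.data[list(feature_cols)], syn[list(feature_cols)],
                       fold_cfg)
        results.append(res)
        infos.append(info)
    if not results:
        raise RuntimeError("every CV fold failed")
    if failed:
        logger.warning("summary based on %d/%d folds", len(results), k)
    psis = np.array([r.psi for r in results])
    bars = np.array([r.psi_bar for r in results])
    ratios = np.array([r.psi_ratio for r in results], dtype=float)
    return CrossvalSummary(
        float(psis.mean()), float(psis.std(ddof=1)) if len(psis) > 1 else 0.0,
        float(bars.mean()), float(bars.std(ddof=1)) if len(bars) > 1 else 0.0,
        float(ratios.mean()), float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
        results, infos, failed,
    )
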