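"""Seeded synthetic cohort generators with the structure the method targets.

Two presets are provided:

* :func:`paper_like_spec` — a breast-cancer-style simulated cohort of 2,500
  individuals and 21 variables (12 binary, 9 continuous), with an
  imbalanced binary exposure E, skewed continuous margins and one bimodal
  variable built conditionally on the exposure: N(0, 1) where E = 0 and
  N(4, 1) where E = 1.  The bimodal marginal is deliberately asymmetric
  (imbalanced exposure) and the modes overlap.  A binary outcome follows a
  logistic model on exposure and selected covariates.
* :func:`two_region_spec` — a stroke-trial-style two-region cohort where at
  least one continuous variable (blood pressure) is identically distributed
  across regions, one (age) is mean-shifted, a delay variable is bimodal,
  and binary variables have region-dependent rates.

These emulate the shape features of the study designs (counts, types,
skewness, exposure-linked bimodality, logistic links) without reproducing
any particular published dependence structure.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CohortTable, ConfigError


@dataclasses.dataclass
class ContinuousSpec:
    """One continuous column: family in {'normal', 'lognormal',
    'exposure_bimodal'} with family-specific params and an optional additive
    mean shift per unit exposure."""
    name: str
    family: str
    params: dict
    exposure_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal", "exposure_bimodal"):
            raise ConfigError(f"unknown continuous family {self.family!r}")


@dataclasses.dataclass
class BinarySpec:
    """One binary column: base rate plus an exposure log-odds shift."""
    name: str
    base_rate: float
    exposure_log_odds: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.base_rate < 1:
            raise ConfigError(f"base rate for {self.name!r} must be in (0,1)")


@dataclasses.dataclass
class CohortSpec:
    """Full recipe for a seeded synthetic cohort."""
    n: int
    continuous: list[ContinuousSpec]
    binary: list[BinarySpec]
    exposure_name: str = "E"
    exposure_prevalence: float = 0.3
    outcome_name: str = "y"
    outcome_coefs: dict = dataclasses.field(default_factory=dict)
    outcome_intercept: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if not 0 < self.exposure_prevalence < 1:
            raise ConfigError("exposure prevalence must be in (0, 1)")


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a cohort: exposure first, then covariates, then the outcome.

    Bimodal columns are drawn conditionally on the exposure exactly as
    specified (mean ``mu0``/``mu1``, sd ``sd``); the outcome comes from a
    logistic model on the configured columns.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    E = (rng.uniform(size=spec.n) < spec.exposure_prevalence).astype(int)
    cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    for cs in spec.continuous:
        if cs.family == "normal":
            x = rng.normal(cs.params.get("mean", 0.0), cs.params.get("sd", 1.0),
                           size=spec.n)
        elif cs.family == "lognormal":
            x = rng.lognormal(cs.params.get("meanlog", 0.0),
                              cs.params.get("sdlog", 1.0), size=spec.n)
        else:  # exposure_bimodal
            mu0 = cs.params.get("mu0", 0.0)
            mu1 = cs.params.get("mu1", 4.0)
            sd = cs.params.get("sd", 1.0)
            x = rng.normal(np.where(E == 1, mu1, mu0), sd)
        x = x + cs.exposure_shift * E
        cols[cs.name] = x
        roles[cs.name] = "continuous"
    for bs in spec.binary:
        base_logit = np.log(bs.base_rate / (1 - bs.base_rate))
        p = 1.0 / (1.0 + np.exp(-(base_logit + bs.exposure_log_odds * E)))
        cols[bs.name] = (rng.uniform(size=spec.n) < p).astype(int)
        roles[bs.name] = "binary"
    cols[spec.exposure_name] = E
    roles[spec.exposure_name] = "group"
    eta = np.full(spec.n, spec.outcome_intercept, dtype=float)
    for name, coef in spec.outcome_coefs.items():
        src = E if name == spec.exposure_name else cols[name]
        eta += coef * np.asarray(src, dtype=float)
    y = (rng.uniform(size=spec.n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    cols[spec.outcome_name] = y
    roles[spec.outcome_name] = "outcome"
    return CohortTable(pd.DataFrame(cols), roles)


def paper_like_spec(n: int = 2500, seed: int = 0) -> CohortSpec:
    """The default study-style simulated cohort (21 variables, 12 binary)."""
    continuous = [
        ContinuousSpec("x_bimodal", "exposure_bimodal",
                       {"mu0": 0.0, "mu1": 4.0, "sd": 1.0}),
        ContinuousSpec("x_skew1", "lognormal", {"meanlog": 0.0, "sdlog": 1.0}),
        ContinuousSpec("x_skew2", "lognormal", {"meanlog": 1.0, "sdlog": 0.8},
                       exposure_shift=0.5),
        ContinuousSpec("x_skew3", "lognormal", {"meanlog": 0.5, "sdlog": 0.7}),
        ContinuousSpec("x_skew4", "lognormal", {"meanlog": 2.0, "sdlog": 0.9}),
        ContinuousSpec("x_norm1", "normal", {"mean": 0.0, "sd": 1.0},
                       exposure_shift=0.8),
        ContinuousSpec("x_norm2", "normal", {"mean": 50.0, "sd": 10.0}),
        ContinuousSpec("x_norm3", "normal", {"mean": -2.0, "sd": 3.0},
                       exposure_shift=-1.0),
        ContinuousSpec("x_norm4", "normal", {"mean": 10.0, "sd": 2.0}),
    ]
    binary = [
        BinarySpec("b1", 0.5, 1.0), BinarySpec("b2", 0.3, -0.8),
        BinarySpec("b3", 0.2, 0.6), BinarySpec("b4", 0.7, 0.0),
        BinarySpec("b5", 0.4, 1.2), BinarySpec("b6", 0.1, 0.0),
        BinarySpec("b7", 0.6, -0.5), BinarySpec("b8", 0.25, 0.4),
        BinarySpec("b9", 0.45, 0.0), BinarySpec("b10", 0.35, 0.9),
    ]
    return CohortSpec(
        n=n, continuous=continuous, binary=binary,
        exposure_prevalence=0.3,
        outcome_coefs={"E": 0.8, "b1": 0.5, "x_norm1": 0.4, "b5": -0.3},
        outcome_intercept=-1.0, seed=seed,
    )


@dataclasses.dataclass
class TwoRegionSpec:
    """Recipe for the two-region (known sub-groups) cohort."""
    n: int = 2668
    region_prevalence: float = 0.5
    age_base: float = 62.0
    age_shift: float = 8.0       # EU-NORTH-style higher stroke age
    age_sd: float = 10.0
    sbp_mean: float = 150.0      # shared across regions
    sbp_sd: float = 25.0
    delay_modes: tuple[float, float] = (8.0, 30.0)
    delay_sd: tuple[float, float] = (3.0, 8.0)
    binary_rates: tuple[tuple[str, float, float], ...] = (
        ("sex", 0.52, 0.46), ("rsleep", 0.25, 0.32), ("ratrial", 0.15, 0.22),
        ("rct", 0.65, 0.75), ("rvisinf", 0.30, 0.42), ("rhep24", 0.10, 0.06),
        ("rasp3", 0.20, 0.28), ("rxasp", 0.50, 0.50), ("rxhep", 0.50, 0.50),
        ("rconsc1", 0.22, 0.18),
    )  # (name, rate in region 0, rate in region 1)
    seed: int = 0


def generate_two_region(spec: TwoRegionSpec) -> CohortTable:
    """Two-region cohort with shared, shifted and bimodal continuous margins."""
    rng = np.random.default_rng(spec.seed)
    R = (rng.uniform(size=spec.n) < spec.region_prevalence).astype(int)
    age = rng.normal(spec.age_base + spec.age_shift * R, spec.age_sd)
    sbp = rng.normal(spec.sbp_mean, spec.sbp_sd, size=spec.n)
    late = rng.uniform(size=spec.n) < 0.45  # latent admission-delay mode
    delay = rng.normal(np.where(late, spec.delay_modes[1], spec.delay_modes[0]),
                       np.where(late, spec.delay_sd[1], spec.delay_sd[0]))
    delay = np.maximum(delay, 0.5)
    cols = {"age": age, "sbp": sbp, "rdelay": delay}
    roles = {"age": "continuous", "sbp": "continuous", "rdelay": "continuous"}
    for name, r0, r1 in spec.binary_rates:
        p = np.where(R == 1, r1, r0)
        cols[name] = (rng.uniform(size=spec.n) < p).astype(int)
        roles[name] = "binary"
    cols["region"] = R
    roles["region"] = "group"
    eta = -6.0 + 0.06 * age + 0.004 * sbp
    cols["fdead"] = (rng.uniform(size=spec.n) < 1 / (1 + np.exp(-eta))).astype(int)
    roles["fdead"] = "outcome"
    return CohortTable(pd.DataFrame(cols), roles)


def default_assignment(preset: str = "paper") -> dict[str, str]:
    """Transform assignment matching the presets' marginal shapes."""
    if preset == "paper":
        return {"x_bimodal": "bimodal", "x_skew1": "boxcox", "x_skew2": "boxcox",
                "x_skew3": "boxcox", "x_skew4": "boxcox"}
    if preset == "two-region":
        return {"rdelay": "bimodal"}
    raise ConfigError(f"unknown preset {preset!r}")
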