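"""Cohort table container, CSV round-tripping, configs and parameter archives.

A :class:`CohortTable` is a thin wrapper around a :class:`pandas.DataFrame`
that records a *role* for every column: ``continuous``, ``binary``,
``group`` (a known sub-group / exposure label) or ``outcome``.  The group
and outcome columns are binary by convention but are excluded from the
generative-model features by default — the generator learns covariates, and
sub-group structure is handled through propensity scores.

Fitted objects (transform pipelines, trained generators) persist to a
version-stamped JSON archive so that generation can be re-run from disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALID_ROLES = ("continuous", "binary", "group", "outcome")

ARCHIVE_FORMAT = "hetsynth-archive"
ARCHIVE_VERSION = 1


class ConfigError(ValueError):
    """A configuration references unknown columns or invalid settings."""


class ArchiveError(ValueError):
    """A parameter archive is corrupt or from an incompatible version."""


# ---------------------------------------------------------------------------
# CohortTable
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CohortTable:
    """Rectangular cohort data with per-column roles.

    Parameters
    ----------
    data:
        The table; one row per individual.
    roles:
        Mapping from column name to one of ``continuous``, ``binary``,
        ``group``, ``outcome``.  Every column of ``data`` must appear.
    """

    data: pd.DataFrame
    roles: dict[str, str]

    def __post_init__(self) -> None:
        for col, role in self.roles.items():
            if role not in VALID_ROLES:
                raise ConfigError(f"unknown role {role!r} for column {col!r}")
            if col not in self.data.columns:
                raise ConfigError(f"role given for unknown column {col!r}")
        missing = [c for c in self.data.columns if c not in self.roles]
        if missing:
            raise ConfigError(f"columns without a role: {missing}")
        for col in self.binary_columns + self.label_columns:
            vals = set(pd.unique(self.data[col].dropna()))
            if not vals <= {0, 1}:
                raise ConfigError(
                    f"column {col!r} declared binary but holds values {sorted(vals)[:6]}"
                )

    # -- column views -------------------------------------------------------
    @property
    def continuous_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.roles[c] == "continuous"]

    @property
    def binary_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.roles[c] == "binary"]

    @property
    def label_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.roles[c] in ("group", "outcome")]

    @property
    def group_column(self) -> str | None:
        cols = [c for c in self.data.columns if self.roles[c] == "group"]
        return cols[0] if cols else None

    @property
    def outcome_column(self) -> str | None:
        cols = [c for c in self.data.columns if self.roles[c] == "outcome"]
        return cols[0] if cols else None

    @property
    def feature_columns(self) -> list[str]:
        """Covariate columns used by the generative model (no labels)."""
        return self.continuous_columns + self.binary_columns

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def subset(self, index) -> "CohortTable":
        return CohortTable(self.data.loc[index].reset_index(drop=True), dict(self.roles))

    def features(self) -> pd.DataFrame:
        return self.data[self.feature_columns]


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path, roles: Mapping[str, str]) -> CohortTable:
    """Read a delimited cohort table and validate it against ``roles``.

    Binary columns may hold any two values (e.g. ``yes``/``no``); they are
    mapped to {0, 1} by sorted order and the mapping is logged.  Rows with
    missing values in any role-assigned column are dropped with a logged
    count.
    """
    df = pd.read_csv(path)
    unknown = [c for c in roles if c not in df.columns]
    if unknown:
        raise ConfigError(f"config references unknown columns: {unknown}")
    df = df[list(roles)]

    n_before = len(df)
    df = df.dropna().reset_index(drop=True)
    if len(df) < n_before:
        logger.info("dropped %d rows with missing values", n_before - len(df))

    for col, role in roles.items():
        if role == "continuous":
            df[col] = pd.to_numeric(df[col])
            continue
        # binary-valued roles
        vals = sorted(pd.unique(df[col]), key=str)
        if len(vals) > 2:
            raise ConfigError(
                f"column {col!r} declared {role} but has {len(vals)} levels: {vals[:6]}"
            )
        if set(vals) <= {0, 1}:
            df[col] = df[col].astype(int)
        else:
            mapping = {v: i for i, v in enumerate(vals)}
            logger.info("column %r mapped to binary: %s", col, mapping)
            df[col] = df[col].map(mapping).astype(int)
    return CohortTable(df, dict(roles))


def write_cohort(table: CohortTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def expand_categorical(df: pd.DataFrame, column: str, reference: Any | None = None
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Expand a k-level categorical column into k-1 binary indicators.

    The reference level (default: the most frequent) gets no indicator; each
    other level ``v`` yields a column ``{column}_{v}``.
    """
    levels = df[column].value_counts().index.tolist()
    if reference is None:
        reference = levels[0]
    out = df.drop(columns=[column]).copy()
    new_cols = []
    for v in levels:
        if v == reference:
            continue
        name = f"{column}_{v}"
        out[name] = (df[column] == v).astype(int)
        new_cols.append(name)
    return out, new_cols


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Declarative run settings parsed from a YAML config file."""

    roles: dict[str, str]
    transforms: dict[str, str] = dataclasses.field(default_factory=dict)
    vae: dict[str, Any] = dataclasses.field(default_factory=dict)
    grid: dict[str, Any] = dataclasses.field(default_factory=dict)
    utility: dict[str, Any] = dataclasses.field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "roles" not in raw:
            raise ConfigError("config must declare a 'roles' block")
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Parameter archives (JSON; endianness-safe, text-only)
# ---------------------------------------------------------------------------

def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _from_jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=obj.get("dtype", "float64"))
        return {k: _from_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_from_jsonable(v) for v in obj]
    return obj


def save_archive(payload: Mapping[str, Any], kind: str, path: str | Path) -> None:
    """Write a fitted object's state to a version-stamped JSON archive."""
    doc = {
        "format": ARCHIVE_FORMAT,
        "version": ARCHIVE_VERSION,
        "kind": kind,
        "payload": _to_jsonable(dict(payload)),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_archive(path: str | Path, kind: str | None = None) -> dict[str, Any]:
    """Load an archive, checking format, version and (optionally) kind."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ArchiveError(f"corrupt archive {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != ARCHIVE_FORMAT:
        raise ArchiveError(f"{path} is not a parameter archive")
    if doc.get("version") != ARCHIVE_VERSION:
        raise ArchiveError(
            f"archive version {doc.get('version')} unsupported "
            f"(expected {ARCHIVE_VERSION})"
        )
    if kind is not None and doc.get("kind") != kind:
        raise ArchiveError(f"archive kind {doc.get('kind')!r}, expected {kind!r}")
    doc["payload"] = _from_jsonable(doc["payload"])
    return doc
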