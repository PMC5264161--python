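"""Process-dataset schema, scaling, and train/test splitting.

A process dataset is a table with five inputs and one target, in this fixed
column order:

    pH (unitless), DMP_in (ug/L), DO (mg/L), ORP (mV), MLSS (mg/L),
    DMP_eff (ug/L, target)

ORP may be negative; the concentration-like columns must be non-negative.
Scaling defaults to the symmetric min-max map onto [-1, 1]; unit-interval
min-max and z-scoring are also available.  Scaling specs are fitted on the
training split only and then applied unchanged to the test split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ScalingError, SchemaError

log = logging.getLogger(__name__)

__all__ = [
    "COLUMNS",
    "INPUT_COLUMNS",
    "TARGET_COLUMN",
    "ScalingSpec",
    "load_dataset",
    "write_dataset",
    "fit_scaling",
    "apply_scaling",
    "invert_scaling",
    "split_dataset",
    "to_arrays",
]

COLUMNS = ("pH", "DMP_in", "DO", "ORP", "MLSS", "DMP_eff")
INPUT_COLUMNS = COLUMNS[:5]
TARGET_COLUMN = COLUMNS[5]
#: columns that cannot physically be negative
_NONNEGATIVE = ("pH", "DMP_in", "DO", "MLSS", "DMP_eff")

SCALING_METHODS = ("minmax_sym", "minmax_unit", "zscore")


def load_dataset(path) -> pd.DataFrame:
    """Read and validate a process-dataset CSV (header case-insensitive)."""
    df = pd.read_csv(path)
    lower = {c.lower(): c for c in df.columns}
    missing = [c for c in COLUMNS if c.lower() not in lower]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    df = df.rename(columns={lower[c.lower()]: c for c in COLUMNS})[list(COLUMNS)]
    return _validate(df, str(path))


def write_dataset(df: pd.DataFrame, path) -> None:
    _validate(df, "in-memory dataset").to_csv(path, index=False)


def _validate(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for col in COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise SchemaError(f"{origin}: non-numeric or missing value at row {row}, column {col!r}")
        if col in _NONNEGATIVE and (vals < 0).any():
            row = int(np.argmax((vals < 0).to_numpy()))
            raise SchemaError(f"{origin}: negative value at row {row}, column {col!r}")
        out[col] = vals.astype(float)
    log.info("validated dataset from %s: %d rows", origin, len(out))
    return out


# ----------------------------------------------------------------------
# scaling
# ----------------------------------------------------------------------

@dataclass
class ScalingSpec:
    """Invertible per-column scaling: the two stats are (min, max) for the
    min-max methods and (mean, sd) for z-scoring."""

    method: str
    stats: dict[str, tuple[float, float]]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"method": self.method, "stats": self.stats}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ScalingSpec":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(method=d["method"], stats={k: tuple(v) for k, v in d["stats"].items()})


def fit_scaling(df: pd.DataFrame, method: str = "minmax_sym", columns=None) -> ScalingSpec:
    if method not in SCALING_METHODS:
        raise ConfigError(f"unknown scaling method {method!r}")
    columns = list(columns) if columns is not None else list(df.columns)
    stats: dict[str, tuple[float, float]] = {}
    for col in columns:
        v = df[col].to_numpy(dtype=float)
        if method == "zscore":
            sd = float(v.std(ddof=0))
            if sd == 0.0:
                raise ScalingError(f"column {col!r} has zero standard deviation")
            stats[col] = (float(v.mean()), sd)
        else:
            lo, hi = float(v.min()), float(v.max())
            if hi <= lo:
                raise ScalingError(f"column {col!r} is constant; min-max scaling degenerate")
            stats[col] = (lo, hi)
    return ScalingSpec(method=method, stats=stats)


def _apply_col(v: np.ndarray, method: str, a: float, b: float) -> np.ndarray:
    if method == "minmax_sym":
        return 2.0 * (v - a) / (b - a) - 1.0
    if method == "minmax_unit":
        return (v - a) / (b - a)
    return (v - a) / b  # zscore: a = mean, b = sd


def _invert_col(v: np.ndarray, method: str, a: float, b: float) -> np.ndarray:
    if method == "minmax_sym":
        return a + (v + 1.0) * (b - a) / 2.0
    if method == "minmax_unit":
        return a + v * (b - a)
    return a + v * b


def apply_scaling(df: pd.DataFrame, spec: ScalingSpec) -> pd.DataFrame:
    out = df.copy()
    for col, (a, b) in spec.stats.items():
        if col not in out.columns:
            raise ScalingError(f"scaling spec column {col!r} absent from data")
        out[col] = _apply_col(out[col].to_numpy(dtype=float), spec.method, a, b)
    return out


def invert_scaling(df: pd.DataFrame, spec: ScalingSpec) -> pd.DataFrame:
    out = df.copy()
    for col, (a, b) in spec.stats.items():
        if col not in out.columns:
            raise ScalingError(f"scaling spec column {col!r} absent from data")
        out[col] = _invert_col(out[col].to_numpy(dtype=float), spec.method, a, b)
    return out


# ----------------------------------------------------------------------
# splitting
# ----------------------------------------------------------------------

def split_dataset(df: pd.DataFrame, n_train: int = 35, seed: int = 0):
    """Seeded random partition into (train, test); disjoint and exhaustive."""
    n = len(df)
    if not 0 < n_train < n:
        raise ConfigError(f"n_train must be in (0, {n}), got {n_train}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = df.iloc[perm[:n_train]].reset_index(drop=True)
    test = df.iloc[perm[n_train:]].reset_index(drop=True)
    return train, test


def to_arrays(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a (possibly scaled) dataset into an (N, 5) input array and the
    target vector."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"dataset missing column(s) {missing}")
    return df[list(INPUT_COLUMNS)].to_numpy(dtype=float), df[TARGET_COLUMN].to_numpy(dtype=float)
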