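"""Evaluation statistics: R^2, MAPE, RMSE, MSE, and the comparison-table layout.

MAPE is reported in percent.  When an observed value is exactly zero MAPE is
undefined and flagged (the other statistics are still computed); likewise R^2
is flagged when the observed values have zero variance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["Metrics", "compute_metrics", "comparison_table"]

#: row order of the comparison table
TABLE_ROWS = ("R2", "MAPE", "RMSE", "MSE")


@dataclass
class Metrics:
    r_squared: float
    mape: float
    rmse: float
    mse: float
    n: int
    mape_defined: bool = True
    r2_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "mape": self.mape,
            "rmse": self.rmse,
            "mse": self.mse,
            "n": self.n,
            "mape_defined": self.mape_defined,
            "r2_defined": self.r2_defined,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compute_metrics(observed, predicted) -> Metrics:
    """Compute MSE, RMSE (= sqrt(MSE)), MAPE (percent) and R^2.

    ``r_squared = 1 - SS_res / SS_tot`` can be negative for a predictor worse
    than the observed mean; it equals 1 iff predictions match observations.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.ndim != 1 or o.shape != p.shape:
        raise SchemaError(
            f"observed and predicted must be equal-length 1-D vectors, got "
            f"{o.shape} and {p.shape}"
        )
    if o.size < 1:
        raise SchemaError("metrics require at least one sample")
    err = o - p
    mse = float(np.mean(err**2))
    rmse = math.sqrt(mse)

    mape_defined = bool(np.all(o != 0.0))
    mape = float(100.0 * np.mean(np.abs(err) / np.abs(o))) if mape_defined else float("nan")

    ss_tot = float(np.sum((o - o.mean()) ** 2))
    r2_defined = ss_tot > 0.0
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if r2_defined else float("nan")

    return Metrics(
        r_squared=r2,
        mape=mape,
        rmse=rmse,
        mse=mse,
        n=int(o.size),
        mape_defined=mape_defined,
        r2_defined=r2_defined,
    )


def comparison_table(metrics_by_model: dict[str, Metrics]) -> pd.DataFrame:
    """Render one Metrics per model as a 4-row table (R2, MAPE, RMSE, MSE)."""
    if not metrics_by_model:
        raise SchemaError("comparison_table requires at least one model")
    cols = {}
    for name, m in metrics_by_model.items():
        cols[name] = [m.r_squared, m.mape, m.rmse, m.mse]
    return pd.DataFrame(cols, index=list(TABLE_ROWS))
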