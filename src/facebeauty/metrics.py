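"""Evaluation metrics for score prediction.

Four statistics summarise agreement between predicted and human-assigned
beauty scores:

MAE = (1/n) sum |y_i - yhat_i|
MSE = (1/n) sum (y_i - yhat_i)^2
R^2 = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2
PC  = (n sum xy - sum x sum y) /
      sqrt((n sum x^2 - (sum x)^2)(n sum y^2 - (sum y)^2))

PC is the Pearson product-moment correlation in its computational form.
PC and R^2 are undefined when a variance term vanishes (constant truth or
constant prediction); they are then flagged as NaN rather than raising, so
batch evaluation proceeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["MetricsReport", "evaluate", "pearson_correlation"]


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; NaN if either argument is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    den_sq = (n * sxx - sx * sx) * (n * syy - sy * sy)
    if den_sq <= 0.0:
        return float("nan")
    return float((n * sxy - sx * sy) / math.sqrt(den_sq))


@dataclass(frozen=True)
class MetricsReport:
    """The four evaluation metrics on one prediction set.

    ``pc`` and ``r2`` are NaN when undefined (zero-variance argument).
    """

    pc: float
    r2: float
    mae: float
    mse: float
    n: int

    def as_dict(self) -> dict:
        return {"pc": self.pc, "r2": self.r2,
                "mae": self.mae, "mse": self.mse, "n": self.n}


def evaluate(y: Sequence[float], yhat: Sequence[float]) -> MetricsReport:
    """Compute PC, R^2, MAE and MSE of predictions against true scores."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size == 0:
        raise ValueError("y and yhat must be equal-length non-empty 1-D arrays")
    err = y - yhat
    mae = float(np.abs(err).mean())
    mse = float((err ** 2).mean())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((err ** 2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return MetricsReport(pc=pearson_correlation(y, yhat), r2=r2,
                         mae=mae, mse=mse, n=int(y.size))
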