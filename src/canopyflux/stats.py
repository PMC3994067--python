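"""Model-evaluation statistics for predicted-vs-observed series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sstats


@dataclass(frozen=True)
class EvalStats:
    """R-squared, RMSE, Willmott's index of agreement, zero-intercept slope."""

    r2: float
    rmse: float
    willmott_d: float
    slope: float
    n: int


def evaluate(pred, obs) -> EvalStats:
    """Compare a predicted series against observations.

    Paired NaNs are dropped.  ``r2`` is the squared correlation of the
    ordinary regression; ``willmott_d`` is
    ``1 - sum((P-O)^2) / sum((|P - Obar| + |O - Obar|)^2)``; ``slope``
    is the zero-intercept regression slope ``sum(P O) / sum(O^2)``.

    Raises
    ------
    ValueError
        On length mismatch, fewer than two valid pairs, or constant
        observations (for which d is undefined).
    """
    p = np.asarray(pred, dtype=float)
    o = np.asarray(obs, dtype=float)
    if p.shape != o.shape:
        raise ValueError("prediction and observation series must have equal length")
    ok = ~(np.isnan(p) | np.isnan(o))
    p, o = p[ok], o[ok]
    if p.size < 2:
        raise ValueError("need at least two paired non-missing values")
    if np.ptp(o) == 0.0:
        raise ValueError("constant observations: agreement index undefined")
    r2 = float(_sstats.linregress(o, p).rvalue ** 2)
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    obar = o.mean()
    denom = np.sum((np.abs(p - obar) + np.abs(o - obar)) ** 2)
    d = float(1.0 - np.sum((p - o) ** 2) / denom)
    slope = float(np.sum(p * o) / np.sum(o * o))
    return EvalStats(r2=r2, rmse=rmse, willmott_d=d, slope=slope, n=int(p.size))
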