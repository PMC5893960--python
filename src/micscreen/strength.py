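"""MIC_e strength estimation for the significant associations.

The independence-testing stage runs at a fixed, power-oriented grid
bound (B = 9 by default); the strength stage re-estimates each
significant pair with the equitability-oriented, sample-size-dependent
bound B(n) = n^alpha, where alpha decreases with n.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .estimators import MineParams, grid_bound, mic_e

__all__ = ["ALPHA_SCHEDULE", "alpha_for_n", "strength_table"]

# (lower bound incl., upper bound excl., alpha); ranges partition [2, inf)
ALPHA_SCHEDULE = (
    (2, 25, 0.85),
    (25, 50, 0.80),
    (50, 250, 0.75),
    (250, 500, 0.70),
    (500, 1_000, 0.65),
    (1_000, 2_500, 0.60),
    (2_500, 5_000, 0.55),
    (5_000, 10_000, 0.50),
    (10_000, 40_000, 0.45),
    (40_000, math.inf, 0.40),
)


def alpha_for_n(n: int) -> float:
    """Default equitability exponent alpha for sample size n."""
    if n < 2:
        raise ValueError(f"need at least 2 samples, got n={n}")
    for lo, hi, alpha in ALPHA_SCHEDULE:
        if lo <= n < hi:
            return alpha
    raise AssertionError("unreachable: schedule partitions [2, inf)")


def strength_table(
    adjusted: pd.DataFrame,
    x: pd.DataFrame,
    y: pd.DataFrame | None = None,
    threshold: float = 0.05,
    alpha: float | None = None,
    c: int = 5,
    adjusted_col: str = "adjusted",
) -> pd.DataFrame:
    """MIC_e strength for every pair whose adjusted value passes threshold.

    ``adjusted`` needs columns var_x, var_y and ``adjusted_col``; data
    vectors are looked up by variable id in ``x`` (and ``y`` for
    cross/row-wise runs).  The significance set is never changed here,
    only annotated.  Returns (var_x, var_y, adjusted, mic_e) sorted by
    descending strength.
    """
    n = x.shape[1]
    if y is not None and y.shape[1] != n:
        raise ValueError("x and y must share the sample columns")
    b = grid_bound(n, alpha_for_n(n) if alpha is None else alpha)
    params = MineParams(b=b, c=c)
    second = x if y is None else y

    sig = adjusted.loc[adjusted[adjusted_col] < threshold]
    records = []
    for row in sig.itertuples(index=False):
        vx, vy = row.var_x, row.var_y
        if vx not in x.index:
            raise KeyError(f"variable {vx!r} not found in the data matrix")
        if vy not in second.index:
            raise KeyError(f"variable {vy!r} not found in the data matrix")
        records.append(
            (
                vx,
                vy,
                getattr(row, adjusted_col),
                mic_e(x.loc[vx].to_numpy(), second.loc[vy].to_numpy(), params),
            )
        )
    out = pd.DataFrame(
        records, columns=["var_x", "var_y", adjusted_col, "mic_e"]
    )
    out = out.sort_values("mic_e", ascending=False, kind="stable")
    return out.reset_index(drop=True)
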