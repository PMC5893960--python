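"""Empirical p-values and multiple-testing correction.

The observed TIC_e t_i is converted to an empirical p-value against the
shared permutation null,

    p_i = (1 + #{r : t0_r >= t_i}) / (1 + R),

whose floor is 1/(1+R).  The screen-level correction of choice is the
Storey q-value: the null fraction pi0 is estimated from the flat
high-p region of the p-value distribution and

    q(p_i) = min_{h >= p_i} pi0 * M * h / #{p_j <= h}

over thresholds h at the observed p-values (ties counted inclusively),
capped at 1.  Classical FWER/FDR step procedures are available through
statsmodels under the same interface.
"""

from __future__ import annotations

import warnings

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "empirical_pvalue",
    "estimate_pi0",
    "storey_qvalues",
    "adjust",
    "pvalue_histogram",
    "check_pvalue_floor",
]

_SM_METHODS = {
    "bh": "fdr_bh",
    "by": "fdr_by",
    "bonferroni": "bonferroni",
    "holm": "holm",
}
METHODS = ("qvalue",) + tuple(_SM_METHODS)

DEFAULT_LAMBDA_GRID = np.round(np.linspace(0.0, 0.95, 20), 2)


def empirical_pvalue(t, null):
    """p = (1 + #{t0 >= t}) / (1 + R) via binary search on the sorted null.

    Accepts a scalar or an array of observed statistics.
    """
    t0 = null.t0
    r = len(t0)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    exceed = r - np.searchsorted(t0, t_arr, side="left")
    p = (1.0 + exceed) / (1.0 + r)
    return float(p[0]) if np.isscalar(t) or np.ndim(t) == 0 else p


def estimate_pi0(pvals, lambda_grid=None):
    """Storey estimate of the null fraction pi0.

    pi0(lambda) = #{p > lambda} / ((1 - lambda) * M) is evaluated on the
    grid (default 0, 0.05, ..., 0.95), a cubic polynomial is fit and read
    off at the largest lambda (Storey-Tibshirani smoother), and the
    result is clipped to (0, 1].  With fewer than 100 p-values the
    smoother is unreliable and the single-point estimate at lambda = 0.5
    is used instead.  If no p-value exceeds max(lambda), falls back to
    pi0 = 1 with a warning.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(
        lambda_grid, dtype=float
    )
    if np.any((grid < 0) | (grid >= 1)):
        raise ValueError("lambda grid must lie in [0, 1)")
    m = p.size

    if not np.any(p > grid.max()):
        warnings.warn(
            "all p-values <= max(lambda): pi0 not estimable, using pi0=1",
            stacklevel=2,
        )
        return 1.0
    if grid.size == 1:
        lam = float(grid[0])
        pi0 = np.mean(p > lam) / (1.0 - lam)
    elif m < 100:
        pi0 = np.mean(p > 0.5) / 0.5
    else:
        grid = np.sort(grid)
        pi0_lam = np.array([np.mean(p > lam) / (1.0 - lam) for lam in grid])
        coef = np.polyfit(grid, pi0_lam, deg=3)
        pi0 = float(np.polyval(coef, grid.max()))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(pvals, pi0=None):
    """q(p_i) = min over h >= p_i of pi0*M*h / #{p <= h}, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    ranks = np.searchsorted(ps, ps, side="right")  # ties inclusive
    fdr = pi0 * m * ps / ranks
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def adjust(pvals, method: str = "qvalue"):
    """Multiple-testing adjustment; returns (adjusted values, pi0 or None).

    method is one of 'qvalue' (Storey), 'bh', 'by', 'bonferroni', 'holm'.
    """
    p = np.asarray(pvals, dtype=float)
    if method == "qvalue":
        if p.size == 0:
            return np.empty(0), None
        pi0 = estimate_pi0(p)
        return storey_qvalues(p, pi0), pi0
    if method in _SM_METHODS:
        if p.size == 0:
            return np.empty(0), None
        return multipletests(p, method=_SM_METHODS[method])[1], None
    raise ValueError(
        f"unknown method {method!r}; valid methods: {', '.join(METHODS)}"
    )


def pvalue_histogram(pvals, n_bins: int = 20):
    """Equal-width bin counts of the p-values on [0, 1] (diagnostic).

    A flat right tail supports the uniform-null assumption behind pi0.
    """
    p = np.asarray(pvals, dtype=float)
    counts, _ = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    return counts


def plot_pvalue_histogram(pvals, path, n_bins: int = 20):
    """Write the diagnostic p-value histogram as a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(np.asarray(pvals, dtype=float), bins=n_bins, range=(0, 1),
            edgecolor="white")
    ax.set_xlabel("empirical p-value")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def check_pvalue_floor(r: int, m: int, threshold: float) -> None:
    """Warn when R is too small for any pair to reach the threshold.

    The smallest attainable p-value is 1/(1+R); if that exceeds
    threshold/M even a Bonferroni-scale correction can never call a pair
    significant.
    """
    floor = 1.0 / (1.0 + r)
    if m > 0 and floor > threshold / m:
        warnings.warn(
            f"p-value floor 1/(1+R)={floor:.3g} exceeds threshold/M="
            f"{threshold / m:.3g}: increase the number of permutations R",
            stacklevel=2,
        )
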