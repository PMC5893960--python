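"""Synthetic benchmark generators with ground truth.

Three families emulate the screening conditions under which power and
FDR control can be scored exactly:

* ``sd_generate`` -- pairs (X, Y) where a configurable fraction (the
  "effect chance" = 1 - pi0) follows Y = f(X) + eta for one of six
  functional forms with uniform additive noise of intensity k_eta, and
  the rest are independent uniforms.  The realized coefficient of
  determination R^2 = Var(f(X))/Var(Y) spans roughly (0, 1) over the
  k_eta pool.
* ``madelon_generate`` -- a binary-classification table in the style of
  the Madelon benchmark: 4 Gaussian clusters (sigma = 1) on vertices of
  a 5-D hypercube give 5 informative features, 15 redundant features are
  random linear combinations of them, and 180 i.i.d. N(0,1) noise
  features are appended, for 200 variables in total.  All C(20,2) = 190
  pairs among the non-random variables are truly dependent.
* ``score_detection`` -- power / FDR / FN accounting of a screening
  result against the generator's truth table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.datasets import make_classification

__all__ = [
    "FUNCTION_NAMES",
    "noise_pool",
    "eval_function",
    "sd_generate",
    "madelon_generate",
    "score_detection",
    "DetectionScore",
]

FUNCTION_NAMES = ("cubic", "exponential", "line", "parabola", "sigmoid",
                  "spike")

# piecewise-linear spike: sharp rise to 1 at x=0.05, drop to 0.1 at
# x=0.1, slow decay to 0 at x=1
_SPIKE_XP = np.array([0.0, 0.05, 0.1, 1.0])
_SPIKE_FP = np.array([0.0, 1.0, 0.1, 0.0])


def eval_function(f_name: str, x):
    """Evaluate one of the six functional forms on x in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if f_name == "line":
        return x.copy()
    if f_name == "parabola":
        return 4.0 * (x - 0.5) ** 2
    if f_name == "cubic":
        u = 2.0 * x - 1.0
        return 4.0 * u ** 3 - 3.0 * u
    if f_name == "exponential":
        return 2.0 ** x
    if f_name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-20.0 * (x - 0.5)))
    if f_name == "spike":
        return np.interp(x, _SPIKE_XP, _SPIKE_FP)
    raise ValueError(
        f"unknown function {f_name!r}; valid names: {', '.join(FUNCTION_NAMES)}"
    )


def noise_pool() -> np.ndarray:
    """The 18,000-value pool of noise intensities k_eta.

    Three half-open arithmetic sequences: [0.05, 1) step 1e-4 (9,500
    values), [1, 2) step 2e-4 (5,000) and [2, 9) step 2e-3 (3,500).
    """
    return np.concatenate(
        [
            0.05 + 1e-4 * np.arange(9_500),
            1.0 + 2e-4 * np.arange(5_000),
            2.0 + 2e-3 * np.arange(3_500),
        ]
    )


def sd_generate(
    n_pairs: int,
    effect_chance: float,
    n_samples: int,
    seed: int = 0,
):
    """Functional-association benchmark (SD1/SD2 family).

    Exactly ``n_pairs * effect_chance`` pairs (must be integral) follow
    Y = f(X) + eta with f drawn uniformly from the six forms, X uniform
    on [0, 1] and eta = k_eta * U(-1/2, 1/2) * (max f - min f) with
    k_eta drawn from :func:`noise_pool`; the remaining pairs are
    independent uniforms on both coordinates.

    Returns (X, Y, truth): two n_pairs-by-n_samples DataFrames whose
    rows pair up row-wise, and a truth table with the per-pair
    is_dependent flag, functional form, k_eta and realized
    R^2 = Var(f(X))/Var(Y).
    """
    if not 0.0 < effect_chance <= 1.0:
        raise ValueError(f"effect chance must be in (0, 1], got {effect_chance}")
    n_dep_f = n_pairs * effect_chance
    n_dep = round(n_dep_f)
    if abs(n_dep_f - n_dep) > 1e-9:
        raise ValueError(
            f"n_pairs * effect_chance = {n_dep_f} is not an integer"
        )
    rng = np.random.default_rng(seed)
    pool = noise_pool()

    X = np.empty((n_pairs, n_samples))
    Y = np.empty((n_pairs, n_samples))
    f_names = np.empty(n_pairs, dtype=object)
    k_etas = np.full(n_pairs, np.nan)
    r2 = np.full(n_pairs, np.nan)

    for i in range(n_dep):
        x = rng.uniform(size=n_samples)
        f = FUNCTION_NAMES[rng.integers(len(FUNCTION_NAMES))]
        k = pool[rng.integers(len(pool))]
        fx = eval_function(f, x)
        eta = k * rng.uniform(-0.5, 0.5, size=n_samples) * np.ptp(fx)
        y = fx + eta
        X[i] = x
        Y[i] = y
        f_names[i] = f
        k_etas[i] = k
        vy = y.var()
        r2[i] = min(fx.var() / vy, 1.0) if vy > 0 else 1.0

    if n_dep < n_pairs:
        X[n_dep:] = rng.uniform(size=(n_pairs - n_dep, n_samples))
        Y[n_dep:] = rng.uniform(size=(n_pairs - n_dep, n_samples))

    xids = [f"x_{i:06d}" for i in range(n_pairs)]
    yids = [f"y_{i:06d}" for i in range(n_pairs)]
    samples = [f"s_{j:05d}" for j in range(n_samples)]
    truth = pd.DataFrame(
        {
            "var_x": xids,
            "var_y": yids,
            "is_dependent": np.arange(n_pairs) < n_dep,
            "f_name": f_names,
            "k_eta": k_etas,
            "r2": r2,
        }
    )
    return (
        pd.DataFrame(X, index=xids, columns=samples),
        pd.DataFrame(Y, index=yids, columns=samples),
        truth,
    )


def madelon_generate(n_samples: int, seed: int = 0):
    """Madelon-style cluster benchmark.

    Returns (data, truth, labels): a 200-by-n_samples DataFrame
    (5 informative + 15 redundant + 180 random variables), a truth table
    over all 19,900 variable pairs (in within-mode enumeration order)
    with relation classes II / IR / RR / null, and the per-sample binary
    class labels.
    """
    if n_samples < 8:
        raise ValueError(f"need at least 8 samples (2 per cluster), got {n_samples}")
    features, labels = make_classification(
        n_samples=n_samples,
        n_features=200,
        n_informative=5,
        n_redundant=15,
        n_repeated=0,
        n_classes=2,
        n_clusters_per_class=2,
        class_sep=2.0,
        flip_y=0.0,
        hypercube=True,
        shuffle=False,
        random_state=seed,
    )
    var_ids = (
        [f"inf_{i:02d}" for i in range(5)]
        + [f"red_{i:02d}" for i in range(15)]
        + [f"rnd_{i:03d}" for i in range(180)]
    )
    samples = [f"s_{j:05d}" for j in range(n_samples)]
    data = pd.DataFrame(features.T, index=var_ids, columns=samples)

    def role(v):
        return v.split("_")[0]

    rel_class = {
        ("inf", "inf"): "II",
        ("inf", "red"): "IR",
        ("red", "inf"): "IR",
        ("red", "red"): "RR",
    }
    rows = []
    for vx, vy in combinations(var_ids, 2):
        cls = rel_class.get((role(vx), role(vy)), "null")
        rows.append((vx, vy, cls != "null", cls))
    truth = pd.DataFrame(rows, columns=["var_x", "var_y", "is_dependent",
                                        "relation"])
    return data, truth, pd.Series(labels, index=samples, name="class")


@dataclass(frozen=True)
class DetectionScore:
    power: float
    tp: int
    fp: int
    fn: int
    fdr: float


def score_detection(
    results: pd.DataFrame,
    truth: pd.DataFrame,
    threshold: float = 0.05,
    adjusted_col: str = "adjusted",
) -> DetectionScore:
    """Score a screening result against ground truth.

    power = TP / #dependent, fdr = FP / max(TP+FP, 1),
    fn = #dependent - TP.  ``results`` and ``truth`` must cover the
    identical set of (var_x, var_y) pairs.
    """
    key = ["var_x", "var_y"]
    rk = set(map(tuple, results[key].itertuples(index=False)))
    tk = set(map(tuple, truth[key].itertuples(index=False)))
    if rk != tk:
        raise ValueError(
            f"results and truth cover different pairs "
            f"({len(rk - tk)} extra, {len(tk - rk)} missing)"
        )
    merged = results.merge(truth[key + ["is_dependent"]], on=key)
    called = merged[adjusted_col] < threshold
    dep = merged["is_dependent"].to_numpy(dtype=bool)
    tp = int(np.sum(called & dep))
    fp = int(np.sum(called & ~dep))
    n_dep = int(dep.sum())
    return DetectionScore(
        power=tp / n_dep if n_dep else 0.0,
        tp=tp,
        fp=fp,
        fn=n_dep - tp,
        fdr=fp / max(tp + fp, 1),
    )
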