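"""End-to-end association screening over TSV variable matrices.

Input matrices are tab-delimited text: first column variable ids, header
row sample ids, variables as rows.  The four pipeline steps are

  1. build (or reuse) the shared permutation null of TIC_e,
  2. compute TIC_e per pair and its empirical p-value,
  3. multiple-testing correction (Storey q-values by default),
  4. MIC_e strength for the pairs that pass the threshold.

Three experiment modes cover the pair enumeration: ``within`` (all
M(M-1)/2 pairs of one matrix), ``cross`` (all M*K pairs of two
matrices) and ``rowwise`` (pairs (x_i, y_i), i <= min(M, K)).  With
sample class labels the whole analysis runs independently within each
class, each with its own class-sized null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .estimators import MineParams, prepare_rank_matrix, stats_many
from .null import DEFAULT_PERMUTATIONS, NullDistribution, build_null
from .significance import adjust, check_pvalue_floor, empirical_pvalue
from .strength import strength_table

__all__ = [
    "read_matrix",
    "write_matrix",
    "enumerate_pairs",
    "PipelineConfig",
    "compute_tic_table",
    "run_pipeline",
    "stratified_run",
]

MODES = ("within", "cross", "rowwise")


def read_matrix(path, drop_missing: bool = True) -> pd.DataFrame:
    """Read a variables-by-samples TSV matrix.

    Lines starting with '#' are ignored.  Duplicate variable ids and
    non-numeric cells are hard errors; rows containing missing values
    are dropped with a warning (the shared null assumes one common n).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate variable id(s): {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample id(s): {dups}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            line = df.index.get_loc(bad.index[0]) + 2  # header is line 1
            raise ValueError(
                f"{path}: non-numeric value {bad.iloc[0]!r} for variable "
                f"{bad.index[0]!r} (line {line}, sample {col!r})"
            )
    na_rows = df.isna().any(axis=1)
    if na_rows.any():
        if drop_missing:
            warnings.warn(
                f"{path}: dropped {int(na_rows.sum())} variable(s) with "
                "missing values",
                stacklevel=2,
            )
            df = df.loc[~na_rows]
        else:
            raise ValueError(
                f"{path}: missing values in variable(s) "
                f"{df.index[na_rows].tolist()}"
            )
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError(f"{path}: non-finite values in matrix")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path, header_comment: str | None = None):
    """Write a variables-by-samples TSV matrix (optional '#' header)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index_label="")


def enumerate_pairs(x: pd.DataFrame, y: pd.DataFrame | None = None,
                    mode: str = "within"):
    """Ordered (var_x, var_y) pairs plus row-index arrays for the mode."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; valid modes: {MODES}")
    if mode == "within":
        m = len(x)
        ix, iy = map(
            np.asarray, zip(*combinations(range(m), 2))
        ) if m > 1 else (np.empty(0, int), np.empty(0, int))
        names_x = x.index.to_numpy()
        return names_x[ix], names_x[iy], ix, iy
    if y is None:
        raise ValueError(f"mode {mode!r} requires a second matrix")
    if list(x.columns) != list(y.columns):
        raise ValueError("matrices must share identical sample columns")
    if mode == "cross":
        ix, iy = map(
            np.ravel, np.meshgrid(range(len(x)), range(len(y)), indexing="ij")
        )
    else:  # rowwise
        k = min(len(x), len(y))
        ix = iy = np.arange(k)
    return x.index.to_numpy()[ix], y.index.to_numpy()[iy], ix, iy


@dataclass(frozen=True)
class PipelineConfig:
    mode: str = "within"
    permutations: int = DEFAULT_PERMUTATIONS
    params: MineParams = field(default_factory=MineParams)
    method: str = "qvalue"
    threshold: float = 0.05
    seed: int = 0
    strength_alpha: float | None = None  # None: schedule by sample size

    def describe(self) -> str:
        return (
            f"mode={self.mode}\tR={self.permutations}\tB={self.params.b}"
            f"\tc={self.params.c}\tmethod={self.method}"
            f"\tthreshold={self.threshold}\tseed={self.seed}"
        )


def compute_tic_table(x: pd.DataFrame, y: pd.DataFrame | None = None,
                      mode: str = "within",
                      params: MineParams = MineParams()) -> pd.DataFrame:
    """TIC_e for every enumerated pair: columns var_x, var_y, tic_e."""
    names_x, names_y, ix, iy = enumerate_pairs(x, y, mode)
    gx, ngx, ox = prepare_rank_matrix(x.to_numpy())
    if y is None or y is x:
        gy, ngy, oy = gx, ngx, ox
    else:
        gy, ngy, oy = prepare_rank_matrix(y.to_numpy())
    _, tic = stats_many(gx, ngx, ox, gy, ngy, oy, ix, iy, params)
    return pd.DataFrame({"var_x": names_x, "var_y": names_y, "tic_e": tic})


def run_pipeline(
    x: pd.DataFrame,
    y: pd.DataFrame | None = None,
    config: PipelineConfig = PipelineConfig(),
    null: NullDistribution | None = None,
    outdir=None,
) -> pd.DataFrame:
    """Run steps 1-4 and return the association table.

    The returned DataFrame has one row per enumerated pair with columns
    (var_x, var_y, tic_e, pval, adjusted, mic_e); mic_e is NaN for
    pairs below the significance threshold.  ``df.attrs`` records pi0
    (q-value method) and the full configuration.  A pre-built null is
    reused when its (n, B, c) match the data; a mismatch is a hard
    error.  With ``outdir`` the per-step TSVs and a run log are written.
    """
    n = x.shape[1]
    if y is not None and list(x.columns) != list(y.columns):
        raise ValueError("matrices must share identical sample columns")

    if null is None:
        null = build_null(n, config.permutations, config.params, config.seed)
    elif null.n != n or null.params != config.params:
        raise ValueError(
            f"null (n={null.n}, B={null.params.b}, c={null.params.c}) does "
            f"not match data (n={n}, B={config.params.b}, c={config.params.c})"
        )

    table = compute_tic_table(x, y, config.mode, config.params)
    check_pvalue_floor(null.r, len(table), config.threshold)
    table["pval"] = empirical_pvalue(table["tic_e"].to_numpy(), null)
    adjusted, pi0 = adjust(table["pval"].to_numpy(), config.method)
    table["adjusted"] = adjusted

    strengths = strength_table(
        table, x, y, threshold=config.threshold, alpha=config.strength_alpha,
        c=config.params.c,
    )
    table = table.merge(
        strengths[["var_x", "var_y", "mic_e"]], on=["var_x", "var_y"],
        how="left",
    )
    table.attrs["pi0"] = pi0
    table.attrs["config"] = config.describe()

    if outdir is not None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        hdr = config.describe()
        with open(out / "associations.tsv", "w") as fh:
            fh.write(f"# {hdr}\tpi0={pi0}\n")
            table.to_csv(fh, sep="\t", index=False)
        with open(out / "strength.tsv", "w") as fh:
            fh.write(f"# {hdr}\n")
            strengths.to_csv(fh, sep="\t", index=False)
        with open(out / "run.log", "w") as fh:
            fh.write(f"{hdr}\tn={n}\tpairs={len(table)}\tpi0={pi0}\n")
    return table


def stratified_run(
    x: pd.DataFrame,
    labels,
    y: pd.DataFrame | None = None,
    config: PipelineConfig = PipelineConfig(),
    min_class_size: int = 5,
) -> dict:
    """Run the pipeline independently within each sample class.

    ``labels`` maps every sample id to a class.  Each class gets its own
    null at the class sample size; classes below ``min_class_size`` are
    skipped with a warning.  Returns {class: association table}.
    """
    labels = pd.Series(labels)
    missing = [c for c in x.columns if c not in labels.index]
    if missing:
        raise ValueError(f"unlabeled sample(s): {missing}")
    out = {}
    for cls, members in labels.groupby(labels).groups.items():
        cols = [c for c in x.columns if c in set(members)]
        if len(cols) < min_class_size:
            warnings.warn(
                f"class {cls!r} has {len(cols)} samples "
                f"(< {min_class_size}); skipped",
                stacklevel=2,
            )
            continue
        out[cls] = run_pipeline(
            x[cols], None if y is None else y[cols], config=config
        )
    return out
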