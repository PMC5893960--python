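"""Empirical TIC_e null distribution by permutation.

TIC_e depends on the data only through rank order, so under independence
its distribution for a given sample size n and parameter set (B, c) does
not depend on the marginals: one null, built by permuting a tie-free
rank sequence against a fixed one, is shared by every variable pair with
the same (n, B, c).  Real data with ties then yields slightly
conservative p-values (ties can only lower the statistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import _tic_null_batch
from .estimators import MineParams

__all__ = ["NullDistribution", "build_null", "save_null", "load_null"]

DEFAULT_PERMUTATIONS = 200_000

_CHUNK = 4096  # fixed so the RNG stream (and thus t0) never depends on R


@dataclass(frozen=True)
class NullDistribution:
    """Sorted null statistics t0_1 <= ... <= t0_R for one (n, B, c)."""

    n: int
    r: int
    params: MineParams
    seed: int
    t0: np.ndarray

    def __post_init__(self):
        if len(self.t0) != self.r:
            raise ValueError("t0 length must equal R")


def build_null(
    n: int,
    r: int = DEFAULT_PERMUTATIONS,
    params: MineParams = MineParams(),
    seed: int = 0,
) -> NullDistribution:
    """R permutation TIC_e statistics at sample size n, sorted ascending."""
    if n < 5:
        raise ValueError(f"need at least 5 samples, got n={n}")
    if r < 1:
        raise ValueError(f"need at least 1 permutation, got R={r}")
    rng = np.random.default_rng(seed)
    t0 = np.empty(r)
    base = np.arange(n, dtype=np.int64)
    done = 0
    while done < r:
        m = min(_CHUNK, r - done)
        perms = rng.permuted(np.broadcast_to(base, (m, n)), axis=1)
        _tic_null_batch(perms.astype(np.int64), params.b, params.c,
                        t0[done:done + m])
        done += m
    t0.sort()
    return NullDistribution(n=n, r=r, params=params, seed=seed, t0=t0)


def save_null(null: NullDistribution, path) -> None:
    """Write a null archive: versioned '#' header plus one value per line."""
    with open(path, "w") as fh:
        fh.write("# micscreen-null v1\n")
        fh.write(
            f"# n={null.n}\tR={null.r}\tB={null.params.b}"
            f"\tc={null.params.c}\tseed={null.seed}\n"
        )
        for v in null.t0:
            fh.write(f"{v:.17g}\n")


def load_null(path, n=None, r=None, params=None) -> NullDistribution:
    """Read a null archive, optionally checking it matches the analysis.

    A null is only valid for matching sample size and estimator
    parameters; any requested value that disagrees with the header is a
    hard error, as is a truncated or malformed file.
    """
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != "# micscreen-null v1":
            raise ValueError(f"{path}: not a micscreen null archive")
        header = fh.readline().strip()
        try:
            fields = dict(
                item.split("=") for item in header.lstrip("# ").split("\t")
            )
            hn = int(fields["n"])
            hr = int(fields["R"])
            hp = MineParams(b=int(fields["B"]), c=int(fields["c"]))
            hseed = int(fields["seed"])
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: malformed null header: {header}") from exc
        try:
            t0 = np.array([float(line) for line in fh])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed null value") from exc
    if len(t0) != hr:
        raise ValueError(
            f"{path}: truncated archive ({len(t0)} values, header says {hr})"
        )
    for name, want, got in (
        ("n", n, hn),
        ("R", r, hr),
        ("params", params, hp),
    ):
        if want is not None and want != got:
            raise ValueError(
                f"{path}: null {name}={got} does not match requested {want}"
            )
    return NullDistribution(n=hn, r=hr, params=hp, seed=hseed, t0=t0)
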