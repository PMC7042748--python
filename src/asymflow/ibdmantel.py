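"""Mantel matrix-correspondence test and isolation-by-distance regression.

The Mantel statistic used here is the raw lower-triangle cross-product
Z = sum_{i<j} X_ij * Y_ij; the null distribution comes from jointly
permuting the row/column order of one matrix.  The one-sided (positive
association) p-value is reported by default, as isolation by distance
predicts genetic distance increasing with waterway distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PairwiseMatrix:
    """Symmetric group x group distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    units: str = ""  # e.g. "linearized_fst" or "metres"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if len(set(self.labels)) != k:
            raise ValueError("labels must be unique")
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    @classmethod
    def from_long(cls, df: pd.DataFrame, units: str = "") -> "PairwiseMatrix":
        """Build from long-format rows group_a,group_b,value."""
        labels: list[str] = []
        for col in ("group_a", "group_b"):
            for g in df[col]:
                if g not in labels:
                    labels.append(g)
        k = len(labels)
        m = np.zeros((k, k))
        pos = {g: i for i, g in enumerate(labels)}
        for r in df.itertuples():
            i, j = pos[r.group_a], pos[r.group_b]
            m[i, j] = m[j, i] = float(r.value)
        return cls(labels=labels, values=m, units=units)

    @classmethod
    def from_csv(cls, path, units: str = "") -> "PairwiseMatrix":
        df = pd.read_csv(path)
        if {"group_a", "group_b", "value"} <= set(df.columns):
            return cls.from_long(df, units=units)
        labels = df.columns[1:].tolist()
        return cls(labels=labels, values=df[labels].to_numpy(), units=units)

    def lower_triangle(self) -> np.ndarray:
        idx = np.tril_indices(len(self.labels), k=-1)
        return self.values[idx]

    def subset(self, labels: list[str]) -> "PairwiseMatrix":
        pos = [self.labels.index(g) for g in labels]
        return PairwiseMatrix(
            labels=list(labels),
            values=self.values[np.ix_(pos, pos)],
            units=self.units,
        )


@dataclass
class MantelResult:
    z: float
    p: float
    n_perm: int
    seed: int
    two_sided: bool = False


def _check_aligned(x: PairwiseMatrix, y: PairwiseMatrix) -> None:
    if x.labels != y.labels:
        raise ValueError("matrices must share labels in the same order")
    if len(x.labels) < 3:
        raise ValueError("need at least 3 groups")


def mantel_test(
    x: PairwiseMatrix,
    y: PairwiseMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    two_sided: bool = False,
) -> MantelResult:
    """Mantel test of matrix correspondence.

    Z = sum over unordered pairs of X_ij * Y_ij.  The permutation null
    reorders the rows and columns of Y jointly; p = (1 + #{extreme}) /
    (1 + n_perm) with Z_perm >= Z_obs as the one-sided criterion (absolute
    deviation from the permutation mean when ``two_sided``).
    """
    _check_aligned(x, y)
    xv = x.lower_triangle()
    if np.allclose(y.lower_triangle(), y.lower_triangle()[0]) or np.allclose(
        xv, xv[0]
    ):
        raise ValueError("constant matrix: Mantel p undefined")
    rng = np.random.default_rng(seed)
    k = len(x.labels)
    z_obs = float(np.sum(xv * y.lower_triangle()))
    z_perm = np.empty(n_perm)
    tril = np.tril_indices(k, k=-1)
    for b in range(n_perm):
        order = rng.permutation(k)
        z_perm[b] = float(np.sum(xv * y.values[np.ix_(order, order)][tril]))
    if two_sided:
        center = z_perm.mean()
        hits = np.sum(np.abs(z_perm - center) >= abs(z_obs - center) - 1e-12)
    else:
        hits = np.sum(z_perm >= z_obs - 1e-12)
    return MantelResult(
        z=z_obs, p=float((1 + hits) / (1 + n_perm)), n_perm=n_perm, seed=seed,
        two_sided=two_sided,
    )


@dataclass
class IbdFit:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n_pairs: int


def ibd_regression(x_geo: PairwiseMatrix, y_gen: PairwiseMatrix) -> IbdFit:
    """OLS of unfolded genetic distance on geographic distance."""
    _check_aligned(x_geo, y_gen)
    xv = x_geo.lower_triangle()
    yv = y_gen.lower_triangle()
    if xv.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.allclose(yv, yv[0]):
        return IbdFit(slope=0.0, intercept=float(yv[0]), r_squared=0.0, p=1.0,
                      n_pairs=int(xv.size))
    fit = stats.linregress(xv, yv)
    return IbdFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n_pairs=int(xv.size),
    )


def load_catchment_fixture() -> tuple[PairwiseMatrix, PairwiseMatrix]:
    """Packaged Burrishoole-catchment distance matrices.

    Returns (geographic metres, linearized-FST genetic distance) for the six
    geographic groups, as published for the study catchment.
    """
    with resources.files("asymflow.data").joinpath("catchment_distances.csv").open() as fh:
        df = pd.read_csv(fh)
    geo = PairwiseMatrix.from_long(
        df.rename(columns={"geographic_m": "value"})[["group_a", "group_b", "value"]],
        units="metres",
    )
    gen = PairwiseMatrix.from_long(
        df.rename(columns={"linearized_fst": "value"})[["group_a", "group_b", "value"]],
        units="linearized_fst",
    )
    return geo, gen
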