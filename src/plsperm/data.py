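"""Two-block data container, column standardisation, and cross-correlation.

The unit of analysis is a pair of numeric matrices with matched rows: a
"brain" block ``X`` (n observations x p features) and a "behaviour" block
``Y`` (n x q).  The block names follow the neuroimaging convention where the
larger block is called brain, but nothing in the code depends on the labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["TwoBlockDataset", "zscore_columns", "cross_correlation"]


def _as_matrix(M, name: str) -> np.ndarray:
    arr = np.asarray(M, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


def zscore_columns(M: np.ndarray, names: Sequence[str] | None = None) -> np.ndarray:
    """Standardise each column to mean 0 and unit sample variance.

    Uses the n-1 (sample) variance denominator so that the cross-correlation
    ``X_z^T Y_z / (n-1)`` of two standardised blocks holds exact Pearson
    correlations.

    Parameters
    ----------
    M : array_like, shape (n, m)
        Input matrix with n >= 2 rows.
    names : sequence of str, optional
        Column labels used in error messages.

    Returns
    -------
    ndarray of the same shape with standardised columns.

    Raises
    ------
    ValueError
        If a column is constant (zero variance), naming the column.
    """
    arr = _as_matrix(M, "M")
    if arr.shape[0] < 2:
        raise ValueError("z-scoring requires at least 2 rows")
    # ptp == 0 is an exact constancy test, immune to round-off in the mean
    constant = np.ptp(arr, axis=0) == 0
    if constant.any():
        j = int(np.flatnonzero(constant)[0])
        label = names[j] if names is not None else f"column {j}"
        raise ValueError(f"zero-variance column: {label}")
    sd = arr.std(axis=0, ddof=1)
    return (arr - arr.mean(axis=0)) / sd


@dataclass
class TwoBlockDataset:
    """Paired data blocks with matched rows and named feature columns.

    Invariants enforced at construction: both blocks are 2-D and finite,
    share the same number of rows n >= 3, and contain no constant column
    (standardisation would be undefined).
    """

    X: np.ndarray
    Y: np.ndarray
    feature_names_x: list[str] = field(default=None)  # type: ignore[assignment]
    feature_names_y: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = _as_matrix(self.X, "X")
        self.Y = _as_matrix(self.Y, "Y")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X and Y must have the same number of rows: "
                f"{self.X.shape[0]} != {self.Y.shape[0]}"
            )
        if self.X.shape[0] < 3:
            raise ValueError("at least 3 observations are required")
        if self.feature_names_x is None:
            self.feature_names_x = [f"x{j}" for j in range(self.X.shape[1])]
        if self.feature_names_y is None:
            self.feature_names_y = [f"y{j}" for j in range(self.Y.shape[1])]
        self.feature_names_x = [str(s) for s in self.feature_names_x]
        self.feature_names_y = [str(s) for s in self.feature_names_y]
        if len(self.feature_names_x) != self.X.shape[1]:
            raise ValueError("feature_names_x length does not match X")
        if len(self.feature_names_y) != self.Y.shape[1]:
            raise ValueError("feature_names_y length does not match Y")
        for block, names in ((self.X, self.feature_names_x), (self.Y, self.feature_names_y)):
            constant = np.ptp(block, axis=0) == 0
            if constant.any():
                j = int(np.flatnonzero(constant)[0])
                raise ValueError(f"zero-variance column: {names[j]}")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Y.shape[1]

    @property
    def k(self) -> int:
        """Number of latent variables, min(p, q)."""
        return min(self.p, self.q)

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_dataframes(cls, x: pd.DataFrame, y: pd.DataFrame) -> "TwoBlockDataset":
        return cls(
            x.to_numpy(dtype=float),
            y.to_numpy(dtype=float),
            feature_names_x=list(map(str, x.columns)),
            feature_names_y=list(map(str, y.columns)),
        )

    @classmethod
    def from_files(cls, x_path, y_path) -> "TwoBlockDataset":
        """Read blocks from delimited text (header row of names) or ``.npy``."""
        X, names_x = _read_block(x_path)
        Y, names_y = _read_block(y_path)
        return cls(X, Y, names_x, names_y)

    # -- derived views ---------------------------------------------------
    def zscored(self) -> tuple[np.ndarray, np.ndarray]:
        """Both blocks standardised columnwise (n-1 convention)."""
        return (
            zscore_columns(self.X, self.feature_names_x),
            zscore_columns(self.Y, self.feature_names_y),
        )

    def subset(self, rows: np.ndarray) -> "TwoBlockDataset":
        """Dataset restricted to (or resampled over) the given row indices."""
        rows = np.asarray(rows)
        return TwoBlockDataset(
            self.X[rows], self.Y[rows], self.feature_names_x, self.feature_names_y
        )


def _read_block(path):
    path = str(path)
    if path.endswith(".npy"):
        arr = np.load(path)
        return arr, None
    df = pd.read_csv(path, sep=None, engine="python")
    return df.to_numpy(dtype=float), list(map(str, df.columns))


def cross_correlation(data: TwoBlockDataset) -> np.ndarray:
    """Pearson cross-correlation matrix C = X_z^T Y_z / (n-1).

    Entry (i, j) is the correlation between X feature i and Y feature j;
    the matrix is p x q and every entry lies in [-1, 1] up to round-off.
    """
    Xz, Yz = data.zscored()
    return (Xz.T @ Yz) / (data.n - 1)
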