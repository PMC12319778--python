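"""Partial least squares correlation: model and results objects.

The PLS correlation (behavioural PLS) decomposes the Pearson
cross-correlation matrix between two data blocks,

    C = X_z^T Y_z / (n - 1) = U S V^T,

into latent variables (LVs): matched columns of U (brain weights) and V
(behaviour weights) with a singular value measuring the cross-block
covariance the pair captures.  Squared singular values normalised by their
sum give each LV's fraction of covariance explained.

``PLSCorrelation`` is the model object (holds the data); ``fit`` returns a
``PLSResults`` carrying the decomposition together with inference and
diagnostic methods (permutation tests, split-half stability, bootstrap
feature reliability).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TwoBlockDataset, cross_correlation

__all__ = ["PLSDecomposition", "decompose", "PLSCorrelation", "PLSResults"]


@dataclass
class PLSDecomposition:
    """SVD of the cross-correlation matrix, one latent variable per column.

    Attributes
    ----------
    U : ndarray, shape (p, k)
        Left singular vectors (brain feature weights), orthonormal columns.
    V : ndarray, shape (q, k)
        Right singular vectors (behaviour feature weights).
    singular_values : ndarray, shape (k,)
        Nonincreasing, nonnegative.
    covariance_explained : ndarray, shape (k,)
        ``s_i^2 / sum_j s_j^2``; sums to 1.
    k : int
        Number of latent variables, always min(p, q) — trailing near-zero
        singular values are retained so null-distribution bookkeeping has a
        fixed LV count.
    """

    U: np.ndarray
    V: np.ndarray
    singular_values: np.ndarray
    covariance_explained: np.ndarray
    k: int


def _svd_with_sign_convention(C: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    V = Vt.T
    # SVD signs are arbitrary; make the largest-|.| element of each V column
    # positive so repeated runs produce identical output.
    flip = V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])] < 0
    U[:, flip] *= -1.0
    V[:, flip] *= -1.0
    return U, s, V


def decompose(data: TwoBlockDataset) -> PLSDecomposition:
    """Singular value decomposition of the cross-correlation matrix.

    Returns exactly k = min(p, q) latent variables ranked by singular value,
    with a deterministic sign convention (largest-magnitude element of each
    V column positive).
    """
    C = cross_correlation(data)
    U, s, V = _svd_with_sign_convention(C)
    total = float((s**2).sum())
    cov = s**2 / total if total > 0 else np.zeros_like(s)
    return PLSDecomposition(
        U=U, V=V, singular_values=s, covariance_explained=cov, k=int(s.size)
    )


class PLSCorrelation:
    """PLS correlation model for a pair of matched data blocks.

    Parameters
    ----------
    X, Y : array_like or TwoBlockDataset
        If ``X`` is a :class:`TwoBlockDataset`, ``Y`` must be omitted.
        Otherwise two matrices with matched rows (observations).
    feature_names_x, feature_names_y : sequence of str, optional
        Column labels; defaults are generated.

    Examples
    --------
    >>> model = PLSCorrelation(X, Y)
    >>> res = model.fit()
    >>> res.singular_values
    >>> nulls = res.permutation_test(method="behaviour", n_perm=1000, seed=0)
    """

    def __init__(self, X, Y=None, feature_names_x=None, feature_names_y=None):
        if isinstance(X, TwoBlockDataset):
            if Y is not None:
                raise ValueError("pass either a TwoBlockDataset or two matrices")
            self.data = X
        else:
            self.data = TwoBlockDataset(X, Y, feature_names_x, feature_names_y)

    @classmethod
    def from_dataframes(cls, x: pd.DataFrame, y: pd.DataFrame) -> "PLSCorrelation":
        return cls(TwoBlockDataset.from_dataframes(x, y))

    @classmethod
    def from_files(cls, x_path, y_path) -> "PLSCorrelation":
        return cls(TwoBlockDataset.from_files(x_path, y_path))

    def fit(self) -> "PLSResults":
        return PLSResults(self.data, decompose(self.data))


class PLSResults:
    """Fitted PLS correlation: decomposition plus inference methods."""

    def __init__(self, data: TwoBlockDataset, decomposition: PLSDecomposition):
        self.data = data
        self.decomposition = decomposition

    # decomposition attributes, flattened for convenience
    @property
    def U(self) -> np.ndarray:
        return self.decomposition.U

    @property
    def V(self) -> np.ndarray:
        return self.decomposition.V

    @property
    def singular_values(self) -> np.ndarray:
        return self.decomposition.singular_values

    @property
    def covariance_explained(self) -> np.ndarray:
        return self.decomposition.covariance_explained

    @property
    def k(self) -> int:
        return self.decomposition.k

    def x_scores(self) -> np.ndarray:
        """Latent scores of the X block: X_z U, shape (n, k)."""
        Xz, _ = self.data.zscored()
        return Xz @ self.U

    def y_scores(self) -> np.ndarray:
        """Latent scores of the Y block: Y_z V, shape (n, k)."""
        _, Yz = self.data.zscored()
        return Yz @ self.V

    # -- inference -------------------------------------------------------
    def permutation_test(self, method: str = "behaviour", n_perm: int = 10_000,
                         seed: int = 0, config=None):
        """Permutation test for LV significance; see :mod:`plsperm.permutation`."""
        from .permutation import PermutationConfig, run_permutation_test

        if config is None:
            config = PermutationConfig(method=method, n_perm=n_perm, seed=seed)
        return run_permutation_test(self.data, config, observed=self.decomposition)

    def permutation_tests(self, n_perm: int = 10_000, seed: int = 0, config=None):
        """All four rotation methods on shared shuffle indices; returns a dict."""
        from .permutation import PermutationConfig, run_all_permutation_tests

        if config is None:
            config = PermutationConfig(method="none", n_perm=n_perm, seed=seed)
        return run_all_permutation_tests(self.data, config, observed=self.decomposition)

    def split_half_stability(self, n_splits: int = 100, seed: int = 0):
        from .stability import split_half_stability

        return split_half_stability(self.data, n_splits=n_splits, seed=seed)

    def bootstrap_reliability(self, n_boot: int = 10_000, seed: int = 0):
        from .stability import bootstrap_reliability

        return bootstrap_reliability(self.data, n_boot=n_boot, seed=seed)

    # -- reporting -------------------------------------------------------
    def lv_table(self, null_distributions=None) -> pd.DataFrame:
        """Per-LV table: singular value, covariance explained, optional p-values.

        ``null_distributions`` may be a single ``NullDistributions`` or a
        dict of them keyed by rotation method.
        """
        tab = pd.DataFrame(
            {
                "lv": np.arange(1, self.k + 1),
                "singular_value": self.singular_values,
                "covariance_explained": self.covariance_explained,
            }
        )
        if null_distributions is not None:
            if not isinstance(null_distributions, dict):
                null_distributions = {null_distributions.method: null_distributions}
            for method, nd in null_distributions.items():
                tab[f"p_{method}"] = nd.p_values
        return tab

    def summary(self, null_distributions=None) -> str:
        d = self.data
        lines = [
            "PLS correlation results",
            "=======================",
            f"observations: {d.n}   X features: {d.p}   Y features: {d.q}   LVs: {self.k}",
            "",
            self.lv_table(null_distributions).to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            ),
        ]
        return "\n".join(lines)

    def save(self, out_dir: str) -> None:
        """Write U, V, singular values and covariance explained as CSV."""
        os.makedirs(out_dir, exist_ok=True)
        cols = [f"lv{i}" for i in range(1, self.k + 1)]
        pd.DataFrame(self.U, index=self.data.feature_names_x, columns=cols).to_csv(
            os.path.join(out_dir, "U.csv")
        )
        pd.DataFrame(self.V, index=self.data.feature_names_y, columns=cols).to_csv(
            os.path.join(out_dir, "V.csv")
        )
        self.lv_table().to_csv(os.path.join(out_dir, "lv_table.csv"), index=False)
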