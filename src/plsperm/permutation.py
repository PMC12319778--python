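"""Permutation inference for PLS latent variables, with and without
orthogonal Procrustes rotation.

Under the null hypothesis of no cross-block association, the rows of one
block are shuffled and the decomposition repeated, giving permuted singular
vectors/values ``U(p), S(p), V(p)``.  Four scoring rules build the per-LV
null distributions:

``none``
    The permuted singular values are recorded directly.
``behaviour``
    The orthogonal Procrustes rotation mapping V(p) onto the original V is
    computed; null values are the column L2 norms of ``V(p) S(p) R``.
``brain``
    Same, but the rotation aligns U(p) to U.
``both``
    Both rotated value vectors are computed on the same permuted
    decomposition and averaged elementwise.

The p-value of LV i is the proportion of its null values that meet or
exceed the observed singular value.

A single table of shuffle indices (one row per permutation instance) is
generated from the seed and consumed by every method, so p-value
differences between methods are attributable to the rotation alone.  A row
shuffle of X by a permutation π re-pairs observations exactly as a shuffle
of Y by π⁻¹; the brain method therefore applies the inverse of each shared
index row to X, which makes the permuted decomposition per instance
identical across all four methods (and, at k = 1, the four tests exactly
coincide).

Two exact consequences of orthogonality are worth noting (and are enforced
by the test suite): the rotation conserves total squared covariance,
``sum_i val_i^2 = sum_i s(p)_i^2``, and no rotated value can exceed the
largest permuted singular value, ``val_i <= s(p)_1``.  Because the permuted
LV1 is already the strongest possible source of covariance, rotation can
only weaken the LV1 null distribution — the mechanism behind the inflated
LV1 pass rates of rotated tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TwoBlockDataset
from .model import PLSDecomposition, _svd_with_sign_convention, decompose

__all__ = [
    "METHODS",
    "PermutationConfig",
    "NullDistributions",
    "make_shuffle_indices",
    "solve_procrustes",
    "rotated_null_values",
    "permuted_decomposition",
    "run_permutation_test",
    "run_all_permutation_tests",
]

METHODS = ("none", "behaviour", "brain", "both")

# singular values below this are treated as exactly 0 in p-value
# comparisons, so float noise on rank-deficient problems cannot register as
# an exceedance
SINGULAR_VALUE_FLOOR = 1e-12


def make_shuffle_indices(n: int, n_perm: int, seed: int) -> np.ndarray:
    """Pseudorandom permutation table, one row (a permutation of 0..n-1)
    per permutation instance."""
    rng = np.random.default_rng(seed)
    return rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)


@dataclass
class PermutationConfig:
    """Configuration shared by the four permutation tests.

    Attributes
    ----------
    method : {"none", "behaviour", "brain", "both"}
        Which component of each permuted decomposition, if any, is
        Procrustes-aligned to the original before scoring the null.
    n_perm : int
        Number of permutation instances (field default 10,000).
    seed : int
        Seeds the shuffle-index table; equal seeds mean all methods consume
        identical permutations.
    shuffle_indices : ndarray (n_perm, n), optional
        Precomputed table; each row must be a permutation of 0..n-1.
    add_one : bool
        If True, use the (count+1)/(n_perm+1) p-value estimator instead of
        the literal proportion.
    """

    method: str = "behaviour"
    n_perm: int = 10_000
    seed: int = 0
    shuffle_indices: np.ndarray | None = field(default=None, repr=False)
    add_one: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if int(self.n_perm) < 1:
            raise ValueError("n_perm must be a positive integer")
        self.n_perm = int(self.n_perm)
        if self.shuffle_indices is not None:
            idx = np.asarray(self.shuffle_indices)
            if idx.ndim != 2:
                raise ValueError("shuffle_indices must be a 2-D index table")
            n = idx.shape[1]
            if not (np.sort(idx, axis=1) == np.arange(n)).all():
                raise ValueError("each row of shuffle_indices must be a permutation of 0..n-1")
            self.shuffle_indices = idx
            self.n_perm = idx.shape[0]

    def indices_for(self, n: int) -> np.ndarray:
        """The shuffle-index table for n observations (precomputed or generated)."""
        if self.shuffle_indices is not None:
            if self.shuffle_indices.shape[1] != n:
                raise ValueError(
                    f"shuffle_indices built for n={self.shuffle_indices.shape[1]}, "
                    f"dataset has n={n}"
                )
            return self.shuffle_indices
        return make_shuffle_indices(n, self.n_perm, self.seed)


@dataclass
class NullDistributions:
    """Per-LV null distributions and p-values for one rotation method."""

    method: str
    values: np.ndarray  # (n_perm, k)
    observed: np.ndarray  # (k,)
    p_values: np.ndarray  # (k,)
    n_perm: int
    seed: int
    add_one: bool = False

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lv": np.arange(1, self.observed.size + 1),
                "observed": self.observed,
                "null_mean": self.values.mean(axis=0),
                "null_q95": np.quantile(self.values, 0.95, axis=0),
                "p_value": self.p_values,
            }
        )


def _p_values(null_values: np.ndarray, observed: np.ndarray, add_one: bool) -> np.ndarray:
    obs = np.where(observed < SINGULAR_VALUE_FLOOR, 0.0, observed)
    nulls = np.where(null_values < SINGULAR_VALUE_FLOOR, 0.0, null_values)
    count = (nulls >= obs[None, :]).sum(axis=0)
    n_perm = null_values.shape[0]
    if add_one:
        return (count + 1.0) / (n_perm + 1.0)
    return count / float(n_perm)


def solve_procrustes(V_perm: np.ndarray, V_ref: np.ndarray) -> np.ndarray:
    """Orthogonal Procrustes rotation mapping ``V_perm`` onto ``V_ref``.

    Solves ``min_R ||V_perm R - V_ref||_F`` over orthogonal R via the SVD
    ``V_perm^T V_ref = N O P^T``, returning ``R = N P^T`` (a rotation and/or
    reflection; it can reorder columns and redistribute weight across them).

    Both inputs must have orthonormal columns of equal shape.
    """
    A = np.asarray(V_perm, dtype=float)
    B = np.asarray(V_ref, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if A.ndim != 2:
        raise ValueError("inputs must be 2-D matrices")
    for M, name in ((A, "V_perm"), (B, "V_ref")):
        gram = M.T @ M
        if not np.allclose(gram, np.eye(M.shape[1]), atol=1e-6):
            raise ValueError(f"{name} does not have orthonormal columns")
    N, _, Pt = np.linalg.svd(A.T @ B)
    return N @ Pt


def rotated_null_values(
    perm_decomp: PLSDecomposition, ref: PLSDecomposition, component: str = "v"
) -> np.ndarray:
    """Null values for one permutation instance after Procrustes alignment.

    Computes R aligning the selected permuted component (``"v"``: V(p)→V,
    ``"u"``: U(p)→U), scales row i of R by the i-th permuted singular value
    (the transform ``V(p) S(p) R``), and returns the column L2 norms.
    """
    if component not in ("u", "v"):
        raise ValueError("component must be 'u' or 'v'")
    if perm_decomp.k != ref.k:
        raise ValueError(f"LV count mismatch: {perm_decomp.k} != {ref.k}")
    if component == "v":
        A, B = perm_decomp.V, ref.V
    else:
        A, B = perm_decomp.U, ref.U
    R = solve_procrustes(A, B)
    transformed = A @ (np.diag(perm_decomp.singular_values) @ R)
    return np.linalg.norm(transformed, axis=0)


def permuted_decomposition(
    data: TwoBlockDataset, perm: np.ndarray, side: str = "y"
) -> PLSDecomposition:
    """Decomposition after shuffling the rows of one block.

    ``side`` selects the shuffled block ("y" for the none/behaviour/both
    methods, "x" for brain).  Columnwise z-scoring is unaffected by row
    order, so this equals the decomposition of the row-shuffled raw data.
    """
    perm = np.asarray(perm)
    n = data.n
    if perm.shape != (n,) or not (np.sort(perm) == np.arange(n)).all():
        raise ValueError("perm must be a permutation of 0..n-1")
    if side not in ("x", "y"):
        raise ValueError("side must be 'x' or 'y'")
    if side == "y":
        shuffled = TwoBlockDataset(
            data.X, data.Y[perm], data.feature_names_x, data.feature_names_y
        )
    else:
        shuffled = TwoBlockDataset(
            data.X[perm], data.Y, data.feature_names_x, data.feature_names_y
        )
    return decompose(shuffled)


def _null_value_table(
    Xz: np.ndarray,
    Yz: np.ndarray,
    ref: PLSDecomposition,
    perms: np.ndarray,
    methods: tuple[str, ...],
    max_elements: int = 20_000_000,
) -> dict[str, np.ndarray]:
    """Vectorised null-value computation for all requested methods.

    Decomposes the Y-shuffled cross-correlation once per instance (the
    brain method consumes the same decomposition via the inverse-index
    equivalence) and scores each method from it.  Permutations are processed
    in chunks to bound memory.
    """
    n, q = Yz.shape
    n_perm = perms.shape[0]
    k = ref.k
    need_v = ("behaviour" in methods) or ("both" in methods)
    need_u = ("brain" in methods) or ("both" in methods)
    out = {m: np.empty((n_perm, k)) for m in methods}

    chunk = max(1, min(n_perm, max_elements // max(1, n * q)))
    XzT = Xz.T
    denom = n - 1
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        Yp = Yz[perms[start:stop]]  # (c, n, q)
        C = np.matmul(XzT, Yp) / denom  # (c, p, q)
        Up, sp, Vpt = np.linalg.svd(C, full_matrices=False)
        if not np.isfinite(sp).all():
            bad = start + int(np.flatnonzero(~np.isfinite(sp).all(axis=1))[0])
            raise FloatingPointError(f"non-finite singular values at permutation {bad}")
        sp2 = sp**2
        if "none" in methods:
            out["none"][start:stop] = sp
        vals_v = vals_u = None
        if need_v:
            M = Vpt @ ref.V  # V(p)^T V, (c, k, k)
            N_, _, Pt = np.linalg.svd(M)
            R = N_ @ Pt
            # columns of V(p) are orthonormal, so the column norms of
            # V(p) S(p) R equal those of S(p) R
            vals_v = np.sqrt(np.einsum("ci,cij->cj", sp2, R**2))
        if need_u:
            M = np.swapaxes(Up, 1, 2) @ ref.U  # U(p)^T U
            N_, _, Pt = np.linalg.svd(M)
            R = N_ @ Pt
            vals_u = np.sqrt(np.einsum("ci,cij->cj", sp2, R**2))
        if "behaviour" in methods:
            out["behaviour"][start:stop] = vals_v
        if "brain" in methods:
            out["brain"][start:stop] = vals_u
        if "both" in methods:
            out["both"][start:stop] = 0.5 * (vals_u + vals_v)
    return out


def run_all_permutation_tests(
    data: TwoBlockDataset,
    config: PermutationConfig,
    observed: PLSDecomposition | None = None,
    methods: tuple[str, ...] = METHODS,
) -> dict[str, NullDistributions]:
    """Run the requested permutation tests on one shared shuffle-index table.

    Returns a dict keyed by method.  Sharing both the indices and the
    per-instance permuted decomposition makes cross-method p-value
    differences attributable purely to the rotation step.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    if observed is None:
        observed = decompose(data)
    Xz, Yz = data.zscored()
    perms = config.indices_for(data.n)
    tables = _null_value_table(Xz, Yz, observed, perms, tuple(methods))
    result = {}
    for m in methods:
        values = tables[m]
        result[m] = NullDistributions(
            method=m,
            values=values,
            observed=observed.singular_values.copy(),
            p_values=_p_values(values, observed.singular_values, config.add_one),
            n_perm=perms.shape[0],
            seed=config.seed,
            add_one=config.add_one,
        )
    return result


def run_permutation_test(
    data: TwoBlockDataset,
    config: PermutationConfig,
    observed: PLSDecomposition | None = None,
) -> NullDistributions:
    """Permutation test for one rotation method; see module docstring."""
    return run_all_permutation_tests(
        data, config, observed=observed, methods=(config.method,)
    )[config.method]
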