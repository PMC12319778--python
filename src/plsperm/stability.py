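"""Split-half stability and bootstrap feature-weight reliability.

These diagnostics complement permutation significance: a latent variable
worth reporting should not only beat its null distribution but also
reproduce across random halves of the sample (stability) and yield feature
weights that are consistent under resampling (bootstrap ratios, loadings).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TwoBlockDataset
from .model import PLSDecomposition, decompose
from .permutation import solve_procrustes

__all__ = [
    "StabilityResult",
    "BootstrapResult",
    "split_stability",
    "split_half_stability",
    "bootstrap_reliability",
]

_SD_FLOOR = 1e-12
_MAX_REDRAWS = 1000


def _column_abs_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """|Pearson r| between matching columns of A and B."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    num = (Ac * Bc).sum(axis=0)
    den = np.sqrt((Ac**2).sum(axis=0) * (Bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return np.abs(np.clip(r, -1.0, 1.0))


@dataclass
class StabilityResult:
    """Split-half stability of each LV, per block.

    ``per_split_x[s, i]`` is |Pearson r| between the i-th left singular
    vectors estimated on the two halves of split s; ``per_split_y`` the
    same for the right singular vectors.  All entries lie in [0, 1].
    """

    per_split_x: np.ndarray  # (n_splits, k)
    per_split_y: np.ndarray
    n_splits: int
    seed: int

    def summary(self) -> pd.DataFrame:
        """Per-LV mean and standard deviation over splits, per block."""
        k = self.per_split_x.shape[1]
        return pd.DataFrame(
            {
                "lv": np.arange(1, k + 1),
                "stability_x_mean": self.per_split_x.mean(axis=0),
                "stability_x_sd": self.per_split_x.std(axis=0, ddof=1) if self.n_splits > 1 else np.zeros(k),
                "stability_y_mean": self.per_split_y.mean(axis=0),
                "stability_y_sd": self.per_split_y.std(axis=0, ddof=1) if self.n_splits > 1 else np.zeros(k),
            }
        )


def split_stability(
    data: TwoBlockDataset, first_half: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Stability of one fixed partition.

    ``first_half`` indexes the rows of the first half; the complement forms
    the second.  Returns (|r| per LV for U, |r| per LV for V), LVs matched
    by rank order.
    """
    first_half = np.asarray(first_half)
    mask = np.zeros(data.n, dtype=bool)
    mask[first_half] = True
    d1 = data.subset(np.flatnonzero(mask))
    d2 = data.subset(np.flatnonzero(~mask))
    dec1, dec2 = decompose(d1), decompose(d2)
    return (
        _column_abs_correlations(dec1.U, dec2.U),
        _column_abs_correlations(dec1.V, dec2.V),
    )


def split_half_stability(
    data: TwoBlockDataset, n_splits: int = 100, seed: int = 0
) -> StabilityResult:
    """Repeated random split-half stability.

    Each split partitions the rows into two disjoint halves (for odd n the
    first half gets the extra row), runs PLS on each half, and records the
    absolute Pearson correlation between the halves' i-th singular vectors
    for each LV i and each block.  Absolute values absorb the arbitrary SVD
    sign; LVs are matched by rank order, with no rotation between halves.
    """
    if data.n < 6:
        raise ValueError("split-half stability requires at least 6 observations")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    rng = np.random.default_rng(seed)
    k = data.k
    half = (data.n + 1) // 2
    per_x = np.empty((n_splits, k))
    per_y = np.empty((n_splits, k))
    for s in range(n_splits):
        for _ in range(_MAX_REDRAWS):
            order = rng.permutation(data.n)
            try:
                per_x[s], per_y[s] = split_stability(data, order[:half])
                break
            except ValueError:
                # a half drew a constant column (possible with discrete
                # features); redraw the split
                continue
        else:
            raise RuntimeError("could not draw a valid split (constant columns)")
    return StabilityResult(per_split_x=per_x, per_split_y=per_y, n_splits=n_splits, seed=seed)


@dataclass
class BootstrapResult:
    """Bootstrap reliability of feature weights.

    ``bootstrap_ratios_x[j, i]`` is the mean over resamples of the aligned
    brain weight of feature j on LV i divided by its standard deviation (a
    z-score analogue).  ``loadings_y`` holds the Pearson correlation of each
    behavioural variable with the Y latent scores on the original sample,
    with 95% percentile confidence bounds across resamples.
    """

    bootstrap_ratios_x: np.ndarray  # (p, k)
    ratio_sd_degenerate: np.ndarray  # bool (p, k): SD below floor, ratio capped
    loadings_y: np.ndarray  # (q, k)
    loading_ci_low: np.ndarray
    loading_ci_high: np.ndarray
    n_boot: int
    seed: int
    n_redraws: int  # resamples redrawn due to constant columns

    def summary(self) -> pd.DataFrame:
        q, k = self.loadings_y.shape
        rows = []
        for i in range(k):
            for j in range(q):
                rows.append(
                    {
                        "lv": i + 1,
                        "variable": j,
                        "loading": self.loadings_y[j, i],
                        "ci_low": self.loading_ci_low[j, i],
                        "ci_high": self.loading_ci_high[j, i],
                    }
                )
        return pd.DataFrame(rows)


def _loadings(Y: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson correlation of each Y column with each score column, (q, k)."""
    Yc = Y - Y.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    den = np.sqrt(
        (Yc**2).sum(axis=0)[:, None] * (Sc**2).sum(axis=0)[None, :]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        L = np.where(den > 0, (Yc.T @ Sc) / den, 0.0)
    return np.clip(L, -1.0, 1.0)


def bootstrap_reliability(
    data: TwoBlockDataset, n_boot: int = 10_000, seed: int = 0
) -> BootstrapResult:
    """Bootstrap resampling of the decomposition with brain-side alignment.

    Observations are resampled with replacement ``n_boot`` times.  For each
    resample the PLS is rerun and a Procrustes rotation aligning the
    resampled brain component U(b) to the original U is applied to both
    weight matrices (resampling can reorder or reflect LVs without breaking
    them; alignment maps them back before accumulation).  Brain bootstrap
    ratios are mean aligned weight over its standard deviation across
    resamples; behavioural loadings are correlations with the original
    Y latent scores, with 2.5/97.5 percentile bounds over the resampled
    (aligned, within-resample) loadings.

    Resamples that draw a constant column are redrawn and counted.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ref = decompose(data)
    _, Yz = data.zscored()
    k = ref.k
    p, q, n = data.p, data.q, data.n

    u_sum = np.zeros((p, k))
    u_sumsq = np.zeros((p, k))
    boot_loadings = np.empty((n_boot, q, k))
    rng = np.random.default_rng(seed)
    n_redraws = 0
    for b in range(n_boot):
        for _ in range(_MAX_REDRAWS):
            rows = rng.integers(0, n, n)
            try:
                sub = data.subset(rows)
                break
            except ValueError:
                n_redraws += 1
                continue
        else:
            raise RuntimeError("could not draw a valid bootstrap resample")
        dec = decompose(sub)
        R = solve_procrustes(dec.U, ref.U)
        U_al = dec.U @ R
        V_al = dec.V @ R
        u_sum += U_al
        u_sumsq += U_al**2
        scores_b = sub.zscored()[1] @ V_al
        boot_loadings[b] = _loadings(sub.Y, scores_b)

    mean = u_sum / n_boot
    var = u_sumsq / n_boot - mean**2
    sd = np.sqrt(np.maximum(var, 0.0)) * np.sqrt(n_boot / max(n_boot - 1, 1))
    degenerate = sd < _SD_FLOOR
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(degenerate, mean / _SD_FLOOR, mean / np.where(degenerate, 1.0, sd))
    ratios = np.where(degenerate & (mean == 0.0), 0.0, ratios)

    loadings = _loadings(data.Y, Yz @ ref.V)
    ci_low = np.quantile(boot_loadings, 0.025, axis=0)
    ci_high = np.quantile(boot_loadings, 0.975, axis=0)
    return BootstrapResult(
        bootstrap_ratios_x=ratios,
        ratio_sd_degenerate=degenerate,
        loadings_y=loadings,
        loading_ci_low=ci_low,
        loading_ci_high=ci_high,
        n_boot=n_boot,
        seed=seed,
        n_redraws=n_redraws,
    )
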