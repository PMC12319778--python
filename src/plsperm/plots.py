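"""Thin plotting layer over sweep tables (requires matplotlib)."""

from __future__ import annotations

import pandas as pd

from .sweeps import SweepResult, pass_rate

__all__ = ["plot_sweep_metrics"]


def plot_sweep_metrics(result: SweepResult, lv: int = 1, alpha: float = 0.05, axes=None):
    """Pass rate per method, strength and stability of one LV across the grid.

    Returns the matplotlib axes (2x2): pass rates, covariance explained,
    stability of X, stability of Y.
    """
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 2, figsize=(9, 7))
    ax = axes.ravel()
    for method in ("none", "behaviour", "brain", "both"):
        pr = pass_rate(result, lv=lv, method=method, alpha=alpha)
        ax[0].plot(pr.index, pr.values, marker="o", label=method)
    ax[0].set_ylabel(f"LV{lv} pass rate (p < {alpha})")
    ax[0].legend(fontsize=8)

    sub = result.table[result.table["lv"] == lv]
    grouped = sub.groupby("grid_value")
    for a, col, label in (
        (ax[1], "covariance_explained", "covariance explained"),
        (ax[2], "stability_x_mean", "stability (X)"),
        (ax[3], "stability_y_mean", "stability (Y)"),
    ):
        m = grouped[col].mean()
        a.plot(m.index, m.values, marker="o", color="k")
        a.scatter(sub["grid_value"], sub[col], s=6, alpha=0.3)
        a.set_ylabel(f"LV{lv} {label}")
    for a in ax:
        a.set_xlabel(result.metadata.get("analysis", "grid value"))
        if pd.api.types.is_numeric_dtype(sub["grid_value"]) and sub["grid_value"].min() > 0:
            span = sub["grid_value"].max() / max(sub["grid_value"].min(), 1e-12)
            if span > 50:
                a.set_xscale("log")
    return axes
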