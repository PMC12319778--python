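"""Simulation sweeps: pass rates, strength, and stability across conditions.

Four analyses mirror the simulation designs this package reproduces, each
varying one dataset property with the others fixed:

``random``
    iid-normal null data across sample sizes (empirical type-I error).
``sample_size``
    One latent effect (r = 0.3) across sample sizes.
``canonical_correlation``
    Effect strength varied at n = 1000.
``noise``
    Additive Gaussian noise varied at n = 1000, r = 0.3.

For every grid value x replicate, a dataset is generated, all four
permutation tests are run on shared shuffle indices, and covariance
explained plus split-half stability are recorded for every LV.  Results
are returned as a tidy table; ``pass_rate`` aggregates the fraction of
replicates with p < alpha.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .permutation import PermutationConfig, run_all_permutation_tests
from .model import decompose
from .simulate import SimulationSpec, generate_dataset
from .stability import split_half_stability

__all__ = ["ANALYSES", "DEFAULT_GRIDS", "PROFILES", "SweepResult", "run_analysis", "pass_rate"]

ANALYSES = ("random", "sample_size", "canonical_correlation", "noise")

# grids mirror the reproduced simulation designs: 10 sample sizes
# log-spaced 10..10,000; 10 canonical correlations linearly spaced
# 0.1..0.9; 10 noise SDs linearly spaced 0..1
DEFAULT_GRIDS: dict[str, np.ndarray] = {
    "random": np.unique(np.geomspace(10, 10_000, 10).round().astype(int)),
    "sample_size": np.unique(np.geomspace(10, 10_000, 10).round().astype(int)),
    "canonical_correlation": np.linspace(0.1, 0.9, 10),
    "noise": np.linspace(0.0, 1.0, 10),
}

# companion parameters held fixed while one is swept
COMPANIONS = {"p": 90, "q": 10, "r": 0.3, "n": 1000}

# desk profile keeps a laptop-scale run tractable; paper profile matches the
# full design (100 replicates, 10,000 permutations, 100 splits)
PROFILES = {
    "desk": {"n_replicates": 20, "n_perm": 1000, "n_splits": 20},
    "paper": {"n_replicates": 100, "n_perm": 10_000, "n_splits": 100},
}


@dataclass
class SweepResult:
    """Tidy per-LV results table plus run metadata.

    One row per (grid_value, replicate, lv) with the four methods'
    p-values, the LV's singular value and covariance explained, and the
    mean split-half stability of each block.
    """

    table: pd.DataFrame
    metadata: dict

    def pass_rate(self, lv: int = 1, method: str = "none", alpha: float = 0.05) -> pd.Series:
        return pass_rate(self, lv=lv, method=method, alpha=alpha)

    def save(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.table.to_csv(os.path.join(out_dir, "sweep.csv"), index=False)
        with open(os.path.join(out_dir, "metadata.json"), "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)

    @classmethod
    def load(cls, out_dir: str) -> "SweepResult":
        table = pd.read_csv(os.path.join(out_dir, "sweep.csv"))
        with open(os.path.join(out_dir, "metadata.json")) as fh:
            metadata = json.load(fh)
        return cls(table=table, metadata=metadata)


def _spec_for(analysis: str, grid_value, companions: dict, seed: int) -> SimulationSpec:
    c = companions
    if analysis == "random":
        return SimulationSpec(n=int(grid_value), p=c["p"], q=c["q"], regime="null", seed=seed)
    if analysis == "sample_size":
        return SimulationSpec(n=int(grid_value), p=c["p"], q=c["q"], r=c["r"], seed=seed)
    if analysis == "canonical_correlation":
        return SimulationSpec(n=c["n"], p=c["p"], q=c["q"], r=float(grid_value), seed=seed)
    if analysis == "noise":
        return SimulationSpec(
            n=c["n"], p=c["p"], q=c["q"], r=c["r"], noise_sd=float(grid_value), seed=seed
        )
    raise ValueError(f"unknown analysis {analysis!r}; expected one of {ANALYSES}")


def _one_replicate(
    analysis: str,
    grid_value,
    replicate: int,
    companions: dict,
    n_perm: int,
    n_splits: int,
    add_one: bool,
    child_seed: int,
) -> list[dict]:
    rng = np.random.default_rng(child_seed)
    data_seed, perm_seed, split_seed = (int(s) for s in rng.integers(0, 2**31, 3))
    spec = _spec_for(analysis, grid_value, companions, data_seed)
    data = generate_dataset(spec)
    dec = decompose(data)
    config = PermutationConfig(method="none", n_perm=n_perm, seed=perm_seed, add_one=add_one)
    nulls = run_all_permutation_tests(data, config, observed=dec)
    stab = split_half_stability(data, n_splits=n_splits, seed=split_seed)
    sx = stab.per_split_x.mean(axis=0)
    sy = stab.per_split_y.mean(axis=0)
    rows = []
    for i in range(dec.k):
        rows.append(
            {
                "analysis": analysis,
                "grid_value": grid_value,
                "replicate": replicate,
                "lv": i + 1,
                "singular_value": dec.singular_values[i],
                "covariance_explained": dec.covariance_explained[i],
                "p_none": nulls["none"].p_values[i],
                "p_behaviour": nulls["behaviour"].p_values[i],
                "p_brain": nulls["brain"].p_values[i],
                "p_both": nulls["both"].p_values[i],
                "stability_x_mean": sx[i],
                "stability_y_mean": sy[i],
                "perm_seed": perm_seed,
            }
        )
    return rows


def run_analysis(
    analysis: str,
    grid=None,
    n_replicates: int = 20,
    n_perm: int = 1000,
    n_splits: int = 20,
    seed: int = 0,
    companions: dict | None = None,
    add_one: bool = False,
    n_jobs: int = 1,
    max_failure_fraction: float = 0.01,
) -> SweepResult:
    """Run one sweep analysis over a grid of conditions.

    Replicate seeds are spawned deterministically from the master seed, so
    results are bit-identical regardless of ``n_jobs``.  Failed replicates
    are recorded and the sweep aborts if more than ``max_failure_fraction``
    of them fail.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}; expected one of {ANALYSES}")
    grid = DEFAULT_GRIDS[analysis] if grid is None else np.asarray(grid)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    comp = dict(COMPANIONS)
    if companions:
        comp.update(companions)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(grid.size * n_replicates)
    tasks = []
    for gi, gv in enumerate(grid):
        for rep in range(n_replicates):
            child = children[gi * n_replicates + rep]
            child_seed = int(child.generate_state(1)[0] % (2**31))
            tasks.append((gv, rep, child_seed))

    def _safe(gv, rep, child_seed):
        try:
            return _one_replicate(
                analysis, gv, rep, comp, n_perm, n_splits, add_one, child_seed
            )
        except Exception as exc:  # recorded; sweep continues
            return {"grid_value": gv, "replicate": rep, "error": repr(exc)}

    results = Parallel(n_jobs=n_jobs)(delayed(_safe)(*t) for t in tasks)
    rows: list[dict] = []
    failures: list[dict] = []
    for res in results:
        if isinstance(res, dict):
            failures.append(res)
        else:
            rows.extend(res)
    if len(failures) > max_failure_fraction * len(tasks):
        raise RuntimeError(f"{len(failures)}/{len(tasks)} replicates failed: {failures[:3]}")

    table = pd.DataFrame(rows)
    metadata = {
        "analysis": analysis,
        "grid": list(np.asarray(grid).tolist()),
        "n_replicates": n_replicates,
        "n_perm": n_perm,
        "n_splits": n_splits,
        "seed": seed,
        "companions": comp,
        "add_one": add_one,
        "shared_shuffle_indices": True,
        "failures": failures,
    }
    return SweepResult(table=table, metadata=metadata)


def pass_rate(result: SweepResult, lv: int = 1, method: str = "none", alpha: float = 0.05) -> pd.Series:
    """Fraction of replicates with p < alpha per grid value (strict <)."""
    col = f"p_{method}"
    if col not in result.table.columns:
        raise ValueError(f"unknown method {method!r}")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    sub = result.table[result.table["lv"] == lv]
    if sub.empty:
        raise ValueError(f"no rows for lv={lv}")
    return sub.groupby("grid_value")[col].apply(lambda s: float((s < alpha).mean()))
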