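"""The two ablation studies over the feature sets.

FS sweep
    For each cardinality c (default 4..19) keep the first c features of a
    retained order and refit every model.  The default order lists the 14
    golden ratios first, then the 5 symmetry ratios, so shrinking the
    cardinality below 19 removes symmetry ratios first — the removal order
    under which the golden ratios' stronger signal shows up cleanly.
    Cardinalities above 19 (up to 30) extend the order with the 4 GLCM
    statistics and then the 7 Hu moments, a documented reconstruction for
    sweeps past the FS.

SFS lattice
    The 8 block configurations — Without, T + C + S, T + C, T + S, C + S,
    T, C, S — each fused with the model's best FS from the sweep, refit
    per model.

Every grid cell refits from scratch on the same seeded 80/20 split, so
cells are comparable and a rerun with the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import BLOCK_COLUMNS, FeatureTables
from .metrics import evaluate
from .models import ModelSpec, default_specs, fit, split_dataset
from .ratios import FEATURE_NAMES

__all__ = [
    "AblationGrid",
    "SFS_CONFIGS",
    "fs_ablation",
    "sfs_ablation",
    "select_best",
    "plot_ablation",
]

#: The 8 SFS block configurations, row labels fixed.
SFS_CONFIGS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("Without", ()),
    ("T + C + S", ("T", "C", "S")),
    ("T + C", ("T", "C")),
    ("T + S", ("T", "S")),
    ("C + S", ("C", "S")),
    ("T", ("T",)),
    ("C", ("C",)),
    ("S", ("S",)),
)

GRID_COLUMNS = ["config", "model", "pc", "r2", "mae", "mse",
                "n_features", "seed"]

_HIGHER_BETTER = {"pc": True, "r2": True, "mae": False, "mse": False}


@dataclass(frozen=True)
class AblationGrid:
    """Tidy metrics grid: one row per (configuration, model)."""

    table: pd.DataFrame

    def row(self, config, model: str) -> pd.Series:
        t = self.table
        hit = t[(t["config"] == config) & (t["model"] == model)]
        if hit.empty:
            raise KeyError((config, model))
        return hit.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.table)


def _extended_order(tables: FeatureTables) -> list[str]:
    return list(FEATURE_NAMES) + BLOCK_COLUMNS["T"] + BLOCK_COLUMNS["S"]


def _run_cell(X: pd.DataFrame, y: np.ndarray, spec: ModelSpec,
              train_idx, test_idx):
    model = fit(spec, X.values[train_idx], y[train_idx])
    return evaluate(y[test_idx], model.predict(X.values[test_idx]))


def fs_ablation(
    tables: FeatureTables,
    models: Mapping[str, ModelSpec] | None = None,
    removal_order: Sequence[str] | None = None,
    cardinalities: Iterable[int] = range(4, 20),
    train_fraction: float = 0.8,
    seed: int = 0,
) -> AblationGrid:
    """Metrics for every (cardinality, model) cell of the FS sweep.

    ``removal_order`` is the *retained* feature order; cardinality c uses
    its first c entries.  Defaults to golden ratios then symmetry ratios
    (then GLCM, then Hu, for c > 19).
    """
    models = models or default_specs(seed)
    order = list(removal_order) if removal_order is not None \
        else _extended_order(tables)
    cardinalities = sorted(set(int(c) for c in cardinalities))
    if any(c < 1 or c > len(order) for c in cardinalities):
        raise ValueError(
            f"cardinalities must lie in 1..{len(order)}: {cardinalities}"
        )
    y = tables.scores.values.astype(float)
    train_idx, test_idx = split_dataset(len(y), train_fraction, seed)
    all_cols = tables.matrix(blocks=("T", "C", "S"))
    rows = []
    for c in cardinalities:
        cols = order[:c]
        X = all_cols[cols]
        for name, spec in models.items():
            rep = _run_cell(X, y, spec, train_idx, test_idx)
            rows.append([c, name, rep.pc, rep.r2, rep.mae, rep.mse, c, seed])
    return AblationGrid(pd.DataFrame(rows, columns=GRID_COLUMNS))


def select_best(grid: AblationGrid, metric: str = "pc") -> dict[str, object]:
    """Best configuration per model; ties break toward fewer features."""
    if metric not in _HIGHER_BETTER:
        raise ValueError(f"unknown metric {metric!r}; "
                         f"expected one of {sorted(_HIGHER_BETTER)}")
    t = grid.table
    if t.empty:
        raise ValueError("empty ablation grid")
    higher = _HIGHER_BETTER[metric]
    best = {}
    for model, sub in t.groupby("model", sort=False):
        sub = sub.sort_values(["n_features"], kind="stable")
        vals = sub[metric].values
        pick = int(np.nanargmax(vals) if higher else np.nanargmin(vals))
        best[model] = sub.iloc[pick]["config"]
    return best


def sfs_ablation(
    tables: FeatureTables,
    models: Mapping[str, ModelSpec] | None = None,
    best_fs: Mapping[str, int] | None = None,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> AblationGrid:
    """Metrics for the 8 SFS block configurations per model.

    Each model's FS part is its best cardinality from the FS sweep
    (computed here when ``best_fs`` is not given, restricted to 4..19),
    fused with the configuration's blocks in the fixed T, C, S order.
    """
    models = models or default_specs(seed)
    if best_fs is None:
        fs_grid = fs_ablation(tables, models, cardinalities=range(4, 20),
                              train_fraction=train_fraction, seed=seed)
        best_fs = {m: int(c) for m, c in select_best(fs_grid, "pc").items()}
    y = tables.scores.values.astype(float)
    train_idx, test_idx = split_dataset(len(y), train_fraction, seed)
    rows = []
    for label, blocks in SFS_CONFIGS:
        for name, spec in models.items():
            fs_cols = list(FEATURE_NAMES)[: best_fs[name]]
            X = tables.matrix(fs_columns=fs_cols, blocks=blocks)
            rep = _run_cell(X, y, spec, train_idx, test_idx)
            rows.append([label, name, rep.pc, rep.r2, rep.mae, rep.mse,
                         X.shape[1], seed])
    return AblationGrid(pd.DataFrame(rows, columns=GRID_COLUMNS))


def plot_ablation(grid: AblationGrid, metric: str, path: str | Path,
                  title: str | None = None) -> None:
    """Line plot of one metric vs. configuration, one series per model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = grid.table
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for model, sub in t.groupby("model", sort=False):
        ax.plot(sub["config"].astype(str), sub[metric], marker="o",
                label=model)
    ax.set_xlabel("configuration")
    ax.set_ylabel(metric.upper())
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
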