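"""Measure stability across a grid of tree counts.

For each tree count t in the grid, R independently seeded forests are grown
on identical data; their predictions (or variable importances) form an
n x R ratings matrix whose agreement — ICC(1,1) for continuous outputs,
Fleiss' kappa for categorical ones — is the measured stability at t, along
with the Fleiss' kappa of the derived top-alpha selection decisions and the
mean wall time per forest. The resulting curve is the raw material the 2PL
model is fitted to.

Seeding: repetition r at grid position g uses seed
(base_seed + g * R + r) mod 2^31, so a curve is a pure function of
(data, config) and grid points can be reproduced in isolation.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd

from .exceptions import InputError, UndefinedStabilityError
from .forest import ForestSpec, fit_forest, oob_predict, predict_forest, importances
from .metrics import drop_incomplete_subjects, prediction_stability, icc_1_1
from .selection import (
    SelectionSpec,
    select_from_importances,
    select_from_predictions,
    selection_stability,
)

__all__ = ["TrialConfig", "StabilityCurve", "run_prediction_trials", "run_importance_trials"]

log = logging.getLogger(__name__)

DEFAULT_GRID = (250, 500, 750, 1000, 2000)


@dataclass(frozen=True)
class TrialConfig:
    """Configuration of one stability-measurement run."""

    tree_grid: Tuple[int, ...] = DEFAULT_GRID
    repetitions: int = 10
    base_seed: int = 0
    selection: SelectionSpec = field(default_factory=SelectionSpec)
    task: str = "regression"
    mode: str = "prediction"
    oob: bool = False
    importance_kind: str = "permutation"

    def __post_init__(self):
        grid = tuple(int(t) for t in self.tree_grid)
        if len(grid) < 3:
            raise InputError("tree grid needs at least 3 points (the 2PL fit does)")
        if any(t < 1 for t in grid):
            raise InputError("tree counts must be positive")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise InputError("tree grid must be strictly increasing")
        object.__setattr__(self, "tree_grid", grid)
        if self.repetitions < 2:
            raise InputError("need at least 2 repetitions")
        if self.mode not in ("prediction", "importance"):
            raise InputError("mode must be 'prediction' or 'importance'")

    def seed_for(self, grid_index: int, repetition: int) -> int:
        return (self.base_seed + grid_index * self.repetitions + repetition) % (2**31)


@dataclass
class StabilityCurve:
    """Measured (tree count, stability, selection stability, runtime) rows."""

    table: pd.DataFrame
    mode: str
    task: str
    config: TrialConfig

    COLUMNS = ("num_trees", "stability", "selection_stability", "runtime_sec")

    @property
    def num_trees(self) -> np.ndarray:
        return self.table["num_trees"].to_numpy()

    def stability_values(self, basis: str = "primary") -> np.ndarray:
        col = "selection_stability" if basis == "selection" else "stability"
        return self.table[col].to_numpy()

    @property
    def n_usable(self) -> int:
        return int(self.table["stability"].notna().sum())

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, mode="prediction", task="regression", config=None):
        table = pd.read_csv(path)
        missing = set(cls.COLUMNS) - set(table.columns)
        if missing:
            raise InputError(f"curve file lacks columns {sorted(missing)}")
        return cls(table=table, mode=mode, task=task, config=config)


def _safe_metric(fn, *args, what, num_trees):
    try:
        return fn(*args)
    except UndefinedStabilityError as err:
        log.warning("%s undefined at %d trees: %s", what, num_trees, err)
        return np.nan


def _ratings_matrix(columns) -> np.ndarray:
    first = np.asarray(columns[0])
    if first.dtype.kind in "fiu":
        return np.column_stack([np.asarray(c, dtype=float) for c in columns])
    return np.column_stack([np.asarray(c, dtype=object) for c in columns])


def run_prediction_trials(X, y, X_test=None, cfg: TrialConfig = None) -> StabilityCurve:
    """Prediction-stability curve over the tree grid.

    With a test table, each repetition predicts its rows; without one,
    ``cfg.oob`` must be set and out-of-bag predictions on the training data
    are used instead (individuals lacking any OOB prediction in a repetition
    are dropped from that grid point's ratings matrix).
    """
    cfg = cfg or TrialConfig()
    if X_test is None and not cfg.oob:
        raise InputError("either supply X_test or enable OOB mode")
    rows = []
    for g, t in enumerate(cfg.tree_grid):
        preds, elapsed = [], 0.0
        for r in range(cfg.repetitions):
            spec = ForestSpec(num_trees=t, task=cfg.task, seed=cfg.seed_for(g, r),
                              importance_kind=cfg.importance_kind)
            tic = time.perf_counter()
            forest = fit_forest(X, y, spec)
            if X_test is None:
                pred = oob_predict(forest, X)
            else:
                pred = predict_forest(forest, X_test)
            elapsed += time.perf_counter() - tic
            preds.append(pred)
        pm = drop_incomplete_subjects(_ratings_matrix(preds))
        stab = _safe_metric(prediction_stability, pm, cfg.task,
                            what="prediction stability", num_trees=t)
        sm = select_from_predictions(pm, cfg.selection)
        sel = _safe_metric(selection_stability, sm,
                           what="selection stability", num_trees=t)
        rows.append((t, stab, sel, elapsed / cfg.repetitions))
        log.info("t=%d: stability=%.4f selection=%.4f (%.2fs/forest)", t, stab, sel, rows[-1][3])
    table = pd.DataFrame(rows, columns=list(StabilityCurve.COLUMNS))
    _check_usable(table)
    return StabilityCurve(table=table, mode="prediction", task=cfg.task, config=cfg)


def run_importance_trials(X, y, cfg: TrialConfig = None) -> StabilityCurve:
    """Variable-importance stability curve over the tree grid.

    The ratings matrix is p x R importance estimates; its ICC(1,1) is the
    primary stability and the Fleiss' kappa of top-alpha variable selection
    the selection stability.
    """
    cfg = cfg or TrialConfig(mode="importance",
                             selection=SelectionSpec(alpha=0.05, criterion="high"))
    rows = []
    for g, t in enumerate(cfg.tree_grid):
        imps, elapsed = [], 0.0
        for r in range(cfg.repetitions):
            spec = ForestSpec(num_trees=t, task=cfg.task, seed=cfg.seed_for(g, r),
                              importance_kind=cfg.importance_kind)
            tic = time.perf_counter()
            forest = fit_forest(X, y, spec)
            imp = importances(forest, X, y)
            elapsed += time.perf_counter() - tic
            imps.append(imp)
        im = _ratings_matrix(imps)
        stab = _safe_metric(icc_1_1, im, what="importance stability", num_trees=t)
        sm = select_from_importances(im, cfg.selection.alpha)
        sel = _safe_metric(selection_stability, sm,
                           what="selection stability", num_trees=t)
        rows.append((t, stab, sel, elapsed / cfg.repetitions))
        log.info("t=%d: stability=%.4f selection=%.4f (%.2fs/forest)", t, stab, sel, rows[-1][3])
    table = pd.DataFrame(rows, columns=list(StabilityCurve.COLUMNS))
    _check_usable(table)
    return StabilityCurve(table=table, mode="importance", task=cfg.task, config=cfg)


def _check_usable(table: pd.DataFrame):
    usable = int(table["stability"].notna().sum())
    if usable < 3:
        raise UndefinedStabilityError(
            f"only {usable} grid point(s) have a defined stability; "
            "at least 3 are needed to model the curve"
        )
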