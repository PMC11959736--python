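"""User-facing workflows: optimise the tree count for prediction or importance.

Both workflows are scikit-learn style estimators: ``fit(X, y)`` measures the
stability curve, fits the 2PL model and stores the recommendation in fitted
attributes; :func:`opt_prediction` / :func:`opt_importance` are thin
functional wrappers returning a serialisable :class:`RunReport`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import __version__ as _pkg_version
from .exceptions import InputError
from .model import (
    DEFAULT_REC_THRESH,
    Recommendation,
    TwoPLStabilityModel,
    estimate_runtime,
)
from .selection import SelectionSpec
from .trials import DEFAULT_GRID, StabilityCurve, TrialConfig, run_importance_trials, run_prediction_trials

__all__ = [
    "PredictionStabilityOptimizer",
    "ImportanceStabilityOptimizer",
    "RunReport",
    "opt_prediction",
    "opt_importance",
]


@dataclass
class RunReport:
    """Everything needed to reproduce and re-summarise one run."""

    mode: str
    task: str
    curve: pd.DataFrame
    model: dict
    selection_model: Optional[dict]
    recommendation: Recommendation
    runtime_at_recommendation_sec: Optional[float]
    config: dict
    version: str = _pkg_version
    warnings: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "mode": self.mode,
            "task": self.task,
            "curve": self.curve.to_dict(orient="list"),
            "model": self.model,
            "selection_model": self.selection_model,
            "recommendation": asdict(self.recommendation),
            "runtime_at_recommendation_sec": self.runtime_at_recommendation_sec,
            "config": self.config,
            "version": self.version,
            "warnings": self.warnings,
        }
        text = json.dumps(payload, indent=1, default=_json_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple, set, frozenset)):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


class _BaseStabilityOptimizer(BaseEstimator):
    """Shared machinery: run trials, fit 2PL curves, derive a recommendation.

    Fitted attributes (all workflows): ``curve_`` (StabilityCurve),
    ``model_`` (2PL on the primary stability), ``selection_model_`` (2PL on
    the selection stability, when fittable), ``recommendation_``
    (Recommendation), ``n_trees_`` (its tree count) and ``report_``
    (RunReport).
    """

    _mode = None  # set by subclasses

    def _trial_config(self, selection: SelectionSpec, task: str, oob: bool = False) -> TrialConfig:
        return TrialConfig(
            tree_grid=tuple(self.tree_grid),
            repetitions=self.repetitions,
            base_seed=self.random_state,
            selection=selection,
            task=task,
            mode=self._mode,
            oob=oob,
            importance_kind=self.importance_kind,
        )

    def _finish(self, curve: StabilityCurve, basis: str, caught) -> "_BaseStabilityOptimizer":
        self.curve_ = curve
        t = curve.num_trees
        self.model_ = TwoPLStabilityModel(rec_thresh=self.rec_thresh).fit(
            t, curve.stability_values("primary")
        )
        self.selection_model_ = None
        sel_vals = curve.stability_values("selection")
        try:
            self.selection_model_ = TwoPLStabilityModel(rec_thresh=self.rec_thresh).fit(
                t, sel_vals
            )
        except InputError as err:
            caught.append(f"selection-stability curve not modelled: {err}")

        if basis == "selection":
            if self.selection_model_ is None:
                raise InputError(
                    "recommendation basis 'selection' requested but the "
                    "selection-stability curve could not be fitted"
                )
            rec_model = self.selection_model_
        else:
            rec_model = self.model_
        self.recommendation_ = rec_model.recommend(
            rec_thresh=self.rec_thresh, basis=basis
        )
        self.n_trees_ = self.recommendation_.num_trees

        runtime_proj = None
        try:
            runtime_proj = estimate_runtime(
                t, curve.table["runtime_sec"].to_numpy(), self.n_trees_
            )
        except InputError:
            pass
        self.report_ = RunReport(
            mode=self._mode,
            task=curve.task,
            curve=curve.table,
            model=self.model_.to_dict(),
            selection_model=(
                self.selection_model_.to_dict() if self.selection_model_ else None
            ),
            recommendation=self.recommendation_,
            runtime_at_recommendation_sec=runtime_proj,
            config=self.get_params(),
            warnings=caught,
        )
        return self


class PredictionStabilityOptimizer(_BaseStabilityOptimizer):
    """Find the tree count from which forest predictions are stable.

    Repeats random forest ``repetitions`` times at each tree count of
    ``tree_grid`` on identical data, measures how strongly the repeated
    predictions (and the derived top-``alpha`` selection decisions) agree,
    fits the two-parameter logistic stability curve, and recommends the
    smallest tree count beyond which ten additional trees improve the
    modelled stability by at most ``rec_thresh``.

    Parameters
    ----------
    tree_grid : sequence of int, default (250, 500, 750, 1000, 2000)
    repetitions : int, default 10
    alpha : float, default 0.15
        Fraction of test individuals selected per repetition.
    select_for : {"high", "low", "zero"} or sequence of class labels
        Selection criterion; categorical responses require class labels.
    rec_thresh : float, default 1e-6
    basis : {"prediction", "selection"}
        Which stability the recommendation is based on.
    importance_kind : {"permutation", "impurity"}
        Passed through to the forests (irrelevant for this workflow's
        stability, kept for config symmetry).
    random_state : int, default 0

    Examples
    --------
    >>> opt = PredictionStabilityOptimizer(tree_grid=(50, 100, 200),
    ...                                    repetitions=3, random_state=7)
    >>> opt.fit(X_train, y_train, X_test)       # doctest: +SKIP
    >>> opt.n_trees_                            # doctest: +SKIP
    3000
    """

    _mode = "prediction"

    def __init__(self, tree_grid: Sequence[int] = DEFAULT_GRID, repetitions: int = 10,
                 alpha: float = 0.15, select_for="high",
                 rec_thresh: float = DEFAULT_REC_THRESH, basis: str = "prediction",
                 importance_kind: str = "permutation", random_state: int = 0):
        self.tree_grid = tree_grid
        self.repetitions = repetitions
        self.alpha = alpha
        self.select_for = select_for
        self.rec_thresh = rec_thresh
        self.basis = basis
        self.importance_kind = importance_kind
        self.random_state = random_state

    def _selection_spec(self, task: str) -> SelectionSpec:
        sf = self.select_for
        if task == "classification":
            if isinstance(sf, str) and sf in ("high", "low", "zero"):
                raise InputError(
                    "categorical response: name the class(es) to select for "
                    "in select_for (e.g. select_for=['high'] for that label)"
                )
            labels = frozenset([sf] if isinstance(sf, str) else sf)
            return SelectionSpec(alpha=self.alpha, criterion="classes", classes=labels)
        if not isinstance(sf, str) or sf not in ("high", "low", "zero"):
            raise InputError("metric response: select_for must be high/low/zero")
        return SelectionSpec(alpha=self.alpha, criterion=sf)

    def fit(self, X, y, X_test=None):
        """Measure the curve and derive the recommendation.

        Without ``X_test``, stability is measured on out-of-bag predictions
        for the training individuals.
        """
        task = _infer_task(y)
        cfg = self._trial_config(self._selection_spec(task), task, oob=X_test is None)
        caught = []
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            curve = run_prediction_trials(X, y, X_test, cfg)
        caught.extend(str(w.message) for w in wlist)
        return self._finish(curve, self.basis, caught)


class ImportanceStabilityOptimizer(_BaseStabilityOptimizer):
    """Find the tree count from which variable importances are stable.

    As :class:`PredictionStabilityOptimizer`, but the ratings matrix holds
    the p per-variable importance estimates of each repetition; the primary
    stability is their ICC(1,1) and the selection stability the agreement of
    top-``alpha`` variable selection (default top 5%).
    """

    _mode = "importance"

    def __init__(self, tree_grid: Sequence[int] = DEFAULT_GRID, repetitions: int = 10,
                 alpha: float = 0.05, rec_thresh: float = DEFAULT_REC_THRESH,
                 basis: str = "importance", importance_kind: str = "permutation",
                 random_state: int = 0):
        self.tree_grid = tree_grid
        self.repetitions = repetitions
        self.alpha = alpha
        self.rec_thresh = rec_thresh
        self.basis = basis
        self.importance_kind = importance_kind
        self.random_state = random_state

    def fit(self, X, y):
        task = _infer_task(y)
        sel = SelectionSpec(alpha=self.alpha, criterion="high")
        cfg = self._trial_config(sel, task)
        caught = []
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            curve = run_importance_trials(X, y, cfg)
        caught.extend(str(w.message) for w in wlist)
        return self._finish(curve, self.basis, caught)


def _infer_task(y) -> str:
    arr = np.asarray(y)
    if arr.dtype.kind in "fiu":
        return "regression"
    return "classification"


def opt_prediction(X, y, X_test=None, **options) -> RunReport:
    """Optimise the tree count for prediction/selection stability.

    Functional wrapper around :class:`PredictionStabilityOptimizer`;
    ``options`` are its constructor parameters. Returns a
    :class:`RunReport`.
    """
    return PredictionStabilityOptimizer(**options).fit(X, y, X_test).report_


def opt_importance(X, y, **options) -> RunReport:
    """Optimise the tree count for variable-importance stability."""
    return ImportanceStabilityOptimizer(**options).fit(X, y).report_
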