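"""Uniform contract over the random-forest learner.

Everything downstream (trial running, stability metrics, selection) talks to
forests only through :class:`ForestSpec`, :func:`fit_forest`,
:func:`predict_forest`, :func:`oob_predict` and :func:`importances`, so the
wrapped learner (scikit-learn's forests) never leaks into the rest of the
package.

Defaults follow the conventions of the forest implementations used in
genomics rather than scikit-learn's legacy ones: regression draws p/3
candidate variables per split with minimum node size 5, classification draws
sqrt(p) with minimum node size 1. Bootstrap sampling is with replacement at
sample fraction 1.0, so each tree leaves about a fraction e^-1 of the
individuals out of bag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .exceptions import InputError, SchemaError

__all__ = [
    "ForestSpec",
    "FittedForest",
    "fit_forest",
    "predict_forest",
    "oob_predict",
    "importances",
]

_TASKS = ("regression", "classification")
_IMPORTANCE_KINDS = ("permutation", "impurity")


@dataclass(frozen=True)
class ForestSpec:
    """Complete, reproducible description of one forest to grow.

    A fixed (spec, data) pair yields bit-identical predictions and
    importances on repeated calls.

    Parameters
    ----------
    num_trees : int
        Number of trees t in the ensemble (>= 1).
    task : {"regression", "classification"}
    seed : int
        Seeds both the bootstrap/tree randomness and the permutation used
        for permutation importance.
    importance_kind : {"permutation", "impurity"}
    max_features : float, int, str or None
        Candidate variables per split; None picks the task default
        (p/3 for regression, sqrt(p) for classification).
    min_node_size : int or None
        Minimum samples per leaf; None picks the task default (5 / 1).
    sample_fraction : float
        Bootstrap sample size as a fraction of n (with replacement).
    """

    num_trees: int
    task: str = "regression"
    seed: int = 0
    importance_kind: str = "permutation"
    max_features: Optional[object] = None
    min_node_size: Optional[int] = None
    sample_fraction: float = 1.0

    def __post_init__(self):
        if self.num_trees < 1:
            raise InputError(f"num_trees must be >= 1, got {self.num_trees}")
        if self.task not in _TASKS:
            raise InputError(f"task must be one of {_TASKS}, got {self.task!r}")
        if self.importance_kind not in _IMPORTANCE_KINDS:
            raise InputError(
                f"importance_kind must be one of {_IMPORTANCE_KINDS}, "
                f"got {self.importance_kind!r}"
            )
        if not 0 < self.sample_fraction <= 1.0:
            raise InputError("sample_fraction must be in (0, 1]")


@dataclass
class FittedForest:
    """Trained forest plus the per-tree in-bag records needed for OOB work."""

    model: object
    spec: ForestSpec
    columns: tuple
    n_train: int
    inbag: np.ndarray = field(repr=False)  # (num_trees, n_train) counts
    classes: Optional[np.ndarray] = None

    @property
    def oob_mask(self) -> np.ndarray:
        """Boolean (num_trees, n_train): True where the individual was out of bag."""
        return self.inbag == 0


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise InputError("predictor table must be two-dimensional")
    return arr, tuple(range(arr.shape[1]))


def fit_forest(X, y, spec: ForestSpec) -> FittedForest:
    """Grow a random forest honouring ``spec`` exactly, retaining in-bag records."""
    Xm, columns = _as_matrix(X)
    n, p = Xm.shape
    if n < 2:
        raise InputError("need at least 2 training individuals")
    if np.isnan(Xm).any():
        raise InputError("predictor table contains missing values")
    y = np.asarray(y)
    if y.shape[0] != n:
        raise InputError(f"response length {y.shape[0]} != n rows {n}")

    if spec.task == "regression":
        yv = np.asarray(y, dtype=float)
        if np.isnan(yv).any():
            raise InputError("response contains missing values")
        est = RandomForestRegressor(
            n_estimators=spec.num_trees,
            max_features=spec.max_features if spec.max_features is not None else 1 / 3,
            min_samples_leaf=spec.min_node_size if spec.min_node_size is not None else 5,
            bootstrap=True,
            max_samples=None if spec.sample_fraction == 1.0 else spec.sample_fraction,
            random_state=spec.seed,
            n_jobs=1,
        )
    else:
        yv = y
        if pd.isna(pd.Series(yv)).any():
            raise InputError("response contains missing values")
        if len(np.unique(yv)) < 2:
            raise InputError("classification requires at least 2 classes")
        est = RandomForestClassifier(
            n_estimators=spec.num_trees,
            max_features=spec.max_features if spec.max_features is not None else "sqrt",
            min_samples_leaf=spec.min_node_size if spec.min_node_size is not None else 1,
            bootstrap=True,
            max_samples=None if spec.sample_fraction == 1.0 else spec.sample_fraction,
            random_state=spec.seed,
            n_jobs=1,
        )
    est.fit(Xm, yv)

    inbag = np.zeros((spec.num_trees, n), dtype=np.int32)
    for t, idx in enumerate(est.estimators_samples_):
        inbag[t] = np.bincount(idx, minlength=n)

    return FittedForest(
        model=est,
        spec=spec,
        columns=columns,
        n_train=n,
        inbag=inbag,
        classes=getattr(est, "classes_", None),
    )


def _check_schema(forest: FittedForest, X):
    Xm, columns = _as_matrix(X)
    if columns != forest.columns:
        raise SchemaError(
            "test predictors do not match training predictors in name/order"
        )
    if np.isnan(Xm).any():
        raise InputError("test predictor table contains missing values")
    return Xm


def predict_forest(forest: FittedForest, X_test) -> np.ndarray:
    """Forest prediction for each test row (class labels for classification)."""
    Xm = _check_schema(forest, X_test)
    return forest.model.predict(Xm)


def per_tree_predictions(forest: FittedForest, X) -> np.ndarray:
    """(num_trees, n_rows) matrix of single-tree predictions.

    For classification the entries are indices into ``forest.classes``.
    """
    Xm = _check_schema(forest, X)
    preds = np.empty((forest.spec.num_trees, Xm.shape[0]))
    if forest.spec.task == "regression":
        for t, tree in enumerate(forest.model.estimators_):
            preds[t] = tree.predict(Xm)
    else:
        for t, tree in enumerate(forest.model.estimators_):
            # tree predict returns encoded class indices of the parent forest
            proba = tree.predict_proba(Xm)
            preds[t] = np.argmax(proba, axis=1)
    return preds


def oob_predict(forest: FittedForest, X, y=None) -> np.ndarray:
    """Out-of-bag prediction per training individual.

    Regression: mean of predictions of the trees whose bootstrap sample
    excluded the individual. Classification: the class most frequently
    predicted by those trees (ties broken by class order). Individuals that
    were in-bag for every tree get a missing entry (NaN / None) and a
    warning; they carry no OOB information.
    """
    preds = per_tree_predictions(forest, X)
    oob = forest.oob_mask  # (T, n)
    n = forest.n_train
    n_oob_trees = oob.sum(axis=0)
    never = n_oob_trees == 0
    if never.any():
        warnings.warn(
            f"{int(never.sum())} individual(s) were in-bag for every tree; "
            "their OOB predictions are missing",
            stacklevel=2,
        )
    if forest.spec.task == "regression":
        sums = np.where(oob, preds, 0.0).sum(axis=0)
        out = np.full(n, np.nan)
        np.divide(sums, n_oob_trees, out=out, where=~never)
        return out
    # classification: modal class among OOB trees
    k = len(forest.classes)
    counts = np.zeros((n, k), dtype=np.int64)
    pred_idx = preds.astype(np.int64)
    for t in range(forest.spec.num_trees):
        rows = np.nonzero(oob[t])[0]
        np.add.at(counts, (rows, pred_idx[t, rows]), 1)
    labels = forest.classes[np.argmax(counts, axis=1)]
    out = np.array(labels, dtype=object)
    out[never] = None
    return out


def _prediction_score(task, y_true, y_pred):
    if task == "regression":
        d = y_true - y_pred
        return -float(np.mean(d * d))  # negative MSE, higher is better
    return float(np.mean(y_true == y_pred))


def importances(forest: FittedForest, X=None, y=None, *, chunk_cells: int = 4_000_000) -> np.ndarray:
    """One importance value per predictor, ordered as the input columns.

    ``impurity`` passes through the forest's mean decrease in impurity.
    ``permutation`` measures, for each variable, the drop in prediction score
    (negative MSE for regression, accuracy for classification) when that
    variable's column is permuted once on the evaluation data (X, y) — by
    default the training data the forest was grown on must be supplied.
    The permutation RNG derives from the forest's seed, so a fixed
    (spec, data) pair gives bit-identical importances. Evaluation is
    vectorised by stacking permuted copies of X and predicting in chunks of
    at most ``chunk_cells`` matrix cells.
    """
    if forest.spec.importance_kind == "impurity":
        return np.asarray(forest.model.feature_importances_, dtype=float)
    if X is None or y is None:
        raise InputError("permutation importance needs the evaluation data (X, y)")
    Xm = _check_schema(forest, X)
    n, p = Xm.shape
    if forest.spec.task == "regression":
        yv = np.asarray(y, dtype=float)
    else:
        yv = np.asarray(y)
    base = _prediction_score(forest.spec.task, yv, forest.model.predict(Xm))

    rng = np.random.default_rng(np.random.SeedSequence([forest.spec.seed, 0x1B5]))
    perms = np.array([rng.permutation(n) for _ in range(p)])  # one draw per variable

    imp = np.empty(p)
    feats_per_chunk = max(1, int(chunk_cells // (n * p)))
    for start in range(0, p, feats_per_chunk):
        stop = min(start + feats_per_chunk, p)
        m = stop - start
        block = np.repeat(Xm[None, :, :], m, axis=0)  # (m, n, p)
        for i, j in enumerate(range(start, stop)):
            block[i, :, j] = Xm[perms[j], j]
        pred = forest.model.predict(block.reshape(m * n, p))
        pred = pred.reshape(m, n)
        for i, j in enumerate(range(start, stop)):
            imp[j] = base - _prediction_score(forest.spec.task, yv, pred[i])
    return imp
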