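"""Selection decisions from repeated predictions or importances.

Each repetition ranks its subjects and marks the top fraction ``alpha`` as
selected; the agreement of those binary decisions across repetitions
(Fleiss' kappa on a selected/rejected matrix) is the selection stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Optional

import numpy as np

from .exceptions import InputError, UndefinedStabilityError
from .metrics import fleiss_kappa

__all__ = [
    "SelectionSpec",
    "select_from_predictions",
    "select_from_importances",
    "selection_stability",
    "always_selected_fraction",
]

_CRITERIA = ("high", "low", "zero", "classes")


@dataclass(frozen=True)
class SelectionSpec:
    """How to turn one column of predictions into selected/rejected calls.

    alpha : fraction of subjects to select (0 < alpha < 1); the count is
        k = round(alpha * n), floored at 1.
    criterion : "high" (largest values), "low" (smallest), "zero"
        (closest to zero), or "classes" with a label set for categorical
        predictions.
    """

    alpha: float = 0.15
    criterion: str = "high"
    classes: Optional[FrozenSet] = None

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise InputError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.criterion not in _CRITERIA:
            raise InputError(f"criterion must be one of {_CRITERIA}")
        if self.criterion == "classes" and not self.classes:
            raise InputError("criterion 'classes' needs a non-empty label set")

    def k(self, n: int) -> int:
        """Number selected per repetition among n subjects (round, floor 1)."""
        k = max(1, int(round(self.alpha * n)))
        if k >= n:
            raise InputError(
                f"alpha={self.alpha} with n={n} would select every subject"
            )
        return k


def _rank_select(values: np.ndarray, k: int, criterion: str) -> np.ndarray:
    """Boolean mask of the k best subjects. Ties break by subject index."""
    if criterion == "high":
        key = -values
    elif criterion == "low":
        key = values
    else:  # zero
        key = np.abs(values)
    order = np.argsort(key, kind="stable")
    mask = np.zeros(len(values), dtype=bool)
    mask[order[:k]] = True
    return mask


def select_from_predictions(pm, spec: SelectionSpec) -> np.ndarray:
    """Binary n x R selection matrix from an n x R prediction matrix."""
    arr = np.asarray(pm)
    if arr.ndim != 2:
        raise InputError("prediction matrix must be two-dimensional")
    n, r = arr.shape
    if spec.criterion == "classes":
        labels = {str(c) for c in spec.classes}
        observed = {str(v) for v in arr.ravel()}
        unknown = labels - observed
        if unknown == labels:
            raise InputError(
                f"none of the requested classes {sorted(labels)} appear in the "
                "predictions"
            )
        flat = np.array([str(v) in labels for v in arr.ravel()])
        return flat.reshape(n, r)
    vals = arr.astype(float)
    k = spec.k(n)
    out = np.empty((n, r), dtype=bool)
    for j in range(r):
        out[:, j] = _rank_select(vals[:, j], k, spec.criterion)
    return out


def select_from_importances(im, alpha: float = 0.05) -> np.ndarray:
    """Binary p x R selection matrix: top-alpha variables by importance per column."""
    spec = SelectionSpec(alpha=alpha, criterion="high")
    return select_from_predictions(np.asarray(im, dtype=float), spec)


def selection_stability(sm) -> float:
    """Fleiss' kappa of the selected/rejected decisions across repetitions."""
    arr = np.asarray(sm, dtype=bool)
    labels = np.where(arr, "selected", "rejected")
    try:
        return fleiss_kappa(labels)
    except UndefinedStabilityError:
        raise UndefinedStabilityError(
            "selection stability undefined: every repetition made the same "
            "call for every subject in the same single category"
        ) from None


def always_selected_fraction(sm) -> float:
    """Share of ever-selected subjects that were selected in every repetition.

    |selected in all repetitions| / |selected in at least one repetition|.
    """
    arr = np.asarray(sm, dtype=bool)
    ever = arr.any(axis=1)
    if not ever.any():
        raise InputError("no subject was ever selected")
    always = arr.all(axis=1)
    return float(always.sum() / ever.sum())
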