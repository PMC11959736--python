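"""Agreement statistics that define stability.

Repeated forest runs on identical data are treated as R "raters" scoring the
same n subjects (test individuals or predictor variables). For continuous
outputs stability is the intraclass correlation ICC(1,1) — one-way
random-effects model, single measures; for categorical outputs it is
Fleiss' kappa. Both equal 1 exactly on perfect agreement (given
between-subject variation) and are below 1 otherwise.
"""

from __future__ import annotations

import logging

import numpy as np

from .exceptions import InputError, UndefinedStabilityError

__all__ = [
    "icc_1_1",
    "fleiss_kappa",
    "prediction_stability",
    "drop_incomplete_subjects",
]

log = logging.getLogger(__name__)


def _check_matrix(m, *, numeric):
    arr = np.asarray(m)
    if arr.ndim != 2:
        raise InputError("ratings matrix must be two-dimensional")
    n, r = arr.shape
    if n < 2:
        raise InputError("need at least 2 subjects")
    if r < 2:
        raise InputError("need at least 2 repetitions (raters)")
    if numeric:
        arr = arr.astype(float)
        if np.isnan(arr).any():
            raise InputError("ratings matrix contains missing cells")
    else:
        if any(x is None for x in arr.ravel()):
            raise InputError("ratings matrix contains missing cells")
    return arr


def icc_1_1(m) -> float:
    """Intraclass correlation ICC(1,1) of an n x R continuous ratings matrix.

    One-way ANOVA decomposition over subjects:

        MSB = R * var(row means)   (between-subject mean square, df n-1)
        MSW = mean within-row variance (df n(R-1))
        ICC(1,1) = (MSB - MSW) / (MSB + (R-1) * MSW)

    Equals 1 iff every repetition returned identical values per subject while
    subjects differ. Raises :class:`UndefinedStabilityError` when all cells
    are identical, i.e. both variance components vanish.
    """
    arr = _check_matrix(m, numeric=True)
    n, r = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    ssb = r * np.sum((row_means - grand) ** 2)
    ssw = np.sum((arr - row_means[:, None]) ** 2)
    msb = ssb / (n - 1)
    msw = ssw / (n * (r - 1))
    denom = msb + (r - 1) * msw
    if denom == 0.0:
        raise UndefinedStabilityError(
            "ICC(1,1) undefined: all ratings identical (zero between- and "
            "within-subject variance)"
        )
    return float((msb - msw) / denom)


def fleiss_kappa(m) -> float:
    """Fleiss' kappa of an n x R categorical ratings matrix.

    With n_ij the number of raters assigning category j to subject i:

        P_i    = (sum_j n_ij^2 - R) / (R (R - 1))
        p_j    = sum_i n_ij / (n R)
        kappa  = (mean_i P_i - sum_j p_j^2) / (1 - sum_j p_j^2)

    Invariant under relabelling categories. Raises
    :class:`UndefinedStabilityError` when every rater assigns one single
    category to every subject (expected agreement 1).
    """
    arr = _check_matrix(m, numeric=False)
    n, r = arr.shape
    cats, codes = np.unique(arr.astype(str), return_inverse=True)
    codes = codes.reshape(n, r)
    counts = np.zeros((n, len(cats)), dtype=np.int64)
    for j in range(r):
        np.add.at(counts, (np.arange(n), codes[:, j]), 1)
    p_i = (np.sum(counts**2, axis=1) - r) / (r * (r - 1))
    p_j = counts.sum(axis=0) / (n * r)
    p_bar = p_i.mean()
    p_e = float(np.sum(p_j**2))
    if p_e >= 1.0:
        raise UndefinedStabilityError(
            "Fleiss' kappa undefined: a single category was assigned to every "
            "subject by every rater (chance agreement 1)"
        )
    return float((p_bar - p_e) / (1.0 - p_e))


def drop_incomplete_subjects(m) -> np.ndarray:
    """Remove rows with any missing repetition (NaN or None), logging the count.

    OOB prediction can leave individuals without a prediction in some
    repetitions (in-bag for every tree); such subjects are dropped before an
    agreement statistic is computed.
    """
    arr = np.asarray(m)
    if arr.dtype.kind == "f":
        keep = ~np.isnan(arr).any(axis=1)
    else:
        keep = ~np.array(
            [any(x is None or x != x for x in row) for row in arr], dtype=bool
        )
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropped %d subject(s) with missing repetitions", dropped)
    return arr[keep]


def prediction_stability(pm, task: str) -> float:
    """Stability of a prediction matrix: ICC(1,1) for regression, Fleiss' kappa otherwise."""
    if task == "regression":
        return icc_1_1(pm)
    if task == "classification":
        return fleiss_kappa(pm)
    raise InputError(f"unknown task {task!r}")
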