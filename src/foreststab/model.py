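"""The two-parameter logistic (2PL) model of stability versus tree count.

Stability s of a forest with t trees is modelled as

    s_hat(t) = 1 / (1 + (theta1 / t) ** theta2),        theta1, theta2 > 0

a logistic in log t: theta1 is the tree count at which modelled stability is
exactly 0.5 and theta2 the slope there. The curve rises from 0 to an
asymptote of 1, matching the range of the agreement statistics it describes.
Fitting is nonlinear least squares via Levenberg-Marquardt; the closed-form
inverse t(s) = theta1 * (1/s - 1) ** (-1/theta2) supports "how many trees
for stability s*" queries, and a forward-difference scan over t turns the
fitted curve into a concrete tree-count recommendation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .exceptions import FittingError, InputError

__all__ = [
    "TwoPLStabilityModel",
    "Recommendation",
    "fit_2pl",
    "predict_stability",
    "estimate_numtrees",
    "recommend_num_trees",
    "estimate_runtime",
]

SEARCH_MIN = 10
SEARCH_MAX = 10_000_000
SCAN_STEP = 10
DEFAULT_REC_THRESH = 1e-6
ROUND_TO = 1000


@dataclass(frozen=True)
class Recommendation:
    """Recommended tree count with the modelled stability it achieves."""

    num_trees: int
    stability: float
    basis: str
    rec_thresh: float
    saturated: bool = False  # threshold never met inside the search interval


def _two_pl(t, theta1, theta2):
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):  # theta1 may underflow in degenerate fits
        return 1.0 / (1.0 + np.exp(theta2 * (np.log(theta1) - np.log(t))))


class TwoPLStabilityModel(BaseEstimator):
    """Least-squares fit of the two-parameter logistic stability curve.

    Parameters
    ----------
    rec_thresh : float
        Marginal-stability threshold per ten added trees below which more
        trees are judged not worthwhile.
    round_to : int
        Recommendations are rounded up to the next multiple of this
        granularity (set 1 to disable).
    weights : array-like or None
        Optional residual weights; default unweighted.

    Attributes
    ----------
    theta1_ : float
        Tree count at which the modelled stability is 0.5.
    theta2_ : float
        Slope parameter at ``theta1_``.
    residuals_ : ndarray
        Fit residuals s - s_hat at the supplied grid points.
    n_points_ : int
        Number of usable (t, s) points the fit used.
    degenerate_ : bool
        True when the points carry no information about theta1 (e.g. all
        stabilities equal); the fit is then flagged rather than trusted.
    """

    def __init__(self, rec_thresh: float = DEFAULT_REC_THRESH,
                 round_to: int = ROUND_TO, weights=None):
        self.rec_thresh = rec_thresh
        self.round_to = round_to
        self.weights = weights

    # -- fitting -----------------------------------------------------------

    def fit(self, num_trees: Sequence[float], stability: Sequence[float]):
        """Fit the curve to measured (tree count, stability) points.

        Points with stability <= 0 carry no information under the model
        (its range is (0, 1)) and are excluded with a warning; stabilities
        >= 1 are clipped just below 1. At least 3 usable points are
        required.
        """
        t = np.asarray(num_trees, dtype=float)
        s = np.asarray(stability, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise InputError("num_trees and stability must be 1-D and equal length")
        usable = np.isfinite(s) & np.isfinite(t) & (s > 0) & (t > 0)
        if (~usable & np.isfinite(s)).any():
            warnings.warn(
                f"excluding {int((~usable).sum())} point(s) with non-positive "
                "or undefined stability from the 2PL fit",
                stacklevel=2,
            )
        t, s = t[usable], s[usable]
        if t.size < 3:
            raise InputError(
                f"2PL fit needs at least 3 usable (t, s) points, got {t.size}"
            )
        s = np.clip(s, None, 1.0 - 1e-12)

        w = np.ones_like(s) if self.weights is None else np.asarray(self.weights, float)[usable]

        # Closed-form start: logit(s) = theta2 * (ln t - ln theta1) is linear
        # in ln t; an OLS line gives robust initial values even for s near 1.
        logit = np.log(s / (1.0 - s))
        slope, intercept = np.polyfit(np.log(t), logit, 1)
        slope = max(slope, 1e-3)
        log_theta1 = float(np.clip(-intercept / slope, math.log(1e-3), math.log(1e12)))
        x0 = np.array([log_theta1, math.log(slope)])

        def resid(x):
            th1, th2 = math.exp(x[0]), math.exp(x[1])
            return w * (s - _two_pl(t, th1, th2))

        # exp-parameterisation keeps both parameters positive under plain LM
        res = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if not res.success:
            raise FittingError(
                f"Levenberg-Marquardt did not converge: {res.message}",
                init=x0, residuals=res.fun,
            )
        self.theta1_ = float(math.exp(res.x[0]))
        self.theta2_ = float(math.exp(res.x[1]))
        self.residuals_ = s - _two_pl(t, self.theta1_, self.theta2_)
        self.n_points_ = int(t.size)
        # no spread in stabilities -> theta1 unidentified
        self.degenerate_ = bool(np.ptp(s) < 1e-6 or not np.isfinite(self.theta1_))
        if self.degenerate_:
            warnings.warn(
                "2PL fit is degenerate: stability points carry no information "
                "about theta1", stacklevel=2,
            )
        return self

    @classmethod
    def from_parameters(cls, theta1: float, theta2: float, **kwargs):
        """Construct an already-parameterised model (no fitting)."""
        if theta1 <= 0 or theta2 <= 0:
            raise InputError("theta1 and theta2 must be positive")
        m = cls(**kwargs)
        m.theta1_ = float(theta1)
        m.theta2_ = float(theta2)
        m.residuals_ = np.array([])
        m.n_points_ = 0
        m.degenerate_ = False
        return m

    def _check_fitted(self):
        if not hasattr(self, "theta1_"):
            raise InputError("model is not fitted")

    # -- forward and inverse evaluation ------------------------------------

    def predict(self, num_trees) -> np.ndarray:
        """Modelled stability s_hat(t) in (0, 1), strictly increasing in t."""
        self._check_fitted()
        t = np.asarray(num_trees, dtype=float)
        if np.any(t <= 0):
            raise InputError("tree counts must be positive")
        return _two_pl(t, self.theta1_, self.theta2_)

    def estimate_stability(self, num_trees) -> float:
        """Scalar convenience wrapper around :meth:`predict`."""
        return float(self.predict(num_trees))

    def estimate_numtrees(self, target_stability: float) -> int:
        """Smallest integer tree count whose modelled stability reaches the target.

        Closed-form inverse t = theta1 * (1/s* - 1) ** (-1/theta2), ceiled.
        """
        self._check_fitted()
        s = float(target_stability)
        if not 0.0 < s < 1.0:
            raise InputError("target stability must be in (0, 1)")
        t = self.theta1_ * (1.0 / s - 1.0) ** (-1.0 / self.theta2_)
        return int(math.ceil(t))

    # -- recommendation ----------------------------------------------------

    def recommend(self, rec_thresh: Optional[float] = None,
                  basis: str = "prediction") -> Recommendation:
        """Smallest worthwhile tree count.

        Scans t = 10, 20, ..., 10,000,000 and returns the first t at which
        adding ten more trees raises the modelled stability by at most
        ``rec_thresh``, rounded up to the configured granularity (multiples
        of 1,000 by default). If the threshold is never met the upper end of
        the interval is returned with a saturation flag.
        """
        self._check_fitted()
        thresh = self.rec_thresh if rec_thresh is None else float(rec_thresh)
        t_found = None
        chunk = 100_000
        for lo in range(SEARCH_MIN, SEARCH_MAX, chunk * SCAN_STEP):
            hi = min(lo + chunk * SCAN_STEP, SEARCH_MAX)
            grid = np.arange(lo, hi, SCAN_STEP, dtype=float)
            gain = self.predict(grid + SCAN_STEP) - self.predict(grid)
            idx = np.nonzero(gain <= thresh)[0]
            if idx.size:
                t_found = int(grid[idx[0]])
                break
        saturated = t_found is None
        if saturated:
            warnings.warn(
                "stability gain never fell below rec_thresh inside the search "
                "interval; recommendation saturates at its upper end",
                stacklevel=2,
            )
            t_rec = SEARCH_MAX
        else:
            t_rec = t_found
            if self.round_to > 1:
                t_rec = int(math.ceil(t_rec / self.round_to) * self.round_to)
        return Recommendation(
            num_trees=t_rec,
            stability=float(self.predict(t_rec)),
            basis=basis,
            rec_thresh=thresh,
            saturated=saturated,
        )

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "theta1": self.theta1_,
            "theta2": self.theta2_,
            "residuals": np.asarray(self.residuals_).tolist(),
            "n_points": self.n_points_,
            "degenerate": self.degenerate_,
        }


# -- functional façade ------------------------------------------------------

def fit_2pl(num_trees, stability, **kwargs) -> TwoPLStabilityModel:
    """Fit the 2PL stability curve; see :class:`TwoPLStabilityModel`."""
    return TwoPLStabilityModel(**kwargs).fit(num_trees, stability)


def predict_stability(fit: TwoPLStabilityModel, num_trees):
    """Evaluate a fitted 2PL model; scalar in, scalar out."""
    out = fit.predict(num_trees)
    return float(out) if np.ndim(num_trees) == 0 else out


def estimate_numtrees(fit: TwoPLStabilityModel, target_stability: float) -> int:
    return fit.estimate_numtrees(target_stability)


def recommend_num_trees(fit: TwoPLStabilityModel,
                        rec_thresh: float = DEFAULT_REC_THRESH,
                        basis: str = "prediction") -> Recommendation:
    return fit.recommend(rec_thresh=rec_thresh, basis=basis)


def estimate_runtime(num_trees, runtime_sec, t) -> float:
    """Extrapolate forest runtime to t trees from grid measurements.

    Runtime grows linearly in the number of trees, so an ordinary
    least-squares line a + b*t (slope clamped at 0) is fitted to the
    measured (tree count, seconds) pairs and evaluated at t.
    """
    x = np.asarray(num_trees, dtype=float)
    y = np.asarray(runtime_sec, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise InputError("runtime extrapolation needs >= 2 distinct tree counts")
    b, a = np.polyfit(x, y, 1)
    if b < 0:
        b, a = 0.0, float(y.mean())
    return float(a + b * float(t))
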