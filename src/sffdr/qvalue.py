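"""Storey q values: the standard (covariate-free) FDR baseline.

The proportion of truly null tests pi0 is estimated on the grid
lambda = 0.05, 0.10, ..., 0.95 as ``#{p > lambda} / (m (1 - lambda))`` and
smoothed with a cubic fit evaluated at the largest lambda; q values are the
pi0-scaled Benjamini-Hochberg running minimum.  With ``pi0_method="fixed"``
and ``pi0_fixed=1`` the q values reduce exactly to BH adjusted P values.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["StoreyQValue", "storey_qvalue", "storey_pi0"]


def _validate_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a nonempty 1-d array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p values must lie in (0, 1]")
    return p


def storey_pi0(p, lambda_grid=None) -> float:
    """Smoother estimate of the null proportion.

    A cubic least-squares fit of the thresholding estimates
    pi0(lambda) over the lambda grid, evaluated at the largest lambda.
    """
    p = _validate_p(p)
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.951, 0.05)
    lam = np.asarray(lambda_grid, dtype=float)
    pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
    coef = np.polynomial.polynomial.polyfit(lam, pi0_lam, 3)
    pi0 = float(np.polynomial.polynomial.polyval(lam.max(), coef))
    return float(np.clip(pi0, 1.0 / len(p), 1.0))


def _qvalues_from_p(p: np.ndarray, pi0: float) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class StoreyQValue(BaseEstimator):
    """FDR q values from P values alone.

    Parameters
    ----------
    pi0_method : {"smoother", "fixed"}
        How to estimate the null proportion.
    pi0_fixed : float, optional
        Value used when ``pi0_method="fixed"``.
    lambda_grid : array-like, optional
        Thresholds for the smoother (default 0.05..0.95 step 0.05).

    Attributes
    ----------
    pi0_ : float
        Estimated null proportion.
    qvalues_ : ndarray
        Per-test q values, aligned with the input order.
    """

    def __init__(self, pi0_method="smoother", pi0_fixed=None, lambda_grid=None):
        self.pi0_method = pi0_method
        self.pi0_fixed = pi0_fixed
        self.lambda_grid = lambda_grid

    def fit(self, p, y=None):
        p = _validate_p(p)
        if self.pi0_method == "smoother":
            self.pi0_ = storey_pi0(p, self.lambda_grid)
        elif self.pi0_method == "fixed":
            if self.pi0_fixed is None or not 0 < self.pi0_fixed <= 1:
                raise ValueError("pi0_fixed must be in (0,1] when pi0_method='fixed'")
            self.pi0_ = float(self.pi0_fixed)
        else:
            raise ValueError(f"unknown pi0_method {self.pi0_method!r}")
        self.qvalues_ = _qvalues_from_p(p, self.pi0_)
        return self


def storey_qvalue(p, pi0_method="smoother", pi0_fixed=None, lambda_grid=None) -> StoreyQValue:
    """Convenience wrapper returning a fitted :class:`StoreyQValue`."""
    return StoreyQValue(
        pi0_method=pi0_method, pi0_fixed=pi0_fixed, lambda_grid=lambda_grid
    ).fit(p)
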