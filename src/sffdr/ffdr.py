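"""Functional local FDR, functional q values and functional P values.

Given per-SNP primary P values p and informative-study P values z, the
two-group mixture posterior null probability (functional local FDR) is

    Lambda(p, z) = pi0(z) / f(p | z)  ~=  pi0(z) * f(r) / f(p, r),

where r is the surrogate variable built from ranked pi0(z).  From the
local FDRs:

* the functional q value of SNP i is the mean of all Lambda values less
  than or equal to Lambda_i (the pFDR of the smallest significance region
  containing the SNP), and
* the functional P value is ECDF_Lambda(Lambda_i) * q_f,i / pi0 -- the
  type I error rate of that region -- which behaves like a standard
  P value and can enter FWER procedures.

The :class:`SfFDR` estimator wires the full pipeline together: fit the
pi0(z) GAM and the surrogate density on an (optionally LD-independent)
training subset, predict both for every scored SNP, and form Lambda, q_f
and p_f.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .density import SurrogateDensity, make_surrogate
from .pi0 import DEFAULT_KNOT_QUANTILES, Pi0GAM, _validate_pz

__all__ = ["SfFDR", "local_fdr", "qf_values", "pf_values", "overall_pi0"]

LFDR_FLOOR = 1e-12


def local_fdr(pi0_z, joint, marginal, lfdr_floor: float = LFDR_FLOOR) -> np.ndarray:
    """Lambda = min(1, pi0(z) * f(r) / f(p, r)), floored away from zero."""
    pi0_z = np.asarray(pi0_z, dtype=float)
    joint = np.asarray(joint, dtype=float)
    marginal = np.asarray(marginal, dtype=float)
    lam = pi0_z * marginal / joint
    return np.clip(lam, lfdr_floor, 1.0)


def qf_values(lfdr) -> np.ndarray:
    """Running mean of the ascending-sorted local FDRs, ties pooled.

    q_f,i = mean of {Lambda_j : Lambda_j <= Lambda_i}; for tied Lambda the
    averaging set includes every tied SNP.
    """
    lfdr = np.asarray(lfdr, dtype=float)
    if lfdr.ndim != 1 or lfdr.size == 0:
        raise ValueError("lfdr must be a nonempty 1-d array")
    n = lfdr.size
    order = np.argsort(lfdr, kind="mergesort")
    s = lfdr[order]
    cummean = np.cumsum(s) / np.arange(1, n + 1)
    last = np.searchsorted(s, s, side="right") - 1  # last index of each tie group
    q = np.empty(n)
    q[order] = cummean[last]
    return q


def pf_values(lfdr, qf, pi0_overall: float) -> np.ndarray:
    """p_f,i = ECDF_Lambda(Lambda_i) * q_f,i / pi0, clipped to (0, 1].

    The ECDF uses the weak inequality over all scored SNPs.
    """
    lfdr = np.asarray(lfdr, dtype=float)
    qf = np.asarray(qf, dtype=float)
    if lfdr.shape != qf.shape:
        raise ValueError("lfdr and qf must be aligned")
    if not 0 < pi0_overall <= 1:
        raise ValueError("pi0_overall must be in (0, 1]")
    s = np.sort(lfdr)
    ecdf = np.searchsorted(s, lfdr, side="right") / lfdr.size
    pf = ecdf * qf / pi0_overall
    return np.clip(pf, np.finfo(float).tiny, 1.0)


def overall_pi0(pi0_z, method: str = "mean", qf=None) -> float:
    """Study-wide null proportion: mean of pi0(z) or the maximum q_f."""
    if method == "mean":
        value = float(np.mean(np.asarray(pi0_z, dtype=float)))
    elif method == "max_qf":
        if qf is None:
            raise ValueError("method='max_qf' requires the q_f values")
        value = float(np.max(np.asarray(qf, dtype=float)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(np.clip(value, np.finfo(float).tiny, 1.0))


class SfFDR(BaseEstimator):
    """Surrogate functional FDR estimator.

    Parameters
    ----------
    lambda_grid, knot_quantiles, pi0_floor, min_training
        Passed to :class:`~sffdr.pi0.Pi0GAM`.
    span_floor : float
        Lower bound on the density smoothing fraction (the neighbourhood
        always covers at least this share of the training data).
    grid_size, density_floor, probit_clamp
        Passed to :class:`~sffdr.density.SurrogateDensity`.
    pi0_method : {"mean", "max_qf"}
        Study-wide pi0 estimate entering the functional P value.
    null_robust : bool
        Guard for primary studies with little or no signal: hold pi0(z)
        at its constant mean and widen the smoothing span to at least 0.1,
        suppressing the slight inflation overfitting can otherwise cause.
    random_state : int, optional
        Seeds the surrogate tie-break; fits are otherwise deterministic.

    Attributes
    ----------
    lfdr_, qvalues_, pvalues_ : ndarray
        Functional local FDR, q_f and p_f per scored SNP.
    pi0_ : float
        Study-wide null-proportion estimate.
    pi0_z_ : ndarray
        Predicted functional null proportion per SNP.
    r_ : ndarray
        Surrogate variable per SNP.
    span_ : float
        Smoothing fraction used by the density estimator.
    pi0_fit_ : Pi0GAM
    density_fit_ : SurrogateDensity
    """

    def __init__(
        self,
        lambda_grid=None,
        knot_quantiles=DEFAULT_KNOT_QUANTILES,
        pi0_floor=1e-4,
        min_training=1000,
        span_floor=0.02,
        grid_size=(300, 32),
        density_floor=1e-10,
        probit_clamp=1e-15,
        pi0_method="mean",
        null_robust=False,
        random_state=None,
    ):
        self.lambda_grid = lambda_grid
        self.knot_quantiles = knot_quantiles
        self.pi0_floor = pi0_floor
        self.min_training = min_training
        self.span_floor = span_floor
        self.grid_size = grid_size
        self.density_floor = density_floor
        self.probit_clamp = probit_clamp
        self.pi0_method = pi0_method
        self.null_robust = null_robust
        self.random_state = random_state

    def fit(self, Z, p, train=None):
        """Fit the pipeline and score every SNP.

        Parameters
        ----------
        Z : array-like of shape (n, d)
            Informative-study P values.
        p : array-like of shape (n,)
            Primary-study P values.
        train : boolean array-like of shape (n,), optional
            LD-independent training subset used to fit pi0(z) and the
            joint density; all SNPs are scored.  Default: train on all.
        """
        Z, p = _validate_pz(Z, p)
        n = len(p)
        if train is None:
            train = np.ones(n, dtype=bool)
        else:
            train = np.asarray(train, dtype=bool)
            if train.shape != (n,):
                raise ValueError("train flag must align with p and Z")
            if not train.any():
                raise ValueError("training subset is empty")
        self.train_ = train

        self.pi0_fit_ = Pi0GAM(
            lambda_grid=self.lambda_grid,
            knot_quantiles=self.knot_quantiles,
            pi0_floor=self.pi0_floor,
            min_training=self.min_training,
        ).fit(Z[train], p[train])
        pi0_z = self.pi0_fit_.predict(Z)
        if self.null_robust:
            pi0_z = np.full(n, float(pi0_z.mean()))
        self.pi0_z_ = pi0_z

        surrogate = make_surrogate(pi0_z[train], seed=self.random_state)
        r = np.empty(n)
        r[train] = surrogate.r
        if (~train).any():
            r[~train] = surrogate.predict(pi0_z[~train])
        self.surrogate_ = surrogate
        self.r_ = r

        span = max(1.0 - float(pi0_z[train].mean()), self.span_floor)
        if self.null_robust:
            span = max(span, 0.1)
        self.span_ = span
        self.density_fit_ = SurrogateDensity(
            span=span,
            grid_size=self.grid_size,
            density_floor=self.density_floor,
            probit_clamp=self.probit_clamp,
        ).fit(p[train], r[train])
        # marginal f(r) over every scored SNP (non-uniform once LD SNPs enter)
        self.density_fit_.fit_marginal(r)

        joint = self.density_fit_.joint(p, r)
        marginal = self.density_fit_.marginal(r)
        self.lfdr_ = local_fdr(pi0_z, joint, marginal)
        self.qvalues_ = qf_values(self.lfdr_)
        self.pi0_ = overall_pi0(pi0_z, method=self.pi0_method, qf=self.qvalues_)
        self.pvalues_ = pf_values(self.lfdr_, self.qvalues_, self.pi0_)
        return self

    def fit_table(self, table, train_col: str = "is_training"):
        """Fit from a harmonized study table (columns p, z_1..z_d)."""
        zcols = [c for c in table.columns if c.startswith("z_")]
        train = table[train_col].to_numpy(dtype=bool) if train_col in table.columns else None
        return self.fit(table[zcols].to_numpy(), table["p"].to_numpy(), train=train)
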