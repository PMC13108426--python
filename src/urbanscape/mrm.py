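"""Multiple regression on distance matrices with permutation inference.

OLS on the vectorised lower triangles of pairwise matrices; significance
by the Mantel-family null: the row/column order of the response matrix is
permuted jointly (preserving the pairwise dependence structure), the
statistic recomputed, and p = (1 + #{perm >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .containers import SymmetricMatrix, check_shared_labels

__all__ = ["MatrixRegression", "MRMResult", "mrm"]


class MRMResult:
    def __init__(self, coefficients, r_squared, f_statistic, p_r2, p_coef, n_perm, seed):
        self.coefficients = coefficients  # intercept first
        self.r_squared = r_squared
        self.f_statistic = f_statistic
        self.p_r2 = p_r2
        self.p_coef = p_coef  # per slope (|t| permutation p), intercept excluded
        self.n_perm = n_perm
        self.seed = seed


def _ols(x: np.ndarray, y: np.ndarray):
    """Least squares with R^2, F and per-coefficient t statistics."""
    n, p = x.shape
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < p:
        raise ValueError("constant or collinear predictor: coefficients undefined")
    resid = y - x @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    df_res = n - p
    sigma2 = ss_res / df_res
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 1e-300))
    tvals = beta / se
    q = p - 1
    f = (r2 / q) / ((1 - r2) / df_res) if q > 0 and r2 < 1 else np.inf
    return beta, r2, f, tvals


class MatrixRegression(BaseEstimator):
    """MRM estimator over labelled symmetric matrices.

    Parameters: n_perm (permutations), random_state.  After ``fit``:
    ``coef_`` (intercept first), ``r_squared_``, ``f_``, ``p_r2_``,
    ``p_coef_`` (per-slope |t| permutation p).
    """

    def __init__(self, n_perm: int = 9999, random_state: int | None = None):
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X: list[SymmetricMatrix], y: SymmetricMatrix) -> "MatrixRegression":
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        labels = check_shared_labels(y, *X)
        preds = [m.reindex(labels) for m in X]
        n = len(labels)
        yv = y.condensed()
        design = np.column_stack([np.ones(len(yv))] + [m.condensed() for m in preds])

        beta, r2, f, tvals = _ols(design, yv)

        rng = np.random.default_rng(self.random_state)
        i, j = np.tril_indices(n, k=-1)
        count_r2 = 0
        count_t = np.zeros(design.shape[1] - 1)
        obs_t = np.abs(tvals[1:])
        for _ in range(self.n_perm):
            perm = rng.permutation(n)
            yp = y.values[np.ix_(perm, perm)][i, j]
            _, r2p, _, tp = _ols(design, yp)
            count_r2 += r2p >= r2
            count_t += np.abs(tp[1:]) >= obs_t
        self.coef_ = beta
        self.r_squared_ = r2
        self.f_ = f
        self.p_r2_ = (1 + count_r2) / (1 + self.n_perm)
        self.p_coef_ = (1 + count_t) / (1 + self.n_perm)
        return self


def mrm(
    response: SymmetricMatrix,
    predictors: list[SymmetricMatrix],
    n_perm: int = 9999,
    seed: int | None = None,
) -> MRMResult:
    """Fit an MRM of ``response`` on ``predictors`` (see module docstring)."""
    est = MatrixRegression(n_perm=n_perm, random_state=seed).fit(predictors, response)
    return MRMResult(
        coefficients=est.coef_,
        r_squared=est.r_squared_,
        f_statistic=est.f_,
        p_r2=est.p_r2_,
        p_coef=est.p_coef_,
        n_perm=n_perm,
        seed=seed,
    )
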