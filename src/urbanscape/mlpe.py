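"""Maximum-likelihood population-effects (MLPE) models on distance matrices.

Pairwise distance observations are not independent: two pairs that share a
population are correlated.  The MLPE model fits y_pair = X beta + eps with
corr(eps_ab, eps_cd) = rho when the pairs {a,b} and {c,d} share exactly
one population and 0 otherwise.  The correlation matrix is I + rho * A
with A the adjacency matrix of the triangular (pair) graph, positive
definite for rho < 0.5.  Estimation is maximum likelihood (not REML, so
models differing in fixed effects are AICc-comparable): profile
likelihood over rho with GLS for beta and sigma^2 at each rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator

from .containers import SymmetricMatrix, check_shared_labels

__all__ = ["MLPE", "MLPEFit", "fit_mlpe", "compare_models", "vif", "pair_adjacency"]


def pair_adjacency(n_pops: int) -> np.ndarray:
    """Adjacency of pairs sharing exactly one population (triangular graph)."""
    i, j = np.tril_indices(n_pops, k=-1)
    pairs = list(zip(i, j))
    m = len(pairs)
    a = np.zeros((m, m))
    for u in range(m):
        for v in range(u + 1, m):
            shared = len(set(pairs[u]) & set(pairs[v]))
            if shared == 1:
                a[u, v] = a[v, u] = 1.0
    return a


@dataclass
class MLPEFit:
    beta: np.ndarray  # intercept first, slopes on z-scored predictors
    beta_se: np.ndarray
    rho: float
    sigma2: float
    loglik: float
    n_pairs: int
    k: int  # betas + rho + sigma^2
    r_squared: float  # squared correlation of fitted vs observed
    predictor_names: list = field(default_factory=list)
    rho_at_boundary: bool = False
    response_id: str = ""

    @property
    def aicc(self) -> float:
        n, k = self.n_pairs, self.k
        if n <= k + 1:
            raise ValueError("AICc undefined: n <= k + 1")
        return -2 * self.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    @property
    def bic(self) -> float:
        return -2 * self.loglik + self.k * np.log(self.n_pairs)

    def wald_ci(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.beta - z * self.beta_se, self.beta + z * self.beta_se])


class MLPE(BaseEstimator):
    """MLPE estimator over labelled symmetric matrices.

    Predictors are z-scored internally; fitted attributes follow the
    sklearn convention (``beta_``, ``rho_``, ``sigma2_``, ``loglik_``).
    """

    def __init__(self, rho_max: float = 0.499):
        self.rho_max = rho_max

    def fit(self, X: list[SymmetricMatrix], y: SymmetricMatrix) -> "MLPE":
        labels = check_shared_labels(y, *X)
        n_pops = len(labels)
        if n_pops < 4:
            raise ValueError("need at least 4 populations")
        yv = y.condensed()
        n = len(yv)
        cols, self.scale_ = [], []
        for m in X:
            v = m.reindex(labels).condensed()
            mu, sd = v.mean(), v.std(ddof=0)
            if sd == 0:
                raise ValueError("constant predictor matrix")
            cols.append((v - mu) / sd)
            self.scale_.append((mu, sd))
        design = np.column_stack([np.ones(n)] + cols)
        p = design.shape[1]
        adj = pair_adjacency(n_pops)
        eye = np.eye(n)

        def profile(rho: float):
            c = eye + rho * adj
            try:
                chol = np.linalg.cholesky(c)
            except np.linalg.LinAlgError:
                return None
            xs = solve_triangular(chol, design, lower=True)
            ys = solve_triangular(chol, yv, lower=True)
            xtx = xs.T @ xs
            try:
                beta = np.linalg.solve(xtx, xs.T @ ys)
            except np.linalg.LinAlgError:
                raise ValueError("singular GLS system")
            resid = ys - xs @ beta
            sigma2 = float(resid @ resid) / n
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
            return ll, beta, sigma2, xtx

        res = optimize.minimize_scalar(
            lambda r: -profile(r)[0],
            bounds=(0.0, self.rho_max),
            method="bounded",
            options={"xatol": 1e-8},
        )
        rho = float(res.x)
        ll, beta, sigma2, xtx = profile(rho)
        # boundary check: compare against the endpoints explicitly
        for edge in (0.0, self.rho_max):
            ll_edge = profile(edge)[0]
            if ll_edge > ll:
                rho, (ll, beta, sigma2, xtx) = edge, profile(edge)
        cov_beta = sigma2 * np.linalg.inv(xtx)
        self.beta_ = beta
        self.beta_se_ = np.sqrt(np.diag(cov_beta))
        self.rho_ = rho
        self.sigma2_ = sigma2
        self.loglik_ = float(ll)
        self.n_pairs_ = n
        self.k_ = p + 2
        fitted = design @ beta
        if np.std(fitted) > 0 and np.std(yv) > 0:
            self.r_squared_ = float(np.corrcoef(fitted, yv)[0, 1] ** 2)
        else:
            self.r_squared_ = 0.0
        self.rho_at_boundary_ = rho >= self.rho_max - 1e-6
        return self

    def to_fit(self, names: list | None = None, response_id: str = "") -> MLPEFit:
        return MLPEFit(
            beta=self.beta_,
            beta_se=self.beta_se_,
            rho=self.rho_,
            sigma2=self.sigma2_,
            loglik=self.loglik_,
            n_pairs=self.n_pairs_,
            k=self.k_,
            r_squared=self.r_squared_,
            predictor_names=names or [],
            rho_at_boundary=self.rho_at_boundary_,
            response_id=response_id,
        )


def fit_mlpe(
    response: SymmetricMatrix,
    predictors: list[SymmetricMatrix],
    names: list | None = None,
) -> MLPEFit:
    """ML fit of the MLPE model (see module docstring)."""
    est = MLPE().fit(predictors, response)
    return est.to_fit(names=names, response_id=str(id(response)))


def _weights(ic: np.ndarray) -> np.ndarray:
    delta = ic - ic.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def compare_models(fits: list[MLPEFit], names: list | None = None) -> pd.DataFrame:
    """AICc/BIC evidence weights and Wald CIs across candidate models.

    All fits must be on the same response (same number of pairs).
    """
    if len({f.n_pairs for f in fits}) != 1:
        raise ValueError("fits are not on the same response")
    aicc = np.array([f.aicc for f in fits])
    bic = np.array([f.bic for f in fits])
    w_aicc = _weights(aicc)
    w_bic = _weights(bic)
    rows = []
    for i, f in enumerate(fits):
        ci = f.wald_ci()
        rows.append(
            {
                "model": (names[i] if names else f"model_{i}"),
                "r_squared": f.r_squared,
                "loglik": f.loglik,
                "k": f.k,
                "aicc": aicc[i],
                "delta_aicc": aicc[i] - aicc.min(),
                "aicc_weight": w_aicc[i],
                "bic_weight": w_bic[i],
                "beta": f.beta[1] if len(f.beta) > 1 else np.nan,
                "ci_lower": ci[1, 0] if len(f.beta) > 1 else np.nan,
                "ci_upper": ci[1, 1] if len(f.beta) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def vif(predictors: list[SymmetricMatrix], names: list | None = None) -> pd.DataFrame:
    """Variance inflation factors over vectorised predictor matrices."""
    if len(predictors) < 2:
        raise ValueError("need at least 2 predictors")
    labels = check_shared_labels(*predictors)
    cols = np.column_stack([m.reindex(labels).condensed() for m in predictors])
    out = []
    for j in range(cols.shape[1]):
        others = np.delete(cols, j, axis=1)
        x = np.column_stack([np.ones(len(cols)), others])
        beta, _, _, _ = np.linalg.lstsq(x, cols[:, j], rcond=None)
        resid = cols[:, j] - x @ beta
        ss_tot = ((cols[:, j] - cols[:, j].mean()) ** 2).sum()
        r2 = 1.0 - (resid @ resid) / ss_tot if ss_tot > 0 else 0.0
        out.append(
            {
                "predictor": names[j] if names else f"pred_{j}",
                "vif": np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2),
            }
        )
    return pd.DataFrame(out)
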