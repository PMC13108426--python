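"""Admixture estimation by masked nonnegative matrix factorisation.

Emulates sparse-NMF ancestry inference: the dosage matrix (divided by
ploidy) is factorised as Q G with ancestry proportions Q on the simplex
and ancestral allele frequencies G in [0, 1], by alternating least squares
with projection.  Model choice over K uses masked cross-entropy: a random
fraction of observed genotypes is held out, the model is fitted on the
rest, and the criterion is the negative mean binomial log-likelihood of
the held-out genotypes under p = (QG).  The number of clusters minimising
the mean cross-entropy across repetitions is selected.

This is a behavioural emulation of the LEA/snmf approach (ALS-NMF plus
masked cross-entropy), not a numeric port.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy
from sklearn.base import BaseEstimator

__all__ = ["SNMF", "AdmixtureResult", "admixture_snmf"]


def _project_rows_to_simplex(q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = q.shape
    if k == 1:
        return np.ones_like(q)
    u = np.sort(q, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(q - theta[:, None], 0.0)


def _binomial_cross_entropy(x: np.ndarray, p: np.ndarray) -> float:
    """Negative mean log Binomial(2, p) likelihood of dosages x."""
    p = np.clip(p, 1e-6, 1.0 - 1e-6)
    ll = xlogy(x, p) + xlogy(2.0 - x, 1.0 - p) + np.where(x == 1.0, np.log(2.0), 0.0)
    return float(-np.mean(ll))


class SNMF(BaseEstimator):
    """Single-K masked NMF admixture model.

    Parameters
    ----------
    n_clusters : number of ancestral clusters K.
    mask_frac : fraction of observed genotypes held out for cross-entropy.
    max_iter : maximum ALS sweeps.
    tol : relative change in training loss treated as convergence.
    random_state : seed for initialisation and masking.

    Attributes (after fit)
    ----------------------
    Q_ : (n_individuals, K) ancestry proportions, rows on the simplex.
    G_ : (K, n_loci) ancestral allele frequencies in [0, 1].
    cross_entropy_ : masked cross-entropy on the held-out genotypes.
    train_loss_path_ : per-sweep training squared loss (non-increasing;
        a sweep that would increase it is reverted and iteration stops).
    converged_ : False if max_iter was reached without the tol criterion.
    """

    def __init__(
        self,
        n_clusters: int = 1,
        mask_frac: float = 0.05,
        max_iter: int = 200,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.mask_frac = mask_frac
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "SNMF":
        """Fit on an individuals x loci dosage matrix (nan = missing)."""
        x = np.asarray(X, dtype=float)
        n, L = x.shape
        k = self.n_clusters
        if not (1 <= k <= n - 1 or k == 1):
            raise ValueError("n_clusters must be in [1, n_individuals - 1]")
        rng = np.random.default_rng(self.random_state)

        observed = ~np.isnan(x)
        heldout = observed & (rng.random(x.shape) < self.mask_frac)
        train = observed & ~heldout

        y01 = np.where(train, x / 2.0, np.nan)
        col_mean = np.nanmean(y01, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.5, col_mean)

        q = rng.dirichlet(np.ones(k), size=n)
        g = np.clip(col_mean[None, :] + 0.1 * rng.standard_normal((k, L)), 1e-4, 1 - 1e-4)

        # EM-style fill of non-training entries with the model prediction
        filled = np.where(train, y01, col_mean[None, :])
        loss_path = []

        def train_loss(qm, gm):
            resid = (y01 - qm @ gm)[train]
            return float(np.mean(resid**2))

        prev = train_loss(q, g)
        loss_path.append(prev)
        self.converged_ = False
        for _ in range(self.max_iter):
            filled = np.where(train, y01, q @ g)
            qtq = q.T @ q + 1e-9 * np.eye(k)
            g_new = np.clip(np.linalg.solve(qtq, q.T @ filled), 1e-4, 1 - 1e-4)
            ggt = g_new @ g_new.T + 1e-9 * np.eye(k)
            q_new = _project_rows_to_simplex(filled @ g_new.T @ np.linalg.inv(ggt))
            # guard against degenerate all-zero rows from the projection
            bad = q_new.sum(axis=1) <= 0
            if bad.any():
                q_new[bad] = 1.0 / k
            cur = train_loss(q_new, g_new)
            if cur > prev:  # monotone safeguard: revert and stop
                break
            q, g = q_new, g_new
            loss_path.append(cur)
            if prev - cur < self.tol * max(prev, 1e-12):
                self.converged_ = True
                prev = cur
                break
            prev = cur

        self.Q_ = q
        self.G_ = g
        self.train_loss_path_ = np.array(loss_path)
        p_held = (q @ g)[heldout]
        self.cross_entropy_ = (
            _binomial_cross_entropy(x[heldout], p_held) if heldout.any() else np.nan
        )
        self.n_heldout_ = int(heldout.sum())
        return self

    def predict_proba(self, X=None) -> np.ndarray:
        return self.Q_


@dataclass
class AdmixtureResult:
    """Per-K fits plus the cross-entropy-selected best K."""

    per_k: dict = field(default_factory=dict)  # K -> dict(Q, G, cross_entropies, mean_ce)
    best_k: int = 1

    def q_matrix(self, k: int | None = None) -> np.ndarray:
        return self.per_k[k or self.best_k]["Q"]


def admixture_snmf(
    gt_or_dosages,
    k_range=range(1, 6),
    n_rep: int = 10,
    mask_frac: float = 0.05,
    seed: int = 0,
) -> AdmixtureResult:
    """Fit masked-NMF admixture models for each K and select the best K.

    For each K, ``n_rep`` restarts are run with independent masks and
    initialisations; the mean held-out cross-entropy across restarts
    drives K selection and the best (lowest-CE) restart's Q/G are kept.
    """
    x = gt_or_dosages.dosages if hasattr(gt_or_dosages, "dosages") else np.asarray(gt_or_dosages)
    rng = np.random.default_rng(seed)
    result = AdmixtureResult()
    for k in k_range:
        ces, fits = [], []
        for _ in range(n_rep):
            m = SNMF(
                n_clusters=k,
                mask_frac=mask_frac,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(x)
            ces.append(m.cross_entropy_)
            fits.append(m)
        best = fits[int(np.nanargmin(ces))]
        result.per_k[k] = {
            "Q": best.Q_,
            "G": best.G_,
            "cross_entropies": np.array(ces),
            "mean_ce": float(np.nanmean(ces)),
        }
    result.best_k = min(result.per_k, key=lambda k: result.per_k[k]["mean_ce"])
    return result
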