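"""Genotype-environment association by redundancy analysis (RDA).

The constrained ordination regresses every (centred, unit-scaled) SNP
dosage column on the environmental design, extracts the constrained axes
from a singular decomposition of the fitted matrix, and flags SNPs whose
axis loadings fall more than k standard deviations from the mean loading
as selection candidates.  Candidates are then re-screened by the Pearson
correlation of raw dosage with the environment (two-sided t test); only
SNPs with p below alpha are retained.  Under a single constraint the
loading ranking is algebraically the ranking of |r|, so the two screens
agree on order and differ only in thresholding.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import GenotypeTable

log = logging.getLogger(__name__)

__all__ = ["impute_by_cluster", "RDA", "RDAResult", "rda", "detect_outliers", "correlate_candidates"]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def impute_by_cluster(gt: GenotypeTable, clusters=None) -> tuple[np.ndarray, list[str]]:
    """Impute missing genotypes by the rounded within-cluster mean dosage.

    ``clusters`` maps individual id -> cluster label; by default all
    individuals form one cluster (the no-structure case).  Rounding is to
    the nearest integer with ties away from zero.  Clusters with no data
    at a locus fall back to the global locus mean; loci missing everywhere
    are dropped (returned in the second element).
    """
    x = gt.dosages.copy()
    if clusters is None:
        labels = np.zeros(gt.n_individuals, dtype=int)
    else:
        labels = np.array([clusters[i] for i in gt.individuals["id"]])

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        global_mean = np.nanmean(x, axis=0)
    dropped = gt.loci["locus_id"][np.isnan(global_mean)].tolist()
    if dropped:
        log.warning("%d loci missing in all individuals were dropped", len(dropped))

    for lab in pd.unique(labels):
        sel = labels == lab
        block = x[sel]
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(block, axis=0)
        mean = np.where(np.isnan(mean), global_mean, mean)
        fill = np.clip(_round_half_away(mean), 0, 2)
        miss = np.isnan(block)
        block[miss] = np.broadcast_to(fill, block.shape)[miss]
        x[sel] = block

    keep = ~np.isnan(global_mean)
    return x[:, keep], dropped


class RDAResult:
    def __init__(self, loadings, eigenvalues, total_variance, pseudo_f, p_full, p_axis, locus_ids, n_perm, seed):
        self.loadings = loadings  # loci x constrained axes
        self.eigenvalues = eigenvalues
        self.total_variance = total_variance
        self.pseudo_f = pseudo_f
        self.p_full = p_full
        self.p_axis = p_axis
        self.locus_ids = locus_ids
        self.n_perm = n_perm
        self.seed = seed

    @property
    def constrained_variance(self) -> float:
        return float(np.sum(self.eigenvalues))


class RDA(BaseEstimator):
    """Redundancy analysis of a genotype matrix on environmental predictors.

    fit(X, env): X is individuals x loci (complete, no nan); env is a
    per-individual vector or matrix of constraints.  Zero-variance SNP
    columns are dropped with a warning.  Fitted attributes: ``loadings_``
    (SNP scores per constrained axis), ``eigenvalues_``,
    ``total_variance_``, ``pseudo_f_``, ``p_full_``, ``p_axis_``.
    """

    def __init__(self, n_perm: int = 999, random_state: int | None = None, scale: bool = True):
        self.n_perm = n_perm
        self.random_state = random_state
        self.scale = scale

    @staticmethod
    def _constraint_basis(env: np.ndarray) -> np.ndarray:
        """Orthonormal basis of the centred constraint design (collinear
        constraints collapse onto the same subspace)."""
        x = env - env.mean(axis=0)
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
        if rank == 0:
            raise ValueError("constraining variable is constant")
        return u[:, :rank]

    @staticmethod
    def _stats(basis: np.ndarray, y: np.ndarray, total_ss: float):
        n, q = basis.shape
        b = basis.T @ y  # q x loci projection; fitted SS = ||b||^2
        s2 = np.linalg.svd(b, compute_uv=False) ** 2
        eig = s2 / (n - 1)
        ss_fit = float(s2.sum())
        ss_res = total_ss - ss_fit
        f = (ss_fit / q) / (ss_res / (n - q - 1))
        return eig, f

    def fit(self, X: np.ndarray, env) -> "RDA":
        y = np.asarray(X, dtype=float)
        if np.isnan(y).any():
            raise ValueError("genotype matrix must be complete (impute first)")
        env = np.asarray(env, dtype=float)
        if env.ndim == 1:
            env = env[:, None]
        if np.allclose(env.std(axis=0), 0):
            raise ValueError("constraining variable is constant")
        n = y.shape[0]
        sd = y.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            log.warning("dropped %d zero-variance SNP columns", int((~keep).sum()))
        self.kept_columns_ = keep
        y = y[:, keep] - y[:, keep].mean(axis=0)
        if self.scale:
            y = y / sd[keep]

        basis = self._constraint_basis(env)
        q = basis.shape[1]
        total_ss = float((y**2).sum())
        b = basis.T @ y
        u_b, s_b, vt_b = np.linalg.svd(b, full_matrices=False)
        eig = s_b**2 / (n - 1)
        ss_fit = float((s_b**2).sum())
        f = (ss_fit / q) / ((total_ss - ss_fit) / (n - q - 1))
        self.eigenvalues_ = eig
        self.pseudo_f_ = f
        self.total_variance_ = total_ss / (n - 1)
        # species-style loadings: right singular vectors scaled by axis magnitude
        self.loadings_ = (vt_b.T * s_b) / np.sqrt(n - 1)

        rng = np.random.default_rng(self.random_state)
        count_f = 0
        count_axis = np.zeros(q)
        for _ in range(self.n_perm):
            perm = rng.permutation(n)
            eig_p, f_p = self._stats(basis[perm], y, total_ss)
            count_f += f_p >= f
            count_axis += eig_p[:q] >= eig[:q]
        self.p_full_ = (1 + count_f) / (1 + self.n_perm)
        self.p_axis_ = (1 + count_axis) / (1 + self.n_perm)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project (centred/scaled) genotypes onto the constrained axes."""
        y = np.asarray(X, dtype=float)[:, self.kept_columns_]
        y = y - y.mean(axis=0)
        denom = np.sqrt(np.sum(self.loadings_**2, axis=0))
        return y @ self.loadings_ / denom


def rda(
    genotypes: np.ndarray,
    env,
    n_perm: int = 999,
    seed: int | None = None,
    locus_ids=None,
) -> RDAResult:
    """Functional wrapper over the RDA estimator."""
    est = RDA(n_perm=n_perm, random_state=seed).fit(genotypes, env)
    if locus_ids is not None:
        locus_ids = np.asarray(locus_ids)[est.kept_columns_]
    return RDAResult(
        loadings=est.loadings_,
        eigenvalues=est.eigenvalues_,
        total_variance=est.total_variance_,
        pseudo_f=est.pseudo_f_,
        p_full=est.p_full_,
        p_axis=est.p_axis_,
        locus_ids=locus_ids,
        n_perm=n_perm,
        seed=seed,
    )


def detect_outliers(res: RDAResult, k: float = 3.0) -> np.ndarray:
    """Indices of loci whose loading on any constrained axis deviates from
    the mean loading by more than k standard deviations (n-1 denominator)."""
    loadings = np.atleast_2d(res.loadings)
    if loadings.shape[0] < 10:
        raise ValueError("need at least 10 loadings")
    hits = np.zeros(loadings.shape[0], dtype=bool)
    for ax in range(loadings.shape[1]):
        col = loadings[:, ax]
        sd = col.std(ddof=1)
        if sd == 0:
            continue
        hits |= np.abs(col - col.mean()) > k * sd
    return np.flatnonzero(hits)


def correlate_candidates(
    dosages: np.ndarray,
    env: np.ndarray,
    candidates: np.ndarray,
    alpha: float = 0.05,
    locus_ids=None,
    loadings: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pearson dosage-environment correlation screen for candidate loci.

    Correlations use pairwise-complete observations; p is the two-sided
    t-based p-value; rows with p < alpha carry retained=True.  Candidates
    whose dosage is constant among complete observations are dropped with
    a warning.
    """
    env = np.asarray(env, dtype=float)
    rows = []
    for c in np.atleast_1d(candidates):
        x = dosages[:, c]
        ok = ~np.isnan(x)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(env[ok]) == 0:
            log.warning("candidate column %d constant or too sparse; dropped", c)
            continue
        r, p = stats.pearsonr(x[ok], env[ok])
        rows.append(
            {
                "locus_id": locus_ids[c] if locus_ids is not None else c,
                "loading": loadings[c] if loadings is not None else np.nan,
                "r": float(r),
                "abs_r": float(abs(r)),
                "p": float(p),
                "retained": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows, columns=["locus_id", "loading", "r", "abs_r", "p", "retained"])
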