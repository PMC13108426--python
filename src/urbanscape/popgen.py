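"""Differentiation, diversity and principal component analysis.

FST follows the Weir-Cockerham (1984) variance-components estimator theta,
combined across loci as a ratio of summed components (the "weighted"
multi-locus estimator).  Per-individual heterozygosity and the inbreeding
coefficient F follow the method-of-moments used by PLINK's ``--het``:
expected homozygosity from sample allele frequencies with the small-sample
correction 2*p*q*n/(n-1) on allele count n.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeTable, SymmetricMatrix

log = logging.getLogger(__name__)


def _wc_components(
    dosages_a: np.ndarray, dosages_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components (a, b, c) for two groups.

    Arrays are individuals x loci with nan for missing.  Loci where either
    group has no data are returned as nan components (skipped by callers).
    """
    groups = (dosages_a, dosages_b)
    r = 2
    n_i = np.stack([np.sum(~np.isnan(g), axis=0) for g in groups]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.stack([np.nanmean(g, axis=0) / 2.0 for g in groups])
        # heterozygote proportion over non-missing genotypes only
        h_i = np.stack(
            [
                np.sum(g == 1.0, axis=0) / np.maximum(np.sum(~np.isnan(g), axis=0), 1)
                for g in groups
            ]
        )
        n_bar = n_i.mean(axis=0)
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0

    bad = (n_i < 1).any(axis=0) | (n_bar <= 1)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return a, b, c


def wc_fst_pair(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Multi-locus Weir-Cockerham theta between two groups (ratio of sums).

    Negative estimates are reported as computed, not truncated to zero.
    """
    a, b, c = _wc_components(dosages_a, dosages_b)
    ok = ~np.isnan(a)
    denom = np.nansum(a[ok] + b[ok] + c[ok])
    if denom == 0:
        return 0.0
    return float(np.nansum(a[ok]) / denom)


def pairwise_fst(gt: GenotypeTable, grouping=None) -> SymmetricMatrix:
    """Pairwise multi-locus Weir-Cockerham FST between colonies.

    ``grouping`` maps individual id -> group label; defaults to the table's
    colony assignment.  Requires >= 2 groups with >= 2 individuals each.
    """
    if grouping is None:
        labels_per_ind = gt.colony_ids
    else:
        labels_per_ind = np.array([grouping[i] for i in gt.individuals["id"]])
    groups = list(pd.unique(labels_per_ind))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    blocks = {g: gt.dosages[labels_per_ind == g] for g in groups}
    for g, blk in blocks.items():
        if blk.shape[0] < 2:
            raise ValueError(f"group {g!r} has fewer than 2 individuals")
    n = len(groups)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            theta = wc_fst_pair(blocks[groups[i]], blocks[groups[j]])
            values[i, j] = values[j, i] = theta
    return SymmetricMatrix(groups, values, kind="fst")


def linearise_fst(m: SymmetricMatrix) -> SymmetricMatrix:
    """Elementwise FST / (1 - FST), the transform regressed on distance."""
    if np.any(m.values >= 1.0):
        raise ValueError("FST value >= 1 cannot be linearised")
    return SymmetricMatrix(m.labels, m.values / (1.0 - m.values), kind="linearised_fst")


def het_inbreeding(gt: GenotypeTable) -> pd.DataFrame:
    """Observed/expected homozygosity and inbreeding F per individual.

    Expected homozygous count for an individual sums, over its non-missing
    loci, 1 - 2*p*q*n/(n-1) with p the sample alternate-allele frequency
    and n the non-missing allele count at the locus.  F = (O - E)/(L - E).
    Individuals with zero non-missing loci are excluded with a warning.
    """
    dos = gt.dosages
    n_gen = np.sum(~np.isnan(dos), axis=0).astype(float)
    n_all = 2.0 * n_gen
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nanmean(dos, axis=0) / 2.0
        exp_het_locus = 2.0 * p * (1.0 - p) * n_all / (n_all - 1.0)
    exp_het_locus = np.where(n_all > 1, exp_het_locus, np.nan)

    rows = []
    for i in range(gt.n_individuals):
        obs = dos[i]
        ok = ~np.isnan(obs) & ~np.isnan(exp_het_locus)
        L = int(ok.sum())
        if L == 0:
            log.warning("individual %s has no usable genotypes; excluded", gt.individuals["id"].iloc[i])
            continue
        o_hom = int(np.sum(obs[ok] != 1.0))
        e_hom = float(np.sum(1.0 - exp_het_locus[ok]))
        denom = L - e_hom
        f = (o_hom - e_hom) / denom if denom != 0 else np.nan
        rows.append(
            {
                "id": gt.individuals["id"].iloc[i],
                "colony_id": gt.individuals["colony_id"].iloc[i],
                "n_loci": L,
                "obs_hom": o_hom,
                "exp_hom": e_hom,
                "Ho": (L - o_hom) / L,
                "He": (L - e_hom) / L,
                "F": f,
            }
        )
    return pd.DataFrame(rows)


def het_group_summary(het: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Mean +/- SD of Ho/He ratio and F per group (urban/rural)."""
    het = het.copy()
    het["group"] = het["colony_id"].map(groups)
    het["ho_he"] = het["Ho"] / het["He"]
    return het.groupby("group").agg(
        ho_he_mean=("ho_he", "mean"),
        ho_he_sd=("ho_he", "std"),
        f_mean=("F", "mean"),
        f_sd=("F", "std"),
    )


# ---------------------------------------------------------------------------
# PCA with Tracy-Widom significance

# Shifted-gamma approximation to the Tracy-Widom beta=1 distribution
# (Chiani 2014): TW1 ~ Gamma(k, theta) - alpha.
_TW1_K = 46.44604884387805
_TW1_THETA = 0.18605402228279955
_TW1_ALPHA = 9.848012835954916


def tracy_widom_sf(x: np.ndarray) -> np.ndarray:
    """Upper-tail probability of the Tracy-Widom (beta=1) law."""
    return stats.gamma.sf(np.asarray(x, dtype=float) + _TW1_ALPHA, _TW1_K, scale=_TW1_THETA)


class PCAResult:
    def __init__(self, scores, eigenvalues, variance_fractions, tw_stats, tw_p):
        self.scores = scores
        self.eigenvalues = eigenvalues
        self.variance_fractions = variance_fractions
        self.tw_stats = tw_stats
        self.tw_p = tw_p


def _tw_pvalues(eigenvalues: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Moment-matched Tracy-Widom statistics for leading eigenvalues.

    For axis k the trailing eigenvalues lambda_k..lambda_m estimate an
    effective marker count; the normalised top eigenvalue is referred to
    the TW(beta=1) law.
    """
    lam_all = np.asarray(eigenvalues, dtype=float)
    lam = lam_all[lam_all > 1e-12]
    m_tot = len(lam)
    tw = np.full(len(lam_all), np.nan)
    p = np.full(len(lam_all), np.nan)
    for k in range(m_tot - 1):
        tail = lam[k:]
        m = len(tail)
        s1 = tail.sum()
        s2 = (tail**2).sum()
        n_eff = ((m + 2) * s1**2) / (m * s2 - s1**2) if m * s2 > s1**2 else np.nan
        if not np.isfinite(n_eff) or n_eff <= 1:
            continue
        ell = m * tail[0] / s1
        sq_n = np.sqrt(n_eff - 1)
        sq_m = np.sqrt(m)
        mu = (sq_n + sq_m) ** 2 / n_eff
        sigma = (sq_n + sq_m) / n_eff * (1.0 / sq_n + 1.0 / sq_m) ** (1.0 / 3.0)
        tw[k] = (ell - mu) / sigma
        p[k] = tracy_widom_sf(tw[k])
    return tw, p


def pca(gt: GenotypeTable, scaling: str = "unit", n_axes: int | None = None) -> PCAResult:
    """PCA of the genotype matrix.

    Missing values are imputed by the locus mean; loci are centred and
    scaled per ``scaling``: "unit" (sample SD), "patterson"
    (sqrt(p(1-p))), or "none".  Zero-variance loci are dropped.
    """
    if gt.n_individuals < 3:
        raise ValueError("need at least 3 individuals")
    x = gt.dosages.copy()
    mu = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(mu, idx[1])
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    x = x[:, keep] - mu[keep]
    if scaling == "unit":
        x /= sd[keep]
    elif scaling == "patterson":
        p = mu[keep] / 2.0
        x /= np.sqrt(p * (1 - p))
    elif scaling != "none":
        raise ValueError(f"unknown scaling {scaling!r}")

    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / (gt.n_individuals - 1)
    frac = eig / eig.sum()
    tw, tw_p = _tw_pvalues(eig)
    scores = u * s
    if n_axes is not None:
        scores = scores[:, :n_axes]
    return PCAResult(scores, eig, frac, tw, tw_p)
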