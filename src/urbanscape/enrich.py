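"""Hypergeometric GO-term enrichment with Benjamini-Hochberg control.

For each term with at least ``min_genes`` candidate genes, the upper-tail
hypergeometric probability P(X >= k) is computed for k candidate genes
carrying the term out of n annotated candidates, against K of N background
genes; fold enrichment is (k/n)/(K/N).  The minimum-gene filter is applied
before multiple-testing correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def enrich(
    candidate_genes: set,
    ontology: pd.DataFrame,
    min_genes: int = 3,
    alpha: float = 0.05,
    background: set | None = None,
) -> pd.DataFrame:
    """GO enrichment of ``candidate_genes`` against the ontology table.

    ``ontology`` needs columns gene, term_id, term_name, namespace.  The
    background defaults to all genes in the table.  Returns one row per
    tested term: term_id, term_name, namespace, k, n, K, N, fold, p, q,
    significant (q < alpha), sorted by q then p.
    """
    bg = background if background is not None else set(ontology["gene"])
    cands = set(candidate_genes) & bg
    if not cands:
        raise ValueError("no candidate gene intersects the background")
    n_bg = len(bg)
    n_cand = len(cands)

    onto = ontology[ontology["gene"].isin(bg)]
    rows = []
    for (term_id, term_name, ns), sub in onto.groupby(["term_id", "term_name", "namespace"]):
        term_genes = set(sub["gene"])
        k = len(term_genes & cands)
        if k < min_genes:
            continue
        big_k = len(term_genes)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_cand))
        fold = (k / n_cand) / (big_k / n_bg)
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "namespace": ns,
                "k": k,
                "n": n_cand,
                "K": big_k,
                "N": n_bg,
                "fold": fold,
                "p": p,
            }
        )
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "namespace", "k", "n", "K", "N", "fold", "p"])
    if len(df):
        reject, q, _, _ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
        df["q"] = q
        df["significant"] = reject
        df = df.sort_values(["q", "p"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
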