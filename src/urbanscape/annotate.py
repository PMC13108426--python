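"""Classify candidate SNPs against gene models from a GTF.

A SNP is "exon" if its position falls inside any exon of a gene, "intron"
if it falls within a gene span but outside all exons, and "intergenic"
otherwise.  GTF intervals are 1-based and closed; both boundary positions
belong to the feature.  Genes with unrecognised "LOC"-prefixed symbols
are excluded before classification, and overlapping genes are resolved by
the smallest enclosing gene span.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path) -> pd.DataFrame:
    """Light GTF reader: returns chrom, feature, start, end, gene_id, gene_name."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GTF line {ln}")
            attrs = dict(_ATTR_RE.findall(parts[8]))
            rows.append(
                {
                    "chrom": parts[0],
                    "feature": parts[2],
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                    "gene_id": attrs.get("gene_id", ""),
                    "gene_name": attrs.get("gene_name", attrs.get("gene_id", "")),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SNPAnnotation:
    locus_id: str
    snp_class: str  # exon | intron | intergenic
    gene: str | None
    distance_bp: int | None  # to nearest gene when intergenic


def classify_snps(loci: pd.DataFrame, gtf: pd.DataFrame, flank_bp: int = 0) -> pd.DataFrame:
    """Annotate loci (chrom, pos, locus_id) against gene models.

    ``flank_bp`` extends gene spans on both sides when deciding gene
    membership (0 = strict span).  Returns a DataFrame with locus_id,
    snp_class, gene, distance_bp.
    """
    genes = gtf[gtf["feature"] == "gene"].copy()
    genes = genes[~genes["gene_name"].str.startswith("LOC")]
    exons = gtf[gtf["feature"] == "exon"].copy()
    exons = exons[~exons["gene_name"].str.startswith("LOC")]

    rows = []
    gtf_chroms = set(genes["chrom"])
    for _, locus in loci.iterrows():
        chrom, pos, lid = locus["chrom"], int(locus["pos"]), locus["locus_id"]
        if chrom not in gtf_chroms:
            log.warning("locus %s on chromosome %s absent from GTF", lid, chrom)
            rows.append(SNPAnnotation(lid, "intergenic", None, None).__dict__)
            continue
        g = genes[genes["chrom"] == chrom]
        inside = g[(g["start"] - flank_bp <= pos) & (pos <= g["end"] + flank_bp)]
        if len(inside) == 0:
            dist = int(np.min(np.minimum(np.abs(g["start"] - pos), np.abs(g["end"] - pos))))
            rows.append(SNPAnnotation(lid, "intergenic", None, dist).__dict__)
            continue
        # overlapping genes: smallest enclosing span wins
        spans = inside["end"] - inside["start"]
        gene = inside.iloc[int(np.argmin(spans.to_numpy()))]
        ex = exons[
            (exons["gene_name"] == gene["gene_name"])
            & (exons["start"] <= pos)
            & (pos <= exons["end"])
        ]
        cls = "exon" if len(ex) else "intron"
        rows.append(SNPAnnotation(lid, cls, gene["gene_name"], None).__dict__)
    return pd.DataFrame(rows, columns=["locus_id", "snp_class", "gene", "distance_bp"])
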