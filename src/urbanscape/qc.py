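"""SNP quality control: VCF parsing, site/genotype filters, LD pruning.

Filters mirror a standard reduced-representation workflow: genotypes below
a depth floor are masked, loci are dropped for excess missingness, for
excess mean depth (a proxy for collapsed repeats) and for low minor allele
frequency, and the remaining panel is thinned by sliding-window LD pruning
on the squared dosage correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeTable

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Per-stage locus/genotype accounting; input = output + total removed."""

    n_input: int = 0
    n_genotypes_masked_depth: int = 0
    n_removed_missingness: int = 0
    n_removed_mean_depth: int = 0
    n_removed_maf: int = 0
    n_removed_biallelic: int = 0
    n_removed_ld: int = 0
    n_output: int = 0

    @property
    def n_removed_total(self) -> int:
        return (
            self.n_removed_biallelic
            + self.n_removed_missingness
            + self.n_removed_mean_depth
            + self.n_removed_maf
            + self.n_removed_ld
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, getattr(self, k)) for k in self.__dataclass_fields__],
            columns=["stage", "count"],
        )


def read_vcf(path) -> tuple[GenotypeTable, FilterReport]:
    """Parse a VCF into a GenotypeTable.

    Multi-allelic records are dropped (counted in the report); half-calls
    are treated as missing.  Requires the GT FORMAT field; DP is used when
    present, otherwise depth is nan.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    dosages, depths, loci = [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = var.gt_types.astype(float)  # 0/1/2, 3 = unknown with gts012
        gt[gt == 3] = np.nan
        try:
            dp = var.format("DP")
            dp = dp.astype(float).reshape(-1)
            dp[dp < 0] = np.nan
        except (KeyError, TypeError, ValueError):
            dp = np.full(len(samples), np.nan)
        dosages.append(gt)
        depths.append(dp)
        loci.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0],
                "locus_id": var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}",
            }
        )
    if n_multi:
        log.warning("dropped %d multi-allelic records", n_multi)
    loci_df = pd.DataFrame(loci)
    order = np.lexsort((loci_df["pos"].to_numpy(), loci_df["chrom"].to_numpy()))
    loci_df = loci_df.iloc[order].reset_index(drop=True)
    dos = np.array(dosages).T[:, order]
    dep = np.array(depths).T[:, order]
    individuals = pd.DataFrame({"id": samples, "colony_id": [s.rsplit("_ind", 1)[0] for s in samples]})
    table = GenotypeTable(dosages=dos, depths=dep, loci=loci_df, individuals=individuals)
    report = FilterReport(n_input=len(loci_df) + n_multi, n_removed_biallelic=n_multi, n_output=len(loci_df))
    return table, report


def allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Alternate-allele frequency per locus over non-missing genotypes."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(dosages, axis=0) / 2.0


def apply_filters(
    gt: GenotypeTable,
    maf_min: float = 0.03,
    depth_min: int = 5,
    miss_max: float = 0.20,
    mean_depth_max: float = 50.0,
) -> tuple[GenotypeTable, FilterReport]:
    """Apply genotype and site filters in a fixed order.

    1. genotypes with depth < depth_min are set missing;
    2. loci with > miss_max missing genotypes are removed;
    3. loci with mean depth (over non-missing genotypes) > mean_depth_max
       are removed;
    4. loci with minor allele frequency < maf_min (computed from the
       remaining genotypes) are removed — MAF exactly at the threshold is
       retained.
    """
    report = FilterReport(n_input=gt.n_loci)
    gt = gt.copy()

    low = gt.depths < depth_min  # nan depths compare False -> untouched
    newly_masked = low & ~np.isnan(gt.dosages)
    report.n_genotypes_masked_depth = int(newly_masked.sum())
    gt.dosages[low] = np.nan

    keep = np.ones(gt.n_loci, dtype=bool)
    miss_frac = np.isnan(gt.dosages).mean(axis=0)
    fail = miss_frac > miss_max
    report.n_removed_missingness = int(fail.sum())
    keep &= ~fail

    with np.errstate(invalid="ignore"):
        dep = np.where(np.isnan(gt.dosages), np.nan, gt.depths)
        mean_depth = np.nanmean(dep, axis=0)
    fail = keep & (mean_depth > mean_depth_max)
    report.n_removed_mean_depth = int(fail.sum())
    keep &= ~fail

    freq = allele_frequencies(gt.dosages)
    maf = np.minimum(freq, 1.0 - freq)
    with np.errstate(invalid="ignore"):
        fail = keep & ((maf < maf_min) | np.isnan(maf))
    report.n_removed_maf = int(fail.sum())
    keep &= ~fail

    out = gt.subset_loci(keep)
    report.n_output = out.n_loci
    if out.n_loci == 0:
        log.warning("all loci removed by filters")
    return out, report


def _pairwise_r2(block: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, pairwise-complete.

    Monomorphic columns (zero variance among complete observations of a
    pair) yield r^2 = 0.
    """
    n = block.shape[1]
    r2 = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ok = ~np.isnan(block[:, a]) & ~np.isnan(block[:, b])
            if ok.sum() < 3:
                continue
            x, y = block[ok, a], block[ok, b]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            r2[a, b] = r2[b, a] = r * r
    return r2


def ld_prune(
    gt: GenotypeTable, window: int = 25, step: int = 10, r2_max: float = 0.9
) -> tuple[GenotypeTable, list[str]]:
    """Sliding-window LD pruning per chromosome.

    Within each window of ``window`` SNPs (advancing by ``step``), for every
    pair with squared dosage correlation > ``r2_max`` the later-positioned
    SNP is removed.  Returns the pruned table and the removed locus ids.
    """
    if not (window > step > 0):
        raise ValueError("require window > step > 0")
    removed: set[int] = set()
    chroms = gt.loci["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while True:
            win = idx[start : start + window]
            if len(win) >= 2:
                alive = [i for i in win if i not in removed]
                block = gt.dosages[:, alive]
                r2 = _pairwise_r2(block)
                for a in range(len(alive)):
                    if alive[a] in removed:
                        continue
                    for b in range(a + 1, len(alive)):
                        if alive[b] in removed:
                            continue
                        if r2[a, b] > r2_max:
                            removed.add(alive[b])  # later-positioned SNP
            if start + window >= len(idx):
                break
            start += step
    keep = np.ones(gt.n_loci, dtype=bool)
    keep[list(removed)] = False
    removed_ids = list(gt.loci["locus_id"].iloc[sorted(removed)])
    return gt.subset_loci(keep), removed_ids
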