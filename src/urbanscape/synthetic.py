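"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a near-panmictic colony network sampled along an
urbanisation gradient: ~10 colonies of ~19 individuals, ~20,000 bi-allelic
SNPs, very low differentiation (mean pairwise FST around 0.002), a weak
positive distance-FST slope (isolation by distance), and a small planted
set of loci whose allele frequencies track an environmental covariate
(percent urban cover).

Model
-----
Neutral allele frequencies follow a spatially correlated Balding-Nichols
F-model: each locus draws an ancestral frequency p0 ~ U(0.05, 0.95); each
colony's frequency is marginally Beta(p0(1-F)/F, (1-p0)(1-F)/F), and
colonies are coupled through a Gaussian copula whose correlation declines
linearly with great-circle distance.  For a colony pair at distance d the
expected pairwise FST is then approximately F * d / d_max, i.e. pairwise
differentiation grows linearly with distance, and F is calibrated so the
mean over pairs equals ``target_fst``.  Adaptive loci add an effect
beta * z(env) on the logit of the colony frequency, where z(env) is the
standardised environmental covariate.  Genotypes are Binomial(2, p_c);
depths are negative-binomial around a mean of 15; a configurable fraction
of genotypes is set missing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .containers import GenotypeTable
from .spatial import geodesic_km, geo_distance_matrix

__all__ = [
    "TruthSet",
    "random_truth",
    "simulate_colonies",
    "simulate_genotypes",
    "write_fixture_set",
    "LAND_COVER_CODES",
]

# study-region centroids: urban metropolitan core vs. rural karst area ~55 km apart
_URBAN_CENTROID = (32.10, 34.80)
_RURAL_CENTROID = (31.64, 34.90)

LAND_COVER_CODES = {
    "urban": 1,
    "orchard": 2,
    "forest": 3,
    "grassland": 4,
    "arable": 5,
    "bare": 6,
}


@dataclass
class TruthSet:
    """Ground-truth record for parameter-recovery tests.

    effect_sizes maps locus_id -> slope beta applied to the logit of the
    colony allele frequency per SD of the environmental covariate.
    """

    effect_sizes: dict = field(default_factory=dict)
    target_fst: float = 0.002
    seed: int = 0

    @property
    def adaptive_locus_ids(self) -> set:
        return set(self.effect_sizes)

    def __post_init__(self) -> None:
        if not (0 <= self.target_fst < 1):
            raise ValueError("target_fst must be in [0, 1)")


def _locus_ids(n_loci: int) -> list[str]:
    return [f"L{i:06d}" for i in range(n_loci)]


def random_truth(
    n_loci: int,
    n_adaptive: int = 0,
    beta: float = 2.0,
    target_fst: float = 0.002,
    seed: int = 0,
) -> TruthSet:
    """TruthSet with ``n_adaptive`` randomly placed adaptive loci of slope beta."""
    rng = np.random.default_rng(seed)
    ids = _locus_ids(n_loci)
    chosen = rng.choice(n_loci, size=n_adaptive, replace=False) if n_adaptive else []
    return TruthSet(
        effect_sizes={ids[i]: beta for i in sorted(chosen)},
        target_fst=target_fst,
        seed=seed,
    )


def simulate_colonies(n_urban: int = 5, n_rural: int = 5, seed: int = 0) -> pd.DataFrame:
    """Colony table with urban and rural clusters ~50 km apart.

    Urban colonies scatter within ~15 km of the urban centroid with high
    urban cover (60-95%); rural colonies within ~20 km of the rural
    centroid with low cover (0-15%).
    """
    if n_urban < 1 or n_rural < 1:
        raise ValueError("colony counts must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    km_per_deg_lat = 111.2
    for group, n, (clat, clon), radius_km, cover_rng in (
        ("urban", n_urban, _URBAN_CENTROID, 15.0, (60.0, 95.0)),
        ("rural", n_rural, _RURAL_CENTROID, 20.0, (0.0, 15.0)),
    ):
        km_per_deg_lon = km_per_deg_lat * np.cos(np.radians(clat))
        for i in range(n):
            r = radius_km * np.sqrt(rng.uniform(0.05, 1.0)) / 2.0
            theta = rng.uniform(0, 2 * np.pi)
            rows.append(
                {
                    "colony_id": f"{group}_{i + 1}",
                    "lat": clat + r * np.sin(theta) / km_per_deg_lat,
                    "lon": clon + r * np.cos(theta) / km_per_deg_lon,
                    "group": group,
                    "urban_cover_pct": rng.uniform(*cover_rng),
                }
            )
    return pd.DataFrame(rows)


def _nearest_psd_correlation(r: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    w, v = np.linalg.eigh(r)
    if w.min() >= 0:
        return r
    r2 = (v * np.clip(w, 0, None)) @ v.T
    d = np.sqrt(np.diag(r2))
    return r2 / np.outer(d, d)


def simulate_genotypes(
    colonies: pd.DataFrame,
    n_per_colony: int = 19,
    n_loci: int = 20000,
    truth: TruthSet | None = None,
    missing_rate: float = 0.05,
    depth_mean: float = 15.0,
    depth_shape: float = 8.0,
) -> tuple[GenotypeTable, TruthSet]:
    """Simulate a GenotypeTable under the spatial F-model described above."""
    if truth is None:
        truth = TruthSet()
    if not truth.adaptive_locus_ids <= set(_locus_ids(n_loci)):
        raise ValueError("adaptive locus ids are not a subset of simulated loci")
    rng = np.random.default_rng(truth.seed)
    n_col = len(colonies)
    ids = _locus_ids(n_loci)

    p0 = rng.uniform(0.05, 0.95, size=n_loci)

    if truth.target_fst > 0 and n_col > 1:
        geo = geo_distance_matrix(colonies).values
        d_max = geo.max()
        iu = np.triu_indices(n_col, k=1)
        mean_d = geo[iu].mean()
        # marginal F so that mean pairwise FST ~ F * mean(d)/d_max = target
        f_marg = min(truth.target_fst * d_max / mean_d, 0.5)
        corr = _nearest_psd_correlation(1.0 - geo / d_max)
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(n_col))
        z = chol @ rng.standard_normal((n_col, n_loci))
        u = stats.norm.cdf(z)
        a = p0 * (1.0 - f_marg) / f_marg
        b = (1.0 - p0) * (1.0 - f_marg) / f_marg
        p_c = stats.beta.ppf(u, a[None, :], b[None, :])
    else:
        p_c = np.tile(p0, (n_col, 1))

    n_clipped = 0
    if truth.effect_sizes:
        env = colonies["urban_cover_pct"].to_numpy(dtype=float)
        zenv = (env - env.mean()) / env.std(ddof=0)
        idx = {lid: k for k, lid in enumerate(ids)}
        for lid, beta in truth.effect_sizes.items():
            k = idx[lid]
            shifted = expit(logit(np.clip(p_c[:, k], 1e-9, 1 - 1e-9)) + beta * zenv)
            n_clipped += int(((shifted < 0.001) | (shifted > 0.999)).sum())
            p_c[:, k] = np.clip(shifted, 0.001, 0.999)

    p_c = np.clip(p_c, 0.0, 1.0)

    n_ind = n_per_colony * n_col
    dosages = np.empty((n_ind, n_loci))
    individuals = []
    for c in range(n_col):
        sl = slice(c * n_per_colony, (c + 1) * n_per_colony)
        dosages[sl] = rng.binomial(2, p_c[c][None, :], size=(n_per_colony, n_loci))
        cid = colonies["colony_id"].iloc[c]
        individuals += [
            {"id": f"{cid}_ind{i + 1}", "colony_id": cid} for i in range(n_per_colony)
        ]

    # negative-binomial depths around depth_mean; variance = m + m^2/shape
    p_nb = depth_shape / (depth_shape + depth_mean)
    depths = rng.negative_binomial(depth_shape, p_nb, size=(n_ind, n_loci)).astype(float)
    if missing_rate > 0:
        miss = rng.random((n_ind, n_loci)) < missing_rate
        dosages[miss] = np.nan
        depths[miss] = 0.0

    # 10 synthetic chromosomes, positions increasing within each
    n_chrom = min(10, n_loci)
    chroms = np.repeat(np.arange(n_chrom), int(np.ceil(n_loci / n_chrom)))[:n_loci]
    pos = np.concatenate(
        [
            np.sort(rng.choice(np.arange(1, 10_000_000), size=(chroms == c).sum(), replace=False))
            for c in range(n_chrom)
        ]
    )
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=n_loci)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    loci = pd.DataFrame(
        {
            "chrom": [f"chr{c + 1}" for c in chroms],
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "locus_id": ids,
        }
    )
    gt = GenotypeTable(dosages=dosages, depths=depths, loci=loci, individuals=pd.DataFrame(individuals))
    if n_clipped:
        import logging

        logging.getLogger(__name__).info(
            "clipped %d adaptive colony frequencies to [0.001, 0.999]", n_clipped
        )
    return gt, truth


# ---------------------------------------------------------------------------
# fixture set on disk


def write_vcf(gt: GenotypeTable, path: Path) -> None:
    """Write a minimal VCF v4.2 with GT and DP FORMAT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in pd.unique(gt.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(gt.individuals["id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        dos = gt.dosages
        dep = gt.depths
        for j, locus in gt.loci.iterrows():
            fields = []
            for i in range(gt.n_individuals):
                g = "./." if np.isnan(dos[i, j]) else gt_codes[dos[i, j]]
                d = "." if np.isnan(dep[i, j]) else str(int(dep[i, j]))
                fields.append(f"{g}:{d}")
            fh.write(
                f"{locus.chrom}\t{locus.pos}\t{locus.locus_id}\t{locus.ref}\t{locus.alt}"
                f"\t.\tPASS\t.\tGT:DP\t" + "\t".join(fields) + "\n"
            )


def write_ascii_grid(
    path: Path, grid: np.ndarray, xll: float, yll: float, cellsize: float, nodata: float = -9999
) -> None:
    """ESRI ASCII grid writer (row 0 of ``grid`` = northernmost row)."""
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xll}\n")
        fh.write(f"yllcorner {yll}\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {nodata}\n")
        out = np.where(np.isnan(grid), nodata, grid)
        for row in out:
            fh.write(" ".join(f"{v:g}" for v in row) + "\n")


def _landscape_grids(colonies: pd.DataFrame, seed: int, shape=(36, 30)):
    """Light, tree-cover, land-cover and orchard-mask grids covering the colonies."""
    rng = np.random.default_rng(seed)
    nrows, ncols = shape
    pad = 0.08
    xll = colonies["lon"].min() - pad
    yll = colonies["lat"].min() - pad
    cellsize = max(
        (colonies["lon"].max() + pad - xll) / ncols,
        (colonies["lat"].max() + pad - yll) / nrows,
    )
    # cell-centre coordinates; row 0 = north
    xs = xll + (np.arange(ncols) + 0.5) * cellsize
    ys = yll + (nrows - np.arange(nrows) - 0.5) * cellsize
    lon, lat = np.meshgrid(xs, ys)

    urban = colonies[colonies["group"] == "urban"]
    d_urban = np.full(shape, np.inf)
    for _, c in urban.iterrows():
        d = np.sqrt((lat - c.lat) ** 2 + (lon - c.lon) ** 2) * 111.0
        d_urban = np.minimum(d_urban, d)

    light = np.clip(60.0 * np.exp(-d_urban / 8.0) + rng.uniform(0, 3, shape), 0, 63)
    tree = np.clip(
        80.0 * np.exp(-np.maximum(d_urban - 10, 0) / 25.0) * rng.uniform(0.3, 1.0, shape),
        0,
        100,
    )

    land = np.full(shape, LAND_COVER_CODES["grassland"], dtype=float)
    land[d_urban < 6] = LAND_COVER_CODES["urban"]
    ring = (d_urban >= 6) & (d_urban < 14)
    codes = rng.choice(
        [LAND_COVER_CODES[k] for k in ("orchard", "forest", "arable")], size=shape
    )
    land[ring] = codes[ring]
    far = d_urban >= 14
    codes = rng.choice(
        [LAND_COVER_CODES[k] for k in ("grassland", "arable", "bare", "orchard", "forest")],
        size=shape,
        p=[0.35, 0.25, 0.2, 0.1, 0.1],
    )
    land[far] = codes[far]
    # guarantee all categories occur
    flat = land.ravel()
    for k, code in enumerate(LAND_COVER_CODES.values()):
        if code not in flat:
            flat[rng.integers(len(flat))] = code
    orchard = (land == LAND_COVER_CODES["orchard"]).astype(float)
    geo = {"xll": float(xll), "yll": float(yll), "cellsize": float(cellsize)}
    return {"light": light, "tree_cover": tree, "land_cover": land, "orchard": orchard}, geo


def _toy_gtf(path: Path) -> None:
    """Toy annotation: a compact three-gene fixture (incl. one LOC-prefixed,
    excluded gene) plus one broad gene per synthetic chromosome so that a
    share of simulated SNPs falls in genic space."""
    rows = [
        ("chr1", "toy", "gene", 100, 500, "GENEA"),
        ("chr1", "toy", "exon", 100, 200, "GENEA"),
        ("chr1", "toy", "gene", 1000, 2000, "LOC000001"),
        ("chr1", "toy", "exon", 1000, 1200, "LOC000001"),
        ("chr2", "toy", "gene", 300, 900, "GENEB"),
        ("chr2", "toy", "exon", 300, 400, "GENEB"),
        ("chr2", "toy", "exon", 700, 900, "GENEB"),
    ]
    for i, name in enumerate(f"GENE{c}" for c in "ABCDEFGHIJ"):
        chrom = f"chr{i + 1}"
        rows.append((chrom, "toy", "gene", 2_000_000, 8_000_000, name))
        rows.append((chrom, "toy", "exon", 2_000_000, 2_200_000, name))
    with open(path, "w") as fh:
        for chrom, src, feat, start, end, name in rows:
            attrs = f'gene_id "{name}"; gene_name "{name}";'
            fh.write(f"{chrom}\t{src}\t{feat}\t{start}\t{end}\t.\t+\t.\t{attrs}\n")


def _toy_ontology(path: Path) -> None:
    genes = [f"GENE{c}" for c in "ABCDEFGHIJ"]
    rows = []
    for g in genes[:5]:
        rows.append((g, "GO:0000001", "synaptic signaling", "BP"))
    for g in genes[3:]:
        rows.append((g, "GO:0000002", "metabolic process", "BP"))
    for g in genes:
        rows.append((g, "GO:0000003", "cellular process", "BP"))
    pd.DataFrame(rows, columns=["gene", "term_id", "term_name", "namespace"]).to_csv(
        path, sep="\t", index=False
    )


def _toy_edges(path: Path, seed: int) -> None:
    rng = np.random.default_rng(seed)
    genes = [f"GENE{c}" for c in "ABCDEFGHIJ"]
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if rng.random() < 0.2:
                rows.append((genes[i], genes[j], int(rng.integers(150, 999))))
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_set(
    outdir,
    seed: int = 0,
    n_per_colony: int = 19,
    n_loci: int = 2000,
    n_adaptive: int = 10,
    overwrite: bool = False,
) -> dict:
    """Write a complete fixture set (VCF, colony TSV, rasters, GTF, GO table,
    edge list) plus a manifest with seeds and checksums."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} is not empty; pass overwrite=True")
    outdir.mkdir(parents=True, exist_ok=True)

    colonies = simulate_colonies(seed=seed)
    truth = random_truth(n_loci, n_adaptive=n_adaptive, seed=seed)
    gt, truth = simulate_genotypes(colonies, n_per_colony=n_per_colony, n_loci=n_loci, truth=truth)

    files = {}
    vcf = outdir / "genotypes.vcf"
    write_vcf(gt, vcf)
    files["vcf"] = vcf
    ctsv = outdir / "colonies.tsv"
    colonies.to_csv(ctsv, sep="\t", index=False)
    files["colonies"] = ctsv

    grids, geo = _landscape_grids(colonies, seed)
    for name, grid in grids.items():
        p = outdir / f"{name}.asc"
        write_ascii_grid(p, grid, geo["xll"], geo["yll"], geo["cellsize"])
        files[name] = p

    gtf = outdir / "genes.gtf"
    _toy_gtf(gtf)
    files["gtf"] = gtf
    onto = outdir / "gene2go.tsv"
    _toy_ontology(onto)
    files["ontology"] = onto
    edges = outdir / "edges.tsv"
    _toy_edges(edges, seed)
    files["edges"] = edges

    manifest = {
        "seed": seed,
        "truth": {
            "target_fst": truth.target_fst,
            "adaptive_locus_ids": sorted(truth.adaptive_locus_ids),
            "effect_sizes": truth.effect_sizes,
        },
        "n_individuals": gt.n_individuals,
        "n_loci": gt.n_loci,
        "files": {k: str(p.name) for k, p in files.items()},
        "checksums": {k: _sha256(p) for k, p in files.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
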