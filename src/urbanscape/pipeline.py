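"""End-to-end pipeline orchestration.

Stages: simulate? -> qc -> structure -> ibd -> landscape -> mlpe -> gea ->
annotate -> enrich -> network.  Every stage writes plain TSV outputs into
the run directory and registers them (with checksums) in a machine-
readable manifest; thresholds actually applied are echoed at INFO level so
a run log is an audit trail of the analysis parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as annotate_mod
from . import enrich as enrich_mod
from . import gea as gea_mod
from . import mlpe as mlpe_mod
from . import mrm as mrm_mod
from . import network as network_mod
from . import popgen, qc, resistance, spatial, synthetic
from .admixture import admixture_snmf
from .containers import SymmetricMatrix

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline thresholds; defaults reproduce the study settings."""

    outdir: str = "urbanscape_run"
    simulate: bool = True
    seed: int = 0
    # synthetic sizes (desk-scale defaults)
    n_loci: int = 2000
    n_per_colony: int = 19
    n_adaptive: int = 10
    # qc
    maf_min: float = 0.03
    depth_min: int = 5
    miss_max: float = 0.20
    mean_depth_max: float = 50.0
    ld_window: int = 25
    ld_step: int = 10
    ld_r2: float = 0.9
    # structure
    k_min: int = 1
    k_max: int = 5
    snmf_reps: int = 5
    # inference
    mrm_perms: int = 9999
    rda_perms: int = 999
    sd_threshold: float = 3.0
    alpha: float = 0.05
    score_min: int = 400
    min_genes: int = 3
    # inputs when simulate is off
    vcf: str | None = None
    colonies: str | None = None
    rasters: dict = field(default_factory=dict)
    gtf: str | None = None
    ontology: str | None = None
    edges: str | None = None
    stages: tuple = (
        "qc",
        "structure",
        "ibd",
        "landscape",
        "mlpe",
        "gea",
        "annotate",
        "enrich",
        "network",
    )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Key=value config file; unknown keys are rejected."""
        kwargs = {}
        valid = set(cls.__dataclass_fields__)
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"config line {ln}: expected key=value")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in valid:
                    raise ValueError(f"config line {ln}: unknown key {key!r}")
                typ = cls.__dataclass_fields__[key].type
                if val.lower() in ("true", "false"):
                    kwargs[key] = val.lower() == "true"
                elif key == "stages":
                    kwargs[key] = tuple(v.strip() for v in val.split(","))
                else:
                    try:
                        kwargs[key] = int(val)
                    except ValueError:
                        try:
                            kwargs[key] = float(val)
                        except ValueError:
                            kwargs[key] = val
        return cls(**kwargs)

    def validate(self) -> None:
        if not self.simulate:
            missing = [k for k in ("vcf", "colonies") if getattr(self, k) is None]
            if "gea" in self.stages and self.colonies is None:
                missing.append("colonies (env table)")
            if missing:
                raise ValueError(f"simulate is off but inputs missing: {missing}")


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}, "config": {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()
    }}

    def register(stage: str, name: str, path: Path):
        manifest["files"][name] = {"path": str(path), "sha256": _sha(path)}
        manifest["stages"].setdefault(stage, []).append(name)

    state: dict = {}
    try:
        stage = "simulate"
        if config.simulate:
            log.info("simulate: seed=%d n_loci=%d n_per_colony=%d", config.seed, config.n_loci, config.n_per_colony)
            fx = out / "fixtures"
            synthetic.write_fixture_set(
                fx,
                seed=config.seed,
                n_loci=config.n_loci,
                n_per_colony=config.n_per_colony,
                n_adaptive=config.n_adaptive,
                overwrite=True,
            )
            config.vcf = str(fx / "genotypes.vcf")
            config.colonies = str(fx / "colonies.tsv")
            config.rasters = {k: str(fx / f"{k}.asc") for k in ("light", "tree_cover", "land_cover", "orchard")}
            config.gtf = str(fx / "genes.gtf")
            config.ontology = str(fx / "gene2go.tsv")
            config.edges = str(fx / "edges.tsv")
            register(stage, "fixture_manifest", fx / "manifest.json")

        colonies = pd.read_csv(config.colonies, sep="\t")
        groups = dict(zip(colonies["colony_id"], colonies["group"]))

        stage = "qc"
        if stage in config.stages:
            log.info(
                "qc: maf>=%g depth>=%d miss<=%g mean_depth<=%g ld %d/%d/r2=%g",
                config.maf_min, config.depth_min, config.miss_max,
                config.mean_depth_max, config.ld_window, config.ld_step, config.ld_r2,
            )
            gt, read_report = qc.read_vcf(config.vcf)
            gt, report = qc.apply_filters(
                gt,
                maf_min=config.maf_min,
                depth_min=config.depth_min,
                miss_max=config.miss_max,
                mean_depth_max=config.mean_depth_max,
            )
            gt, removed_ld = qc.ld_prune(gt, config.ld_window, config.ld_step, config.ld_r2)
            report.n_removed_biallelic = read_report.n_removed_biallelic
            report.n_input = read_report.n_input
            report.n_removed_ld = len(removed_ld)
            report.n_output = gt.n_loci
            p = out / "filter_report.tsv"
            report.to_frame().to_csv(p, sep="\t", index=False)
            register(stage, "filter_report", p)
            state["gt"] = gt

        gt = state.get("gt")

        stage = "structure"
        if stage in config.stages and gt is not None:
            pres = popgen.pca(gt)
            p = out / "pca.tsv"
            pd.DataFrame(
                {
                    "axis": np.arange(1, len(pres.eigenvalues) + 1),
                    "eigenvalue": pres.eigenvalues,
                    "variance_fraction": pres.variance_fractions,
                    "tracy_widom_p": pres.tw_p,
                }
            ).to_csv(p, sep="\t", index=False)
            register(stage, "pca", p)

            adm = admixture_snmf(
                gt, k_range=range(config.k_min, config.k_max + 1),
                n_rep=config.snmf_reps, seed=config.seed,
            )
            p = out / "admixture_ce.tsv"
            pd.DataFrame(
                [(k, d["mean_ce"]) for k, d in adm.per_k.items()],
                columns=["K", "mean_cross_entropy"],
            ).to_csv(p, sep="\t", index=False)
            register(stage, "admixture_ce", p)
            pq = out / "admixture_Q.tsv"
            pd.DataFrame(adm.q_matrix(), index=gt.individuals["id"]).to_csv(pq, sep="\t")
            register(stage, "admixture_Q", pq)
            log.info("structure: best K = %d", adm.best_k)

            fst = popgen.pairwise_fst(gt)
            lin = popgen.linearise_fst(fst)
            pf = out / "fst.tsv"
            fst.to_tsv(pf)
            register(stage, "fst", pf)
            pl = out / "fst_linearised.tsv"
            lin.to_tsv(pl)
            register(stage, "fst_linearised", pl)
            state["fst_lin"] = lin

            het = popgen.het_inbreeding(gt)
            ph = out / "het.tsv"
            het.to_csv(ph, sep="\t", index=False)
            register(stage, "het", ph)

        stage = "ibd"
        if stage in config.stages and "fst_lin" in state:
            geo = spatial.geo_distance_matrix(colonies)
            state["geo"] = geo
            pg = out / "geo_km.tsv"
            geo.to_tsv(pg)
            register(stage, "geo_km", pg)
            summ = spatial.group_summary(state["fst_lin"], geo, groups)
            ps = out / "group_summary.tsv"
            summ.to_dataframe().to_csv(ps, sep="\t", index=False)
            register(stage, "group_summary", ps)
            res = mrm_mod.mrm(state["fst_lin"], [geo], n_perm=config.mrm_perms, seed=config.seed)
            pm = out / "ibd_mrm.tsv"
            pd.DataFrame(
                [
                    {
                        "intercept": res.coefficients[0],
                        "slope_per_km": res.coefficients[1],
                        "r_squared": res.r_squared,
                        "f": res.f_statistic,
                        "p": res.p_r2,
                        "n_perm": res.n_perm,
                    }
                ]
            ).to_csv(pm, sep="\t", index=False)
            register(stage, "ibd_mrm", pm)
            log.info("ibd: R^2=%.4f p=%.4g (%d permutations)", res.r_squared, res.p_r2, res.n_perm)

        stage = "landscape"
        if stage in config.stages and config.rasters:
            layers = {k: resistance.read_ascii_grid(v) for k, v in config.rasters.items()}
            state["resistance"] = {}
            for hyp in resistance.HYPOTHESES:
                surf = resistance.build_surface(resistance.CostScheme(hyp), layers)
                mat = resistance.effective_resistance(surf, colonies)
                state["resistance"][hyp] = mat
                p = out / f"resistance_{hyp}.tsv"
                mat.to_tsv(p)
                register(stage, f"resistance_{hyp}", p)

        stage = "mlpe"
        if stage in config.stages and "fst_lin" in state and state.get("resistance"):
            geo = state.get("geo") or spatial.geo_distance_matrix(colonies)
            models = {"isolation_by_distance": geo}
            for hyp in ("light", "orchard_distance", "tree_cover", "land_cover_3", "orchard_plus_light"):
                models[hyp] = state["resistance"][hyp]
            fits = [
                mlpe_mod.fit_mlpe(state["fst_lin"], [m], names=[name])
                for name, m in models.items()
            ]
            comp = mlpe_mod.compare_models(fits, names=list(models))
            p = out / "mlpe_comparison.tsv"
            comp.to_csv(p, sep="\t", index=False)
            register(stage, "mlpe_comparison", p)
            log.info("mlpe: top model %s", comp.loc[comp["aicc_weight"].idxmax(), "model"])

        stage = "gea"
        if stage in config.stages and gt is not None:
            env_map = dict(zip(colonies["colony_id"], colonies["urban_cover_pct"]))
            env = np.array([env_map[c] for c in gt.colony_ids], dtype=float)
            imputed, _ = gea_mod.impute_by_cluster(gt)
            res = gea_mod.rda(
                imputed, env, n_perm=config.rda_perms, seed=config.seed,
                locus_ids=gt.loci["locus_id"].to_numpy(),
            )
            log.info("gea: full-model permutation p=%.4g (%d perms)", res.p_full, res.n_perm)
            outliers = gea_mod.detect_outliers(res, k=config.sd_threshold)
            cands = gea_mod.correlate_candidates(
                imputed, env, outliers, alpha=config.alpha,
                locus_ids=res.locus_ids, loadings=res.loadings[:, 0],
            )
            p = out / "gea_candidates.tsv"
            cands.to_csv(p, sep="\t", index=False)
            register(stage, "gea_candidates", p)
            state["candidates"] = cands[cands["retained"]]

        stage = "annotate"
        if stage in config.stages and "candidates" in state and config.gtf:
            gtf = annotate_mod.read_gtf(config.gtf)
            cand_loci = gt.loci[gt.loci["locus_id"].isin(state["candidates"]["locus_id"])]
            ann = annotate_mod.classify_snps(cand_loci, gtf)
            p = out / "snp_annotation.tsv"
            ann.to_csv(p, sep="\t", index=False)
            register(stage, "snp_annotation", p)
            state["genes"] = set(ann["gene"].dropna())

        stage = "enrich"
        if stage in config.stages and config.ontology and state.get("genes"):
            onto = pd.read_csv(config.ontology, sep="\t")
            try:
                enr = enrich_mod.enrich(state["genes"], onto, min_genes=config.min_genes, alpha=config.alpha)
            except ValueError as exc:
                log.warning("enrich skipped: %s", exc)
                enr = pd.DataFrame()
            p = out / "go_enrichment.tsv"
            enr.to_csv(p, sep="\t", index=False)
            register(stage, "go_enrichment", p)

        stage = "network"
        if stage in config.stages and config.edges and state.get("genes"):
            edges = pd.read_csv(config.edges, sep="\t")
            mets = network_mod.network_metrics(edges, state["genes"], score_min=config.score_min)
            p = out / "network_metrics.tsv"
            mets.per_node.to_csv(p, sep="\t", index=False)
            register(stage, "network_metrics", p)
            pg = out / "network_global.tsv"
            pd.DataFrame(
                [{"density": mets.density, "average_degree": mets.average_degree, "hubs": ",".join(mets.hubs)}]
            ).to_csv(pg, sep="\t", index=False)
            register(stage, "network_global", pg)
    except Exception as exc:  # partial outputs stay on disk
        raise PipelineError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
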