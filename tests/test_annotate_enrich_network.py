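"""SNP classification, hypergeometric enrichment, network topology."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from urbanscape.annotate import classify_snps, read_gtf
from urbanscape.enrich import enrich
from urbanscape.network import network_metrics

TOY_GTF = pd.DataFrame(
    [
        {"chrom": "chr1", "feature": "gene", "start": 100, "end": 500, "gene_id": "G1", "gene_name": "GENEA"},
        {"chrom": "chr1", "feature": "exon", "start": 100, "end": 200, "gene_id": "G1", "gene_name": "GENEA"},
        {"chrom": "chr1", "feature": "gene", "start": 1000, "end": 2000, "gene_id": "G2", "gene_name": "LOC123"},
        {"chrom": "chr1", "feature": "exon", "start": 1000, "end": 1100, "gene_id": "G2", "gene_name": "LOC123"},
    ]
)


def loci(*positions, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": [chrom] * len(positions), "pos": positions,
         "locus_id": [f"s{p}" for p in positions]}
    )


class TestClassifySnps:
    @pytest.mark.parametrize("pos,expected", [(150, "exon"), (300, "intron"), (600, "intergenic")])
    def test_gene_model_classes(self, pos, expected):
        ann = classify_snps(loci(pos), TOY_GTF)
        assert ann["snp_class"].iloc[0] == expected

    def test_closed_interval_boundary_is_exonic(self):
        ann = classify_snps(loci(200), TOY_GTF)
        assert ann["snp_class"].iloc[0] == "exon"
        assert ann["gene"].iloc[0] == "GENEA"

    def test_loc_gene_excluded(self):
        ann = classify_snps(loci(1500), TOY_GTF)
        assert ann["snp_class"].iloc[0] == "intergenic"
        assert pd.isna(ann["gene"].iloc[0])

    def test_absent_chromosome_is_intergenic(self):
        ann = classify_snps(loci(100, chrom="chrZ"), TOY_GTF)
        assert ann["snp_class"].iloc[0] == "intergenic"

    def test_smallest_enclosing_gene_wins(self):
        gtf = pd.concat(
            [
                TOY_GTF,
                pd.DataFrame(
                    [{"chrom": "chr1", "feature": "gene", "start": 50, "end": 5000,
                      "gene_id": "G3", "gene_name": "GENEWIDE"}]
                ),
            ],
            ignore_index=True,
        )
        ann = classify_snps(loci(300), gtf)
        assert ann["gene"].iloc[0] == "GENEA"

    def test_intergenic_distance_reported(self):
        ann = classify_snps(loci(600), TOY_GTF)
        assert ann["distance_bp"].iloc[0] == 100  # to GENEA end at 500

    def test_gtf_reader_round_trip(self, tmp_path):
        p = tmp_path / "t.gtf"
        p.write_text('chr1\tsrc\tgene\t10\t50\t.\t+\t.\tgene_id "X"; gene_name "XN";\n')
        gtf = read_gtf(p)
        assert gtf.iloc[0]["gene_name"] == "XN"
        bad = tmp_path / "bad.gtf"
        bad.write_text("chr1\tonly\tthree\n")
        with pytest.raises(ValueError, match="line 1"):
            read_gtf(bad)


def hypergeom_p_exact(N, K, n, k):
    """Big-integer upper-tail hypergeometric oracle."""
    total = math.comb(N, n)
    return sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / total


def make_ontology(assignments):
    rows = [
        {"gene": g, "term_id": t, "term_name": t, "namespace": "BP"}
        for t, genes in assignments.items()
        for g in genes
    ]
    return pd.DataFrame(rows)


class TestEnrich:
    def test_worked_combinatorial_example(self):
        # N=20 background, K=5 with the term, n=5 candidates, k=3 hits
        bg = [f"g{i}" for i in range(20)]
        onto = make_ontology({"T1": bg[:5], "ALL": bg})
        cand = set(bg[:3] + bg[10:12])
        out = enrich(cand, onto, min_genes=3)
        row = out[out["term_id"] == "T1"].iloc[0]
        assert row["p"] == pytest.approx(1126 / 15504, rel=1e-12)
        assert row["fold"] == pytest.approx(2.4)

    def test_saturated_term(self):
        bg = [f"g{i}" for i in range(6)]
        onto = make_ontology({"T": bg})
        out = enrich(set(bg), onto, min_genes=3)
        assert out["p"].iloc[0] == pytest.approx(1.0)
        assert out["fold"].iloc[0] == pytest.approx(1.0)

    def test_matches_exact_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            N = int(rng.integers(8, 31))
            bg = [f"g{i}" for i in range(N)]
            K = int(rng.integers(3, N))
            n = int(rng.integers(3, N))
            term_genes = list(rng.choice(bg, K, replace=False))
            cand = set(rng.choice(bg, n, replace=False))
            k = len(cand & set(term_genes))
            onto = make_ontology({"T": term_genes, "ALL": bg})
            out = enrich(cand, onto, min_genes=0)
            row = out[out["term_id"] == "T"]
            if k == 0:
                continue
            assert row["p"].iloc[0] == pytest.approx(hypergeom_p_exact(N, K, n, k), rel=1e-9)

    def test_min_genes_filter_applied_before_bh(self):
        bg = [f"g{i}" for i in range(20)]
        onto = make_ontology({"SMALL": bg[:2], "BIG": bg[:6], "ALL": bg})
        out = enrich(set(bg[:6]), onto, min_genes=3)
        assert "SMALL" not in set(out["term_id"])  # k=2 < 3 excluded pre-BH

    def test_disjoint_candidates_rejected(self):
        onto = make_ontology({"T": ["g1", "g2", "g3"]})
        with pytest.raises(ValueError):
            enrich({"zz"}, onto)

    @given(st.lists(st.floats(1e-9, 1.0), min_size=2, max_size=40))
    def test_bh_q_values_monotone_in_p(self, pvals):
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(pvals, method="fdr_bh")
        order = np.argsort(pvals)
        assert np.all(np.diff(np.array(q)[order]) >= -1e-12)

    def test_null_shuffle_rarely_significant(self):
        rng = np.random.default_rng(1)
        bg = [f"g{i}" for i in range(60)]
        terms = {f"T{t}": list(rng.choice(bg, 8, replace=False)) for t in range(15)}
        terms["ALL"] = bg
        onto = make_ontology(terms)
        n_sig = 0
        for _ in range(50):
            cand = set(rng.choice(bg, 10, replace=False))
            out = enrich(cand, onto, min_genes=3)
            n_sig += int(out["significant"].sum() > 0) if len(out) else 0
        assert n_sig / 50 < 0.1


class TestNetworkMetrics:
    def edges(self, pairs, score=500):
        return pd.DataFrame(
            [{"gene_a": a, "gene_b": b, "combined_score": score} for a, b in pairs]
        )

    def test_candidate_network_density_and_degree(self):
        """56 genes with 7 retained interactions: density 0.0045, mean degree 0.25."""
        nodes = {f"g{i}" for i in range(56)}
        pairs = [(f"g{i}", f"g{i+1}") for i in range(0, 14, 2)]
        m = network_metrics(self.edges(pairs), nodes)
        assert m.density == pytest.approx(2 * 7 / (56 * 55), rel=1e-12)
        assert m.average_degree == pytest.approx(0.25)

    def test_density_complete_triangle(self):
        m = network_metrics(self.edges([("a", "b"), ("b", "c"), ("a", "c")]), {"a", "b", "c"})
        assert m.density == pytest.approx(1.0)

    def test_star_betweenness(self):
        pairs = [("hub", x) for x in ("l1", "l2", "l3")]
        m = network_metrics(self.edges(pairs), {"hub", "l1", "l2", "l3"})
        bt = dict(zip(m.per_node["gene"], m.per_node["betweenness"]))
        assert bt["hub"] == pytest.approx(3.0)  # three leaf pairs routed through it
        assert bt["l1"] == 0.0

    def test_low_scores_filtered(self):
        m = network_metrics(self.edges([("a", "b")], score=399), {"a", "b"})
        assert m.graph.number_of_edges() == 0
        m2 = network_metrics(self.edges([("a", "b")], score=400), {"a", "b"})
        assert m2.graph.number_of_edges() == 1

    def test_self_loops_and_duplicates_collapse(self):
        e = self.edges([("a", "a"), ("a", "b"), ("a", "b")])
        m = network_metrics(e, {"a", "b", "c"})
        assert m.graph.number_of_edges() == 1

    def test_hub_rule_mean_plus_sd(self):
        pairs = [("hub", x) for x in ("a", "b", "c", "d")]
        m = network_metrics(self.edges(pairs), {"hub", "a", "b", "c", "d", "iso"})
        deg = np.array(m.per_node["degree"])
        cut = deg.mean() + deg.std(ddof=0)
        assert m.hubs == sorted(
            g for g, d in zip(m.per_node["gene"], m.per_node["degree"]) if d > cut
        )
        assert "hub" in m.hubs

    def test_density_matches_hand_count_on_random_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            n = int(rng.integers(5, 12))
            nodes = {f"n{i}" for i in range(n)}
            pairs = [
                (f"n{i}", f"n{j}")
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.3
            ]
            m = network_metrics(self.edges(pairs), nodes)
            assert m.density == pytest.approx(2 * len(pairs) / (n * (n - 1)))
            assert m.average_degree == pytest.approx(2 * len(pairs) / n)
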