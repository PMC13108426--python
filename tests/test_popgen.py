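"""FST, heterozygosity and PCA against independent oracles."""

import numpy as np
import pytest

from urbanscape.popgen import (
    het_inbreeding,
    linearise_fst,
    pairwise_fst,
    pca,
    tracy_widom_sf,
    wc_fst_pair,
)
from urbanscape.synthetic import TruthSet, simulate_colonies, simulate_genotypes


def wc_theta_oracle(counts_a, counts_b):
    """Direct per-locus Weir-Cockerham variance components, scalar arithmetic.

    counts_* are lists of dosage lists (one per locus).  Returns the
    multi-locus ratio-of-sums estimate.
    """
    num = den = 0.0
    for da, db in zip(counts_a, counts_b):
        r = 2
        ns = [len(da), len(db)]
        ps = [sum(da) / (2 * len(da)), sum(db) / (2 * len(db))]
        hs = [sum(1 for x in da if x == 1) / len(da), sum(1 for x in db if x == 1) / len(db)]
        n_bar = sum(ns) / r
        n_c = (r * n_bar - sum(n**2 for n in ns) / (r * n_bar)) / (r - 1)
        p_bar = sum(n * p for n, p in zip(ns, ps)) / (r * n_bar)
        s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * n_bar)
        h_bar = sum(n * h for n, h in zip(ns, hs)) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
        num += a
        den += a + b + c
    return num / den


class TestPairwiseFst:
    def test_fixed_difference_gives_theta_one(self, gt_factory):
        dos = np.concatenate([np.zeros((10, 1)), np.full((10, 1), 2.0)])
        gt = gt_factory(dos, colony_of=["a"] * 10 + ["b"] * 10)
        assert pairwise_fst(gt).values[0, 1] == pytest.approx(1.0)

    def test_identical_allele_counts_nonpositive(self, gt_factory):
        block = np.array([0, 0, 1, 1, 2, 2, 1, 0, 2, 1], dtype=float)[:, None]
        dos = np.concatenate([block, block])
        gt = gt_factory(dos, colony_of=["a"] * 10 + ["b"] * 10)
        assert pairwise_fst(gt).values[0, 1] <= 0

    def test_matches_direct_formula_oracle(self, gt_factory):
        rng = np.random.default_rng(10)
        da = rng.binomial(2, rng.uniform(0.2, 0.8, 5)[None, :], (8, 5)).astype(float)
        db = rng.binomial(2, rng.uniform(0.2, 0.8, 5)[None, :], (6, 5)).astype(float)
        expected = wc_theta_oracle(
            [list(da[:, j]) for j in range(5)], [list(db[:, j]) for j in range(5)]
        )
        assert wc_fst_pair(da, db) == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariant_to_individual_order(self, gt_factory):
        rng = np.random.default_rng(11)
        dos = rng.binomial(2, 0.4, (20, 30)).astype(float)
        colony = ["a"] * 10 + ["b"] * 10
        gt = gt_factory(dos, colony_of=colony)
        perm = rng.permutation(20)
        gt2 = gt_factory(dos[perm], colony_of=[colony[i] for i in perm])
        m1 = pairwise_fst(gt)
        m2 = pairwise_fst(gt2).reindex(m1.labels)
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-14)

    def test_requires_two_individuals_per_group(self, gt_factory):
        gt = gt_factory(np.zeros((3, 2)), colony_of=["a", "a", "b"])
        with pytest.raises(ValueError):
            pairwise_fst(gt)


class TestLineariseFst:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.0, 0.0), (0.5, 1.0), (0.0013791, 0.0013791 / (1 - 0.0013791))],
    )
    def test_arithmetic(self, x, expected):
        from urbanscape.containers import SymmetricMatrix

        m = SymmetricMatrix(["a", "b"], np.array([[0, x], [x, 0.0]]), "fst")
        assert linearise_fst(m).values[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_value_one_rejected(self):
        from urbanscape.containers import SymmetricMatrix

        m = SymmetricMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]), "fst")
        with pytest.raises(ValueError):
            linearise_fst(m)


class TestHetInbreeding:
    def test_all_heterozygous_negative_f(self, gt_factory):
        rng = np.random.default_rng(12)
        dos = rng.binomial(2, 0.5, (20, 100)).astype(float)
        dos[0] = 1.0  # heterozygous at every locus
        rep = het_inbreeding(gt_factory(dos))
        assert rep.loc[rep["id"] == "i0", "F"].iloc[0] < 0

    def test_all_homozygous_positive_f(self, gt_factory):
        rng = np.random.default_rng(13)
        dos = rng.binomial(2, 0.5, (20, 100)).astype(float)
        dos[0] = np.where(dos[0] == 1.0, 0.0, dos[0])
        rep = het_inbreeding(gt_factory(dos))
        assert rep.loc[rep["id"] == "i0", "F"].iloc[0] > 0

    def test_panmixia_mean_f_near_zero(self, gt_factory):
        """Hardy-Weinberg draws give mean F ~ 0 within Monte-Carlo error."""
        means = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            p = rng.uniform(0.1, 0.9, 300)
            dos = rng.binomial(2, p[None, :], (30, 300)).astype(float)
            rep = het_inbreeding(gt_factory(dos))
            means.append(rep["F"].mean())
        assert abs(np.mean(means)) < 0.01


class TestPca:
    def test_variance_fractions_sum_to_one(self, gt_factory):
        rng = np.random.default_rng(14)
        dos = rng.binomial(2, 0.4, (15, 60)).astype(float)
        res = pca(gt_factory(dos))
        assert res.variance_fractions.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_scores_match_svd_oracle(self, gt_factory):
        rng = np.random.default_rng(15)
        dos = rng.binomial(2, 0.4, (12, 40)).astype(float)
        res = pca(gt_factory(dos), scaling="none")
        x = dos - dos.mean(axis=0)
        x = x[:, dos.std(axis=0, ddof=1) > 0]
        u, s, _ = np.linalg.svd(x, full_matrices=False)
        expected = u * s
        # columns defined up to sign
        for j in range(3):
            assert min(
                np.abs(res.scores[:, j] - expected[:, j]).max(),
                np.abs(res.scores[:, j] + expected[:, j]).max(),
            ) < 1e-8

    def test_two_population_separation(self, gt_factory):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(16)
        F = 0.1
        p0 = rng.uniform(0.2, 0.8, 500)
        a, b = p0 * (1 - F) / F, (1 - p0) * (1 - F) / F
        p1, p2 = rng.beta(a, b), rng.beta(a, b)
        dos = np.vstack(
            [rng.binomial(2, p1[None, :], (20, 500)), rng.binomial(2, p2[None, :], (20, 500))]
        ).astype(float)
        res = pca(gt_factory(dos))
        labels = [0] * 20 + [1] * 20
        assert silhouette_score(res.scores[:, :1], labels) > 0.5

    def test_tw_detects_structure_not_noise(self, gt_factory):
        rng = np.random.default_rng(17)
        # pure noise: leading axis should not be overwhelmingly significant
        dos = rng.binomial(2, 0.5, (40, 400)).astype(float)
        res_null = pca(gt_factory(dos))
        # two diverged groups: leading axis highly significant
        F = 0.1
        p0 = rng.uniform(0.2, 0.8, 400)
        a, b = p0 * (1 - F) / F, (1 - p0) * (1 - F) / F
        dos2 = np.vstack(
            [
                rng.binomial(2, rng.beta(a, b)[None, :], (20, 400)),
                rng.binomial(2, rng.beta(a, b)[None, :], (20, 400)),
            ]
        ).astype(float)
        res_struct = pca(gt_factory(dos2))
        assert res_struct.tw_p[0] < 1e-6
        assert res_struct.tw_p[0] < res_null.tw_p[0]

    def test_tw_sf_monotone_and_calibrated(self):
        # TW(beta=1) ~95th percentile is near 0.98 (known tabulated value)
        assert tracy_widom_sf(0.98) == pytest.approx(0.05, abs=0.01)
        x = np.linspace(-4, 4, 50)
        assert np.all(np.diff(tracy_widom_sf(x)) < 0)


def test_fst_recovery_within_relative_band():
    """F-model simulations recover the target mean FST within +/-50%."""
    vals = []
    for seed in range(5):
        col = simulate_colonies(seed=seed)
        gt, _ = simulate_genotypes(
            col, n_per_colony=19, n_loci=5000, truth=TruthSet(target_fst=0.002, seed=seed)
        )
        fst = pairwise_fst(gt)
        iu = np.triu_indices(fst.n, 1)
        vals.append(fst.values[iu].mean())
    assert np.mean(vals) == pytest.approx(0.002, rel=0.5)
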