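"""FST variance components, Nei distance, NJ trees, genotype PCA."""

import numpy as np
import pytest

import consgen as cg
from .conftest import make_gm


class TestWeirCockerhamFst:
    def test_fixed_difference_is_one(self):
        p1 = make_gm(np.zeros((10, 1), int))
        p2 = make_gm(np.full((10, 1), 2))
        assert cg.weir_cockerham_fst(p1, p2).weighted_fst == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, (10, 50))
        res = cg.weir_cockerham_fst(make_gm(calls), make_gm(calls))
        assert res.weighted_fst <= 0.0

    def test_variance_components_match_scalar_hand_evaluation(self):
        # 2 pops x 5 individuals x 3 loci; expected a/b/c evaluated by a
        # scalar spreadsheet-style pass over the WC84 component formulas
        pop1 = make_gm([[0, 1, 2], [0, 1, 1], [1, 2, 0], [0, 1, 1], [1, 1, 0]])
        pop2 = make_gm([[2, 1, 0], [2, 2, 1], [1, 2, 0], [2, 1, 1], [2, 2, 0]])
        res = cg.weir_cockerham_fst(pop1, pop2)
        np.testing.assert_allclose(res.a, [0.2325, 0.0075, -0.005], atol=1e-10)
        np.testing.assert_allclose(res.b, [-0.0125, -0.0875, 0.025], atol=1e-10)
        np.testing.assert_allclose(res.c, [0.15, 0.3, 0.2], atol=1e-10)
        expected_weighted = (0.2325 + 0.0075 - 0.005) / (0.2325 - 0.0125 + 0.15 + 0.0075 - 0.0875 + 0.3 - 0.005 + 0.025 + 0.2)
        assert res.weighted_fst == pytest.approx(expected_weighted)

    def test_monomorphic_locus_excluded(self):
        p1 = make_gm([[0, 0], [0, 1], [0, 2]])
        p2 = make_gm([[0, 1], [0, 1], [0, 2]])
        res = cg.weir_cockerham_fst(p1, p2)
        assert np.isnan(res.a[0]) and not np.isnan(res.a[1])

    def test_self_split_fst_near_zero(self):
        """Random halves of one population are undifferentiated."""
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 1000)
        calls = rng.binomial(1, p, (60, 2, 1000)).sum(axis=1)
        gm = make_gm(calls, positions=np.arange(1, 1001) * 1000)
        half = rng.permutation(60)
        g1 = gm.subset_samples([gm.samples[i] for i in half[:30]])
        g2 = gm.subset_samples([gm.samples[i] for i in half[30:]])
        assert abs(cg.weir_cockerham_fst(g1, g2).weighted_fst) < 0.02

    def test_drifted_populations_match_expectation(self):
        """FST between populations diverged t generations from shared founders
        grows with t and tracks 1 - (1 - 1/(2Ne))^t."""
        n, reps = 25, 8
        pos = [np.arange(1, 401) * 50_000]
        means = {}
        for t in (5, 15):
            vals = []
            for rep in range(reps):
                freqs = [np.random.default_rng(500 + rep).uniform(0.1, 0.9, 400)]
                pops = []
                for ps in (0, 1):
                    cfg = cg.SimConfig(n // 2, n - n // 2, t, "RR",
                                       genome=cg.default_genome(1, 400),
                                       sample_generations=(t,), sample_males=n // 2,
                                       sample_females=n - n // 2,
                                       seed=4000 + rep * 2 + ps + t * 100)
                    pops.append(
                        cg.simulate_flock(cfg, positions=pos, founder_freqs=freqs).samples[t]
                    )
                vals.append(cg.weir_cockerham_fst(*pops).weighted_fst)
            means[t] = float(np.mean(vals))
            expected = 1 - (1 - 1 / (2 * n)) ** t
            assert means[t] == pytest.approx(expected, abs=0.05)
        assert means[15] > means[5]


class TestNeiDistance:
    def test_identical_frequencies_zero(self):
        p = np.array([0.3, 0.6, 0.5])
        assert cg.nei_distance(p, p) == 0.0

    def test_disjoint_alleles_infinite(self):
        assert cg.nei_distance(np.array([0.0]), np.array([1.0])) == float("inf")

    def test_two_locus_arithmetic(self):
        p1 = np.array([0.2, 0.5])  # ALT freqs; locus 1: (0.8, 0.2) vs (0.6, 0.4)
        p2 = np.array([0.4, 0.5])
        num = 0.8 * 0.6 + 0.2 * 0.4 + 0.5 * 0.5 + 0.5 * 0.5
        jx = 0.8**2 + 0.2**2 + 0.5**2 + 0.5**2
        jy = 0.6**2 + 0.4**2 + 0.5**2 + 0.5**2
        assert cg.nei_distance(p1, p2) == pytest.approx(-np.log(num / np.sqrt(jx * jy)))

    def test_multilocus_accumulates_before_ratio(self):
        # distinct from averaging per-locus ratios: an extreme locus must not dominate
        p1 = np.array([0.01, 0.5])
        p2 = np.array([0.99, 0.5])
        per_locus_mean = np.mean(
            [cg.nei_distance(p1[[i]], p2[[i]]) for i in range(2)]
        )
        assert cg.nei_distance(p1, p2) < per_locus_mean


def patristic(newick: str, labels):
    """Leaf-to-leaf path lengths from a newick string (independent check)."""
    from skbio import TreeNode
    from io import StringIO

    tree = TreeNode.read(StringIO(newick))
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            ta = tree.find(a)
            tb = tree.find(b)
            out[(a, b)] = ta.distance(tb)
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        nwk = cg.neighbor_joining(d, ["A", "B", "C"])
        dist = patristic(nwk, ["A", "B", "C"])
        assert dist[("A", "B")] == pytest.approx(5)
        assert dist[("A", "C")] == pytest.approx(9)
        assert dist[("B", "C")] == pytest.approx(10)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        nwk = cg.neighbor_joining(d, labels)
        dist = patristic(nwk, labels)
        for i, a in enumerate(labels):
            for j in range(i + 1, 4):
                assert dist[(a, labels[j])] == pytest.approx(d[i, j])

    def test_equidistant_taxa_equal_terminal_branches(self):
        n = 4
        d = np.full((n, n), 2.0)
        np.fill_diagonal(d, 0.0)
        nwk = cg.neighbor_joining(d, list("ABCD"))
        dist = patristic(nwk, list("ABCD"))
        assert all(v == pytest.approx(2.0) for v in dist.values())

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
        with pytest.raises(ValueError):
            cg.neighbor_joining(d, list("ABC"))


class TestGenotypePca:
    def test_duplicated_clusters_separate_on_pc1(self):
        a = [0, 0, 2, 2, 0, 2]
        b = [2, 2, 0, 0, 2, 0]
        gm = make_gm([a, a, a, b, b, b])
        coords, explained = cg.genotype_pca(gm, k=1)
        assert explained[0] == pytest.approx(1.0)
        assert np.allclose(coords[:3, 0], coords[0, 0])
        assert np.allclose(coords[3:, 0], coords[3, 0])
        assert coords[0, 0] * coords[3, 0] < 0

    def test_explained_fractions_nonincreasing_and_bounded(self):
        rng = np.random.default_rng(5)
        gm = make_gm(rng.integers(0, 3, (12, 40)))
        _, explained = cg.genotype_pca(gm, k=5)
        assert explained.sum() <= 1.0 + 1e-12
        assert all(b <= a + 1e-12 for a, b in zip(explained, explained[1:]))

    def test_matches_direct_eigendecomposition(self):
        gm = make_gm([[0, 2], [1, 0], [2, 1]])
        coords, explained = cg.genotype_pca(gm, k=2)
        x = gm.calls.astype(float)
        x -= x.mean(axis=0)
        evals, evecs = np.linalg.eigh(x.T @ x)
        order = np.argsort(evals)[::-1]
        ref = x @ evecs[:, order]
        for j in range(2):
            assert np.allclose(np.abs(coords[:, j]), np.abs(ref[:, j]), atol=1e-9)

    def test_k_above_rank_truncated_with_warning(self):
        gm = make_gm([[0, 2], [2, 0], [1, 1]])
        with pytest.warns(UserWarning, match="rank"):
            coords, _ = cg.genotype_pca(gm, k=4)
        assert coords.shape[1] <= 2
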