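"""LD estimators, decay curves, and the Waples LD-Ne inversion."""

import numpy as np
import pytest

import consgen as cg
from consgen.io import MISSING
from consgen.ld import _waples_ne, genotype_r2_matrix


class TestPairwiseR2:
    def test_perfect_coupling_both_methods(self):
        a = np.array([0, 0, 0, 0, 2, 2, 2, 2])
        assert cg.composite_r2(a, a) == pytest.approx(1.0)
        assert cg.em_haplotype_r2(a, a) == pytest.approx(1.0)

    def test_linkage_equilibrium_product_counts(self):
        # 16 individuals with genotype counts exactly at the product form for
        # p = q = 0.5 at both loci -> D = 0
        a = np.repeat([0, 1, 2], [4, 8, 4])
        b = np.concatenate([[0, 1, 1, 2], [0, 0, 1, 1, 1, 1, 2, 2], [0, 1, 1, 2]])
        assert cg.em_haplotype_r2(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_em_matches_direct_haplotype_counts_without_double_heterozygotes(self):
        # phase is unambiguous when no individual is het at both loci: every
        # genotype decomposes uniquely into haplotypes, so the EM answer must
        # equal the plain haplotype-count r²
        a = np.array([0, 0, 1, 1, 2, 2, 0, 2])
        b = np.array([0, 1, 0, 2, 0, 2, 2, 0])
        counts = {"AB": 0.0, "Ab": 0.0, "aB": 0.0, "ab": 0.0}
        for ga, gb in zip(a, b):  # REF allele = 'A'/'B'
            for copy in range(2):
                ha = "A" if (ga == 0 or (ga == 1 and copy == 0)) else "a"
                hb = "B" if (gb == 0 or (gb == 1 and copy == 0)) else "b"
                counts[ha + hb] += 1
        # the het-het copy pairing above is only valid because no individual
        # is het at both loci (each het locus pairs with a homozygous one)
        total = sum(counts.values())
        pab = counts["AB"] / total
        pa = (counts["AB"] + counts["Ab"]) / total
        pb = (counts["AB"] + counts["aB"]) / total
        d = pab - pa * pb
        expected = d * d / (pa * (1 - pa) * pb * (1 - pb))
        assert cg.em_haplotype_r2(a, b) == pytest.approx(expected, abs=1e-6)

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 3, 40)
        for est in (cg.composite_r2, cg.em_haplotype_r2):
            base = est(a, b)
            assert est(2 - a, b) == pytest.approx(base, abs=1e-9)
            assert est(a, 2 - b) == pytest.approx(base, abs=1e-9)

    def test_monomorphic_locus_undefined(self):
        a = np.zeros(10, dtype=int)
        b = np.array([0, 1] * 5)
        assert np.isnan(cg.composite_r2(a, b))
        assert np.isnan(cg.em_haplotype_r2(a, b))

    def test_missing_calls_use_pairwise_complete(self):
        a = np.array([0, 0, 2, 2, MISSING, 1])
        b = np.array([0, 0, 2, 2, 1, MISSING])
        assert cg.composite_r2(a, b) == pytest.approx(1.0)

    def test_r2_matrix_matches_pairwise_calls(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, (30, 6))
        m = genotype_r2_matrix(calls)
        for i in range(6):
            for j in range(i + 1, 6):
                assert m[i, j] == pytest.approx(cg.composite_r2(calls[:, i], calls[:, j]))


class TestDecayCurve:
    @staticmethod
    def strong_ld_panel():
        genome = [cg.ChromosomeSpec("gga1", 2_000_000, 300, cm_per_mb=30.0)]
        cfg = cg.SimConfig(10, 40, 30, "RR", genome=genome, seed=7,
                           sample_generations=(30,), sample_males=10, sample_females=20)
        return cg.simulate_flock(cfg).samples[30]

    def test_simulated_ld_decays_with_distance(self):
        gm = self.strong_ld_panel()
        curve = cg.ld_decay(gm, max_distance_bp=500_000, n_bins=10, method="composite")
        assert curve.mean_r2[0] > curve.mean_r2[-1]
        assert curve.half_decay_distance_bp is not None
        assert 0 < curve.half_decay_distance_bp < 500_000

    def test_flat_curve_has_no_half_decay(self):
        gm = self.strong_ld_panel()
        curve = cg.ld_decay(gm, max_distance_bp=40_000, n_bins=4, method="composite")
        # within 40 kb the curve stays near its maximum: no half-decay crossing
        if curve.half_decay_distance_bp is not None:
            assert min(curve.mean_r2) < max(curve.mean_r2) / 2

    def test_single_bin_undefined(self):
        gm = self.strong_ld_panel()
        curve = cg.ld_decay(gm, max_distance_bp=500_000, n_bins=1, method="composite")
        assert curve.half_decay_distance_bp is None

    def test_five_bin_preset_shape(self):
        gm = self.strong_ld_panel()
        curve = cg.ld_decay(gm, method="composite")
        assert len(curve.mean_r2) == 5
        assert curve.bin_edges_bp[0] == 0 and curve.bin_edges_bp[-1] == 500_000
        assert int(curve.n_pairs.sum()) > 0


class TestWaplesInversion:
    def test_no_correction_limit_inverts_drift_expectation(self):
        s = 1e7
        ne = _waples_ne(1 / (3 * 100) + 1 / s + 3.19 / s**2, s)
        # the published inversion carries an O(1/Ne) drift-term refinement, so
        # inverting the leading-order expectation 1/(3Ne) is close, not exact
        assert ne == pytest.approx(100, rel=0.05)

    def test_noise_floor_flagged_infinite(self):
        assert _waples_ne(1 / 50 , 50) == float("inf")  # r2 == sampling expectation branch
        assert np.isinf(_waples_ne(0.0, 1000))

    def test_small_sample_branch_used_below_30(self):
        r2 = 0.0018 + 0.907 / 20 + 4.44 / 400 + 0.01
        assert np.isfinite(_waples_ne(r2, 20))

    def test_ne_from_ld_excludes_infinite_chromosomes(self):
        rng = np.random.default_rng(2)
        # two chromosomes of independent loci at huge n: corrected r2 <= 0
        calls = rng.binomial(2, 0.5, (400, 40))
        from .conftest import make_gm

        gm = make_gm(calls, chrom=["gga1"] * 20 + ["gga11"] * 20,
                     positions=list(range(1000, 21000, 1000)) * 2)
        est = cg.ne_from_ld(gm)
        finite = [v for v in est.per_chromosome.values() if np.isfinite(v)]
        assert est.n_infinite + len(finite) == len(est.per_chromosome)
        if finite:
            assert est.class_averages["all"] == pytest.approx(np.mean(finite))
        else:
            assert np.isnan(est.class_averages["all"])

    def test_macro_class_uses_chromosomes_one_to_five(self):
        from consgen.ld import chromosome_size_class

        assert [chromosome_size_class(f"gga{i}") for i in (1, 5)] == ["macro", "macro"]
        assert chromosome_size_class("gga6") == "intermediate"
        assert chromosome_size_class("gga10") == "intermediate"
        assert chromosome_size_class("gga11") == "micro"
        assert chromosome_size_class("gga28") == "micro"
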