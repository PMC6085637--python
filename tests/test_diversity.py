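"""Diversity statistics: Ho/He/P_N, rarefaction richness, windowed pi, trends."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import consgen as cg
from consgen.diversity import DiversitySummary
from consgen.io import MISSING
from .conftest import make_gm


class TestHeterozygosity:
    def test_observed_hand_count(self):
        gm = make_gm([[0, 0], [1, 0], [1, 1], [2, 2]])
        assert cg.observed_heterozygosity(gm) == pytest.approx((2 / 4 + 1 / 4) / 2)

    @pytest.mark.parametrize("code,expected", [(1, 1.0), (0, 0.0), (2, 0.0)])
    def test_observed_extremes(self, code, expected):
        gm = make_gm(np.full((6, 3), code))
        assert cg.observed_heterozygosity(gm) == expected

    def test_expected_closed_form(self):
        # p = 0.1 over 5 diploids -> He = 2 * 0.1 * 0.9
        gm = make_gm([[1], [0], [0], [0], [0]])
        assert cg.expected_heterozygosity(gm) == pytest.approx(0.18)

    def test_expected_maximum_at_half(self):
        gm = make_gm([[0], [2], [1], [1]])
        assert cg.expected_heterozygosity(gm) == pytest.approx(0.5)

    def test_expected_monomorphic_zero_and_unbiased_factor(self):
        gm = make_gm([[0], [0], [0]])
        assert cg.expected_heterozygosity(gm) == 0.0
        gm2 = make_gm([[0], [2]])
        # 2n/(2n-1) factor with n=2: 0.5 * 4/3
        assert cg.expected_heterozygosity(gm2, unbiased=True) == pytest.approx(0.5 * 4 / 3)

    def test_missing_calls_excluded(self):
        gm = make_gm([[1, MISSING], [1, 0], [MISSING, 0], [0, 0]])
        assert cg.observed_heterozygosity(gm) == pytest.approx((2 / 3 + 0.0) / 2)


class TestProportionPolymorphic:
    def test_counts_and_denominator(self):
        gm = make_gm([[0, 1, 0, 1], [0, 2, 1, 0]])
        assert cg.proportion_polymorphic(gm) == pytest.approx(0.75)
        assert cg.proportion_polymorphic(gm, panel_size=8) == pytest.approx(3 / 8)

    def test_fixed_and_fully_segregating(self):
        assert cg.proportion_polymorphic(make_gm(np.zeros((5, 4), int))) == 0.0
        assert cg.proportion_polymorphic(make_gm([[0, 1], [1, 2], [2, 0], [1, 1]])) == 1.0


def richness_subsample_oracle(n_ref: int, n_alt: int, g: int) -> float:
    """Mean distinct-allele count over every size-g subsample of gene copies."""
    copies = [0] * n_ref + [1] * n_alt
    vals = [len(set(c)) for c in itertools.combinations(copies, g)]
    return sum(vals) / len(vals)


class TestAllelicRichness:
    def test_example_counts_8_2_at_g2(self):
        gm = make_gm([[0], [0], [0], [1], [1]])  # 8 ref / 2 alt copies
        assert cg.allelic_richness(gm, 2) == pytest.approx(61 / 45)
        assert cg.allelic_richness(gm, 2) == pytest.approx(richness_subsample_oracle(8, 2, 2))

    def test_monomorphic_is_one_and_full_sample_counts_alleles(self):
        mono = make_gm([[0], [0], [0]])
        assert cg.allelic_richness(mono, 4) == 1.0
        seg = make_gm([[0], [1], [2]])
        assert cg.allelic_richness(seg, 6) == 2.0

    def test_invalid_g_raises(self):
        gm = make_gm([[0], [1]])
        with pytest.raises(ValueError):
            cg.allelic_richness(gm, 0)
        with pytest.raises(ValueError, match="locus"):
            cg.allelic_richness(gm, 5)

    @given(st.integers(0, 6), st.integers(0, 6), st.integers(1, 12))
    def test_matches_exhaustive_enumeration_small_n(self, n_ref, n_alt, g):
        n = n_ref + n_alt
        if n == 0 or g > n or n > 12:
            return
        genos = [0] * (n_ref // 2) + [2] * (n_alt // 2)
        if n_ref % 2 and n_alt % 2:
            genos.append(1)
        elif n_ref % 2 or n_alt % 2:
            return  # odd copy counts not representable by diploid calls
        gm = make_gm(np.array(genos).reshape(-1, 1))
        assert cg.allelic_richness(gm, g) == pytest.approx(
            richness_subsample_oracle(n_ref, n_alt, g), rel=1e-9
        )

    @given(st.integers(1, 8), st.integers(1, 8))
    def test_monotone_in_g(self, n_hom_ref, n_hom_alt):
        gm = make_gm(np.array([0] * n_hom_ref + [2] * n_hom_alt).reshape(-1, 1))
        n = 2 * (n_hom_ref + n_hom_alt)
        vals = [cg.allelic_richness(gm, g) for g in range(1, n + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestPiWindows:
    def test_single_site_hand_value(self):
        gm = make_gm([[1]] * 5, positions=[50])
        w = cg.nucleotide_diversity_windows(gm, window_bp=100, step_bp=100)
        # 5 ref / 5 alt alleles: 25 differing pairs of 45 -> 50/90 per site
        assert w[0].pi == pytest.approx((50 / 90) / 100)
        assert w[0].n_sites == 1

    def test_empty_window_and_fixed_site(self):
        gm = make_gm([[2], [2]], positions=[250])
        w = cg.nucleotide_diversity_windows(gm, window_bp=100, step_bp=100)
        assert w[0].pi == 0.0 and w[0].n_sites == 0  # window 1-100 has no SNP
        assert w[2].pi == 0.0 and w[2].n_sites == 1  # fixed-alt site contributes 0

    def test_windows_tile_with_step(self):
        gm = make_gm(np.tile([0, 1], (3, 5)), positions=np.arange(1, 11) * 1000)
        w = cg.nucleotide_diversity_windows(gm, window_bp=5000, step_bp=1000)
        assert [x.start_bp for x in w[:3]] == [1, 1001, 2001]
        assert all(x.end_bp - x.start_bp + 1 == 5000 for x in w)


class TestGenerationalTrend:
    @staticmethod
    def summary(ho, he=0.2, pn=0.8, ar=1.2):
        return DiversitySummary(Ho=ho, He=he, P_N=pn, A_R=ar, g=20)

    def test_small_decline_retains(self):
        rep = cg.generational_trend(
            {"G07": self.summary(0.2250), "G10": self.summary(0.2211)},
            inbreeding={"G07": 0.05, "G10": 0.06},
        )
        assert rep.relative_change["Ho"]["G10"] == pytest.approx(-0.0173, abs=1e-4)
        assert rep.retention_ok and rep.inbreeding_ok

    def test_identical_generations_zero_change(self):
        rep = cg.generational_trend({"a": self.summary(0.2), "b": self.summary(0.2)})
        assert all(v == 0.0 for m in rep.relative_change.values() for v in m.values())

    def test_15_percent_drop_fails_retention(self):
        rep = cg.generational_trend({"a": self.summary(0.3, he=0.2), "b": self.summary(0.3, he=0.17)})
        assert rep.relative_change["He"]["b"] == pytest.approx(-0.15)
        assert not rep.retention_ok

    def test_inbreeding_above_threshold_flags(self):
        rep = cg.generational_trend(
            {"a": self.summary(0.2), "b": self.summary(0.2)},
            inbreeding={"a": 0.05, "b": 0.12},
        )
        assert rep.inbreeding_ok is False

    def test_zero_baseline_reported_undefined(self):
        rep = cg.generational_trend({"a": self.summary(0.0), "b": self.summary(0.1)})
        assert rep.relative_change["Ho"]["b"] is None


def test_he_declines_at_drift_rate_in_simulation():
    """E[He_t] ~ He_0 * (1 - 1/(2Ne))^t for a random-mating flock of Ne ~ N."""
    import consgen as cg

    n, t, reps = 25, 8, 8
    ratios = []
    for rep in range(reps):
        cfg = cg.SimConfig(
            n_males=n // 2,
            n_females=n - n // 2,
            n_generations=t,
            scheme="RR",
            genome=cg.default_genome(1, 300),
            sample_generations=(0, t),
            sample_males=n // 2,
            sample_females=n - n // 2,
            seed=900 + rep,
        )
        res = cg.simulate_flock(cfg)
        he0 = cg.expected_heterozygosity(res.samples[0])
        het = cg.expected_heterozygosity(res.samples[t])
        ratios.append(het / he0)
    expected = (1 - 1 / (2 * n)) ** t
    assert np.mean(ratios) == pytest.approx(expected, abs=0.05)
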