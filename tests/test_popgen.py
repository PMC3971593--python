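"""Tajima's D against an independent constants oracle, the fixed-S
coalescent null, empirical p-values, BH and ancestral states."""

import math

import numpy as np
import pytest

import lcrflank as lf
from lcrflank.popgen import PopulationFragment, _sample_branch_sizes


def oracle_tajima(n: int, S: int, pi: float) -> float:
    """Independent evaluation of the constants formula."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i / i for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajima:
    def test_no_variation_undefined(self):
        assert math.isnan(lf.tajimas_d(PopulationFragment(10, 3, 0, 0.0)))

    def test_hand_worked_singleton(self):
        frag = PopulationFragment.from_derived_counts(4, 3, [1])
        assert frag.pi == pytest.approx(0.5)
        assert lf.tajimas_d(frag) == pytest.approx(-0.6123724356957968, abs=1e-9)

    def test_zero_numerator_gives_zero(self):
        n = 10
        a1 = sum(1.0 / i for i in range(1, n))
        assert lf.tajimas_d(PopulationFragment(n, 3, 2, 2 / a1)) == pytest.approx(0.0)

    def test_matches_oracle_everywhere(self, rng):
        for _ in range(100):
            n = int(rng.choice([4, 10, 178]))
            S = int(rng.integers(1, 6))
            pi = float(rng.uniform(0, S))
            frag = PopulationFragment(n, 3, S, pi)
            assert lf.tajimas_d(frag) == pytest.approx(
                oracle_tajima(n, S, pi), abs=1e-10
            )

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            lf.tajimas_d(PopulationFragment(3, 3, 1, 0.5))

    def test_from_sequences_skips_gapped_columns(self):
        frag = PopulationFragment.from_sequences(["A-G", "A-G", "T-G", "T-G"])
        assert frag.S == 1
        assert frag.pi == pytest.approx(4 / 6)


class TestFixedS:
    def test_exact_s_when_sites_suffice(self, rng):
        for S in (1, 2, 3):
            frag = lf.simulate_fixed_s_fragment(12, 3, S, rng)
            assert frag.S == S and frag.n == 12 and frag.L == 3

    def test_s_exceeding_sites_keeps_all_sites_polymorphic(self, rng):
        for _ in range(10):
            frag = lf.simulate_fixed_s_fragment(8, 3, 5, rng)
            assert frag.S == 3  # 5 mutation events on 3 sites, all segregating

    def test_seed_determinism(self):
        a = [lf.tajimas_d(lf.simulate_fixed_s_fragment(20, 3, 2, 123)) for _ in (0,)]
        b = [lf.tajimas_d(lf.simulate_fixed_s_fragment(20, 3, 2, 123)) for _ in (0,)]
        rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
        seq1 = [lf.tajimas_d(lf.simulate_fixed_s_fragment(20, 3, 2, rng1)) for _ in range(50)]
        seq2 = [lf.tajimas_d(lf.simulate_fixed_s_fragment(20, 3, 2, rng2)) for _ in range(50)]
        assert a == b and seq1 == seq2

    def test_null_mean_near_zero_large_sample(self, rng):
        ds = [
            lf.tajimas_d(lf.simulate_fixed_s_fragment(178, 3, 2, rng))
            for _ in range(3000)
        ]
        assert abs(np.mean(ds)) < 0.1

    def test_total_branch_length_matches_coalescent_expectation(self, rng):
        # E[total length] = 2 * sum_{i<n} 1/i on the coalescent time scale
        n = 20
        expected = 2 * sum(1.0 / i for i in range(1, n))
        totals = [_sample_branch_sizes(n, rng)[1].sum() for _ in range(2000)]
        assert np.mean(totals) == pytest.approx(expected, rel=0.05)


class TestEmpiricalP:
    def test_extreme_observation_add_one_bound(self):
        draws = np.linspace(0.0, 1.0, 1999)
        assert lf.empirical_pvalue(-5.0, draws) == pytest.approx(1 / 2000)

    def test_median_observation(self):
        draws = np.linspace(-1.0, 1.0, 2001)
        p = lf.empirical_pvalue(1e-9, draws, tail="upper")
        assert p == pytest.approx(0.5, abs=0.01)

    def test_undefined_statistic_rejected(self):
        with pytest.raises(ValueError):
            lf.empirical_pvalue(float("nan"), np.zeros(2000))

    def test_randomised_ties_uniform(self, rng):
        """p-values of null draws against their own (discrete) distribution
        are uniform once ties are randomised."""
        null = rng.integers(0, 5, size=5000).astype(float)  # very discrete
        fresh = rng.integers(0, 5, size=2000).astype(float)
        ps = [lf.empirical_pvalue(x, null, tail="lower", rng=rng) for x in fresh]
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBH:
    def test_step_up_worked_example(self):
        flags = lf.bh_fdr([0.01, 0.02, 0.04, 0.5], alpha=0.05)
        assert list(flags) == [True, True, False, False]

    def test_all_ones_no_rejections(self):
        assert not lf.bh_fdr([1.0] * 5).any()

    def test_single_p_reduces_to_alpha(self):
        assert lf.bh_fdr([0.04], alpha=0.05)[0]

    def test_empty_and_invalid(self):
        assert len(lf.bh_fdr([])) == 0
        with pytest.raises(ValueError):
            lf.bh_fdr([0.0, 0.5])


class TestAncestralState:
    def mk(self, chimp, macaque, alleles=("A", "G")):
        return lf.SnpRecord(0, 10, alleles, {alleles[0]: 0.7, alleles[1]: 0.3},
                            chimp, macaque)

    def test_unanimous_outgroups(self):
        assert lf.ancestral_state(self.mk("A", "A")) == "A"

    def test_conflicting_outgroups_both_segregating(self):
        assert lf.ancestral_state(self.mk("A", "G")) is None

    def test_one_matching_one_foreign(self):
        assert lf.ancestral_state(self.mk("A", "C")) == "A"
        assert lf.ancestral_state(self.mk("C", "G")) == "G"

    def test_missing_outgroup_unresolved(self):
        assert lf.ancestral_state(self.mk(None, "A")) is None

    def test_agreeing_but_foreign_unresolved(self):
        assert lf.ancestral_state(self.mk("C", "C")) is None

    def test_derived_frequency(self):
        snp = self.mk("A", "A")
        snp.ancestral = lf.ancestral_state(snp)
        assert snp.derived_frequency == pytest.approx(0.3)


class TestDerivedFreqVsDistance:
    def mk_snps(self, dists, freqs):
        out = []
        for d, f in zip(dists, freqs):
            snp = lf.SnpRecord(d, d, ("A", "G"), {"A": 1 - f, "G": f}, "A", "A")
            snp.ancestral = "A"
            out.append(snp)
        return out

    def test_monotone_gives_rho_one(self):
        snps = self.mk_snps(range(1, 13), [i / 20 for i in range(1, 13)])
        rho, p = lf.derived_freq_vs_distance(snps)
        assert rho == pytest.approx(1.0)

    def test_duplicated_pairs_do_not_change_rho(self):
        snps = self.mk_snps(range(1, 13), [i / 20 for i in range(1, 13)])
        rho1, _ = lf.derived_freq_vs_distance(snps)
        rho2, _ = lf.derived_freq_vs_distance(snps + snps)
        assert rho1 == pytest.approx(rho2)

    def test_too_few_or_degenerate(self):
        with pytest.raises(ValueError):
            lf.derived_freq_vs_distance(self.mk_snps([1, 2], [0.1, 0.2]))
        with pytest.raises(ValueError):
            lf.derived_freq_vs_distance(self.mk_snps([5] * 12, np.linspace(0.1, 0.9, 12)))
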