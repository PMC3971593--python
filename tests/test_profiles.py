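"""Distance profiles, gap profiles, and correlation reports."""

import math

import numpy as np
import pandas as pd
import pytest

import lcrflank as lf
from lcrflank.flanks import FlankColumn, FlankingRegion


def site_row(gene, side, d, usable=True, gapped=False, k=0.0, call="not_assessable"):
    sign = -1 if side == "upstream" else 1
    return {
        "gene_id": gene, "side": side, "codon_distance": d,
        "signed_distance": sign * d, "usable": usable, "gapped": gapped,
        "k_total": k, "k_syn": k, "k_nonsyn": 0.0, "omega": float("nan"),
        "selection_call": call,
    }


def make_flank(gene, side, n_codons, gapped_at=()):
    cols = [
        FlankColumn(100 + d, d, {"human": None if d in gapped_at else "ATG"})
        for d in range(1, n_codons + 1)
    ]
    return FlankingRegion(gene, side, 100, 100 + n_codons, cols)


class TestAggregate:
    def test_mean_and_n(self):
        table = pd.DataFrame([
            site_row("g1", "downstream", 1, k=1.0),
            site_row("g2", "downstream", 1, k=0.0),
        ])
        prof = lf.aggregate_by_distance(table, "k_total")
        assert prof.loc[0, "mean"] == 0.5 and prof.loc[0, "n"] == 2

    def test_gapped_site_excluded_per_distance(self):
        rows = [site_row("g1", "downstream", d, k=1.0) for d in (1, 2, 3)]
        rows += [site_row("g2", "downstream", d, k=0.0) for d in (1, 2)]
        rows += [site_row("g2", "downstream", 3, usable=False, gapped=True)]
        prof = lf.aggregate_by_distance(pd.DataFrame(rows), "k_total")
        assert list(prof["n"]) == [2, 2, 1]
        assert prof.loc[2, "mean"] == 1.0

    def test_selection_proportion_uses_assessable_denominator(self):
        rows = [
            site_row("g1", "downstream", 2, call="negative"),
            site_row("g2", "downstream", 2, call="neutral"),
            site_row("g3", "downstream", 2, call="neutral"),
            site_row("g4", "downstream", 2, call="neutral"),
            site_row("g5", "downstream", 2, call="not_assessable"),
        ]
        prof = lf.aggregate_by_distance(pd.DataFrame(rows), "prop_negative")
        assert prof.loc[0, "mean"] == pytest.approx(0.25)
        assert prof.loc[0, "n"] == 4

    def test_upstream_distances_negated(self):
        table = pd.DataFrame([site_row("g1", "upstream", 3, k=1.0)])
        prof = lf.aggregate_by_distance(table, "k_total")
        assert list(prof["distance"]) == [-3]

    def test_empty_input(self):
        assert lf.aggregate_by_distance(pd.DataFrame(), "k_total").empty

    def test_gene_order_invariance(self):
        rows = [site_row(f"g{i}", "downstream", 1 + i % 3, k=float(i % 2)) for i in range(12)]
        a = lf.aggregate_by_distance(pd.DataFrame(rows), "k_total")
        b = lf.aggregate_by_distance(pd.DataFrame(rows[::-1]), "k_total")
        pd.testing.assert_frame_equal(a, b)


class TestGapProfile:
    def test_flat_zero_when_no_gaps(self):
        prof = lf.gap_profile([make_flank("g1", "downstream", 10)])
        assert (prof["mean"] == 0.0).all()
        assert len(prof) == 30

    def test_one_of_three_genes_gapped(self):
        flanks = [
            make_flank("g1", "downstream", 5),
            make_flank("g2", "downstream", 5),
            make_flank("g3", "downstream", 5, gapped_at=(4,)),
        ]
        prof = lf.gap_profile(flanks).set_index("distance")
        assert prof.loc[10, "mean"] == pytest.approx(1 / 3)  # nt 10 = codon 4
        assert prof.loc[10, "n"] == 3
        assert prof.loc[1, "mean"] == 0.0

    def test_short_flank_limits_denominator(self):
        flanks = [make_flank("g1", "downstream", 50), make_flank("g2", "downstream", 60)]
        prof = lf.gap_profile(flanks).set_index("distance")
        assert prof.loc[150, "n"] == 2
        assert prof.loc[151, "n"] == 1


class TestPearson:
    def test_perfect_positive_and_negative(self):
        up = pd.DataFrame({"distance": [1, 2, 3], "mean": [2, 4, 6], "n": [5, 5, 5]})
        down = pd.DataFrame({"distance": [1, 2, 3], "mean": [6, 4, 2], "n": [5, 5, 5]})
        assert lf.pearson_with_p(up).r == pytest.approx(1.0)
        assert lf.pearson_with_p(down).r == pytest.approx(-1.0)

    def test_pooled_sides_use_absolute_distance(self):
        prof = pd.DataFrame({
            "distance": [-3, -2, -1, 1, 2, 3],
            "mean": [2.0, 4.0, 6.0, 6.0, 4.0, 2.0],
            "n": [5] * 6,
        })
        assert lf.pearson_with_p(prof).r == pytest.approx(-1.0)
        assert lf.pearson_with_p(prof, side="upstream").n_points == 3

    def test_degenerate_inputs_rejected(self):
        flat = pd.DataFrame({"distance": [1, 2, 3], "mean": [1.0, 1.0, 1.0], "n": [1] * 3})
        with pytest.raises(ValueError):
            lf.pearson_with_p(flat)
        with pytest.raises(ValueError):
            lf.pearson_with_p(flat.iloc[:2])

    def test_permuted_profiles_give_uniform_p(self, rng):
        ps = []
        for _ in range(200):
            prof = pd.DataFrame({
                "distance": np.arange(1, 31),
                "mean": rng.permutation(30).astype(float),
                "n": np.ones(30, dtype=int),
            })
            ps.append(lf.pearson_with_p(prof).p)
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestComposition:
    @staticmethod
    def comp_frame(rng, copy_lcr=False):
        rows = []
        for g in range(15):
            for b in "ACGT":
                flank = rng.uniform(0.1, 0.4)
                lcr = flank if copy_lcr else rng.uniform(0.1, 0.4)
                rows.append((f"g{g}", b, lcr, flank, rng.uniform(0.1, 0.4)))
        return pd.DataFrame(rows, columns=["gene_id", "base", "lcr_freq", "flank_freq", "cds_freq"])

    def test_copied_frequencies_give_r_one(self, rng):
        out = lf.composition_correlation(self.comp_frame(rng, copy_lcr=True))
        lcr_rows = out[out["comparison"] == "flank_vs_lcr"]
        assert np.allclose(lcr_rows["r"], 1.0)

    def test_independent_frequencies_give_small_r(self, rng):
        out = lf.composition_correlation(self.comp_frame(rng))
        assert (out["r"].abs() < 0.8).all()

    def test_too_few_genes(self, rng):
        with pytest.raises(ValueError):
            lf.composition_correlation(self.comp_frame(rng).head(8))


class TestNoGapRobustness:
    def test_identical_when_no_gaps(self, rng):
        rows = []
        for g in range(6):
            for d in range(1, 25):
                rows.append(site_row(f"g{g}", "downstream", d, k=float(rng.poisson(0.3 + 2 / d))))
        table = pd.DataFrame(rows)
        full = lf.pearson_with_p(lf.aggregate_by_distance(table, "k_total"), "k_total")
        clean = lf.no_gap_robustness(table)
        assert clean.r == pytest.approx(full.r)

    def test_all_flanks_gapped_not_computed(self):
        rows = [site_row("g1", "downstream", d, gapped=(d == 2)) for d in (1, 2, 3)]
        with pytest.raises(ValueError):
            lf.no_gap_robustness(pd.DataFrame(rows))
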