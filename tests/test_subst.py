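"""Parsimony counting, syn/nonsyn partitioning, site omega and the neutral
null: worked examples, the exhaustive-enumeration oracle, and the
count-partition identity."""

import itertools
import math

import numpy as np
import pytest

import lcrflank as lf
from lcrflank import codes
from lcrflank.subst import NeutralNull, simulate_neutral_column

from conftest import SPECIES, column_states


def exhaustive_parsimony(states: dict, tree: lf.SpeciesTree) -> int:
    """Independent oracle: minimum mismatching-edge count over all labelings
    of the three internal nodes of the unrooted 5-taxon topology
    (((H,C),G),O,M) — written directly from the topology, no Fitch."""
    best = math.inf
    for hc, hcg, root in itertools.product("ACGT", repeat=3):
        cost = (
            (states["human"] != hc)
            + (states["chimpanzee"] != hc)
            + (hc != hcg)
            + (states["gorilla"] != hcg)
            + (hcg != root)
            + (states["orangutan"] != root)
            + (states["macaque"] != root)
        )
        best = min(best, cost)
    return best


def make_column(codons_by_species: dict, distance: int = 1) -> lf.CodonColumn:
    return lf.CodonColumn("g", "downstream", distance, codons_by_species)


@pytest.mark.parametrize(
    "bases,expected",
    [("AAAAA", 0), ("AAAAG", 1), ("ATATA", 2), ("ACGTA", 3), ("AATTA", 2)],
)
def test_fitch_worked_examples(tree, bases, expected):
    assert lf.fitch_count(column_states(bases), tree) == expected
    assert exhaustive_parsimony(column_states(bases), tree) == expected


def test_fitch_matches_exhaustive_oracle(tree, rng):
    for _ in range(300):
        bases = "".join("ACGT"[i] for i in rng.integers(4, size=5))
        states = column_states(bases)
        assert lf.fitch_count(states, tree) == exhaustive_parsimony(states, tree)


def test_fitch_iupac_and_errors(tree):
    states = column_states("AAAAA")
    states["macaque"] = "R"  # {A,G} includes A: no change required
    assert lf.fitch_count(states, tree) == 0
    with pytest.raises(ValueError):
        lf.fitch_count(column_states("AAAAZ"), tree)
    with pytest.raises(ValueError):
        lf.fitch_count({"human": "A"}, tree)


class TestPartition:
    def test_synonymous_single_change(self, tree):
        col = make_column({sp: ("TTA" if sp == "human" else "TTG") for sp in SPECIES})
        assert lf.partition_syn_nonsyn(col, tree) == (1.0, 0.0, False)

    def test_nonsynonymous_single_change(self, tree):
        col = make_column({sp: ("TCA" if sp == "human" else "TTA") for sp in SPECIES})
        assert lf.partition_syn_nonsyn(col, tree) == (0.0, 1.0, False)

    def test_identical_codons(self, tree):
        col = make_column({sp: "ATG" for sp in SPECIES})
        assert lf.partition_syn_nonsyn(col, tree) == (0.0, 0.0, False)

    def test_gapped_column_rejected(self, tree):
        col = make_column({sp: ("ATG" if sp != "human" else None) for sp in SPECIES})
        assert not col.usable
        with pytest.raises(ValueError):
            lf.partition_syn_nonsyn(col, tree)

    def test_partition_sums_to_parsimony_count(self, tree, rng):
        """k_syn + k_nonsyn equals the nucleotide parsimony count on columns
        spanning the whole range of divergence (neutral sim at an inflated
        scale plus fully random columns)."""
        big = tree.scaled(12.0)
        for i in range(120):
            if i % 2 == 0:
                codons = simulate_neutral_column(big, 2.0, rng)
            else:
                codons = {
                    sp: codes.SENSE_CODONS[rng.integers(61)] for sp in SPECIES
                }
            col = make_column(codons)
            est = lf.site_omega(col, tree)
            assert est.k_syn + est.k_nonsyn == pytest.approx(est.k_total, abs=1e-9)


class TestSiteOmega:
    def test_synonymous_only_gives_zero(self, tree):
        col = make_column({sp: ("TTA" if sp == "human" else "TTG") for sp in SPECIES})
        assert lf.site_omega(col, tree).omega == 0.0

    def test_no_substitutions_undefined(self, tree):
        est = lf.site_omega(make_column({sp: "ATG" for sp in SPECIES}), tree)
        assert est.k_total == 0 and math.isnan(est.omega)
        assert est.selection_call == "not_assessable"

    def test_nonsynonymous_only_gives_large_sentinel(self, tree):
        col = make_column({sp: ("TCA" if sp == "human" else "TTA") for sp in SPECIES})
        assert lf.site_omega(col, tree).omega == math.inf

    def test_ng_site_opportunities_sum_to_three(self):
        for codon in codes.SENSE_CODONS:
            s, n = codes.ng_site_opportunities(codon)
            assert s + n == pytest.approx(3.0)
            assert 0.0 <= s <= 3.0


class TestNeutralNull:
    def test_determinism_under_seed(self, tree):
        kwargs = dict(n_draws=3000, kappa=2.0, seed=5, min_draws=200)
        a = lf.simulate_neutral_null(tree, **kwargs)
        b = lf.simulate_neutral_null(tree, **kwargs)
        assert sorted(a.omega_by_k) == sorted(b.omega_by_k)
        for k in a.omega_by_k:
            assert np.array_equal(a.omega_by_k[k], b.omega_by_k[k])

    def test_zero_substitution_bin_absent(self, tree):
        null = lf.simulate_neutral_null(tree, n_draws=3000, seed=5, min_draws=200)
        assert 0 not in null.omega_by_k

    def test_cutoffs_monotone_in_alpha(self, tree):
        null = lf.simulate_neutral_null(tree, n_draws=6000, seed=5, min_draws=200)
        k = max(k for k in null.omega_by_k if len(null.omega_by_k[k]) >= 200)
        lo1, hi1 = null.cutoffs(k, alpha=0.01)
        lo5, hi5 = null.cutoffs(k, alpha=0.10)
        assert lo1 <= lo5 and hi5 <= hi1


class TestClassify:
    @staticmethod
    def continuous_null() -> NeutralNull:
        return NeutralNull(
            omega_by_k={1: np.linspace(0.01, 2.0, 2000)}, alpha=0.05, min_draws=100
        )

    def test_lower_tail_negative(self):
        assert lf.classify_selection(0.005, 1, self.continuous_null()) == "negative"

    def test_omega_one_always_neutral(self):
        null = NeutralNull(omega_by_k={1: np.full(2000, 1.0)}, min_draws=100)
        assert lf.classify_selection(1.0, 1, null) == "neutral"

    def test_upper_tail_positive(self):
        assert lf.classify_selection(5.0, 1, self.continuous_null()) == "positive"

    def test_bulk_is_neutral(self):
        assert lf.classify_selection(1.2, 1, self.continuous_null()) == "neutral"

    def test_unsupported_k_not_assessable(self):
        assert lf.classify_selection(0.0, 7, self.continuous_null()) == "not_assessable"

    def test_randomised_boundary_atom_flags_at_rate(self):
        """With an atom holding 25% of the null mass at omega=0, the exact
        test must flag it with probability 0.025/0.25 = 0.1."""
        vals = np.sort(np.concatenate([np.zeros(500), np.linspace(1.5, 3, 1500)]))
        null = NeutralNull(omega_by_k={1: vals}, min_draws=100)
        rng = np.random.default_rng(0)
        flags = [
            lf.classify_selection(0.0, 1, null, rng=rng) == "negative"
            for _ in range(4000)
        ]
        rate = np.mean(flags)
        assert abs(rate - 0.1) < 3 * math.sqrt(0.1 * 0.9 / 4000)
        # without an rng the conservative call never flags the atom
        assert lf.classify_selection(0.0, 1, null) == "neutral"


class TestPairwise:
    def test_identical(self):
        assert lf.pairwise_mean_substitutions(["ATG"] * 4) == (0.0, 0.0, 0.0)

    def test_one_synonymous_singleton_among_four(self):
        tot, syn, non = lf.pairwise_mean_substitutions(["TTA", "TTA", "TTA", "TTG"])
        assert (tot, syn, non) == (0.5, 0.5, 0.0)

    def test_balanced_nonsynonymous_alleles(self):
        tot, syn, non = lf.pairwise_mean_substitutions(["TCA", "TCA", "TTA", "TTA"])
        assert tot == pytest.approx(4 / 6)
        assert non == pytest.approx(4 / 6)
        assert syn == 0.0

    def test_counts_path_matches_list_path(self, rng):
        from collections import Counter

        from lcrflank.pipeline import pairwise_mean_from_counts

        for _ in range(20):
            codons = [codes.SENSE_CODONS[i] for i in rng.integers(61, size=8)]
            assert pairwise_mean_from_counts(Counter(codons)) == pytest.approx(
                lf.pairwise_mean_substitutions(codons)
            )

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            lf.pairwise_mean_substitutions(["ATG"])


def test_generator_omega_orders_nonsynonymous_fraction(tree):
    """Simulating with acceptance omega 0.2 / 1 / 5 must yield strictly
    increasing nonsynonymous fractions of the parsimony count."""
    fractions = []
    for om in (0.2, 1.0, 5.0):
        cfg = lf.SimConfig(seed=3, n_genes=3, flank_codons=60, omega=om)
        ds = lf.simulate_dataset(cfg)
        tot = non = 0.0
        for gene in ds.genes:
            for col_idx in range(gene.n_columns):
                codons = {sp: gene.codon_alignment[sp][col_idx] for sp in SPECIES}
                col = lf.CodonColumn(gene.gene_id, "downstream", 1, codons)
                if not col.usable:
                    continue
                est = lf.site_omega(col, tree)
                tot += est.k_total
                non += est.k_nonsyn
        fractions.append(non / tot)
    assert fractions[0] < fractions[1] < fractions[2]
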