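import numpy as np
import pytest

import lcrflank as lf
from lcrflank.pipeline import collect_flanks

SPECIES = ["human", "chimpanzee", "gorilla", "orangutan", "macaque"]

#: one representative codon per amino acid, for reverse translation in toys
AA_TO_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def reverse_translate(protein: str) -> str:
    return "".join(AA_TO_CODON[a] for a in protein)


def make_group(protein: str, gene_id: str = "toy") -> lf.OrthologGroup:
    """An ortholog group with the same gapless protein in all five species."""
    cds = reverse_translate(protein)
    return lf.OrthologGroup(
        gene_id,
        {sp: cds for sp in SPECIES},
        {sp: lf.ProteinRecord(f"{gene_id}|{sp}", protein) for sp in SPECIES},
        {sp: protein for sp in SPECIES},
    )


def column_states(bases: str) -> dict:
    """Map the five species (human, chimp, gorilla, orangutan, macaque order)
    to single-nucleotide states."""
    return dict(zip(SPECIES, bases))


@pytest.fixture(scope="session")
def tree() -> lf.SpeciesTree:
    return lf.SpeciesTree.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_dataset() -> lf.SimConfig:
    cfg = lf.SimConfig(seed=11, n_genes=12, flank_codons=60)
    return lf.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_flanks(small_dataset):
    params = lf.FlankParams(min_flank_nt=150)
    return collect_flanks(small_dataset, flank_params=params)
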