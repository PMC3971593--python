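"""Standard genetic code helpers: translation, synonymous/nonsynonymous
classification, Nei–Gojobori site opportunities and pathway averaging.

All routines use the standard (NCBI table 1) code and treat the three stop
codons as forbidden states for evolutionary paths unless explicitly allowed.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid (one letter), stop codons excluded
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: the 61 sense codons of the standard code, sorted
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; '*' for a stop codon."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA[codon]


def is_transition(a: str, b: str) -> bool:
    """True when the single-nucleotide change a->b is a transition."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def is_synonymous(codon_a: str, codon_b: str) -> bool:
    """True when two sense codons encode the same amino acid."""
    return translate_codon(codon_a) == translate_codon(codon_b)


def codon_neighbors(codon: str, include_stops: bool = False) -> list[str]:
    """All codons reachable by a single nucleotide change."""
    out = []
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if include_stops or alt not in STOP_CODONS:
                out.append(alt)
    return out


@lru_cache(maxsize=None)
def ng_site_opportunities(codon: str) -> tuple[float, float]:
    """Nei–Gojobori synonymous/nonsynonymous site counts for one codon.

    Equal mutation rates across the three alternative bases at each
    position; changes creating stop codons are excluded and the remaining
    fractions renormalised, so s + n = 3 for every sense codon.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon has no site opportunities: {codon}")
    syn_sites = 0.0
    for pos in range(3):
        alts = []
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in STOP_CODONS:
                alts.append(alt)
        if alts:
            syn_sites += sum(is_synonymous(codon, a) for a in alts) / len(alts)
    return syn_sites, 3.0 - syn_sites


def _diff_positions(codon_a: str, codon_b: str) -> list[int]:
    return [i for i in range(3) if codon_a[i] != codon_b[i]]


@lru_cache(maxsize=None)
def pathway_syn_nonsyn(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    """Split the changes between two sense codons into synonymous and
    nonsynonymous steps, averaged over mutational pathways.

    For codons differing at m positions, every ordering of the m
    single-nucleotide steps is enumerated; orderings passing through a stop
    codon are discarded. Each surviving pathway contributes one syn/nonsyn
    classification per step, and the mean over pathways is returned.

    Returns ``(k_syn, k_nonsyn, through_stop)`` with k_syn + k_nonsyn = m.
    ``through_stop`` is True when every ordering transits a stop codon, in
    which case all orderings (stops included) are averaged instead of
    returning nothing.
    """
    positions = _diff_positions(codon_a, codon_b)
    m = len(positions)
    if m == 0:
        return 0.0, 0.0, False
    valid: list[tuple[float, float]] = []
    all_paths: list[tuple[float, float]] = []
    for order in itertools.permutations(positions):
        current = codon_a
        syn = nonsyn = 0.0
        hit_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS or current in STOP_CODONS:
                hit_stop = True
            if translate_codon(current) == translate_codon(nxt):
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        all_paths.append((syn, nonsyn))
        if not hit_stop:
            valid.append((syn, nonsyn))
    pool = valid if valid else all_paths
    k_syn = sum(p[0] for p in pool) / len(pool)
    k_nonsyn = sum(p[1] for p in pool) / len(pool)
    return k_syn, k_nonsyn, not valid


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS (no gaps); trailing stop codon is dropped."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        aa = translate_codon(codon)
        if aa == "*":
            if i == len(cds) - 3:
                break
            raise ValueError(f"internal stop codon at nt {i}")
        aas.append(aa)
    return "".join(aas)
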