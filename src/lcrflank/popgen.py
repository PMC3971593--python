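"""Population-genetic statistics on the human sample: per-codon Tajima's D
with a fixed-S coalescent null, empirical tail p-values, Benjamini–Hochberg
FDR control, and outgroup-parsimony ancestral states for SNPs.

Tajima's D contrasts mean pairwise diversity (pi) with the Watterson
estimator S/a1.  Its null distribution depends on the genealogy and on the
number of segregating sites, so significance is assessed against neutral
coalescent fragments simulated with the same sample size, length and S:
a Kingman genealogy of n lineages is drawn, and exactly S mutations are
placed on branches with probability proportional to branch length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclass
class PopulationFragment:
    """A short alignment of n population sequences (e.g. one codon).

    ``pi`` is the mean number of pairwise differences and ``S`` the number
    of segregating sites, both computed over columns with no gap or
    ambiguous character.
    """

    n: int
    L: int
    S: int
    pi: float

    @classmethod
    def from_sequences(cls, sequences: list) -> "PopulationFragment":
        n = len(sequences)
        if n < 2:
            raise ValueError("need at least two sequences")
        L = len(sequences[0])
        if any(len(s) != L for s in sequences):
            raise ValueError("sequences differ in length")
        S = 0
        pi_sum = 0.0
        pairs = n * (n - 1) / 2
        for j in range(L):
            col = [s[j] for s in sequences]
            if any(c not in "ACGT01" for c in col):
                continue  # gapped/ambiguous column: excluded from S and pi
            counts: dict = {}
            for c in col:
                counts[c] = counts.get(c, 0) + 1
            if len(counts) > 1:
                S += 1
                same = sum(v * (v - 1) / 2 for v in counts.values())
                pi_sum += (pairs - same) / pairs
        return cls(n=n, L=L, S=S, pi=pi_sum)

    @classmethod
    def from_derived_counts(cls, n: int, L: int, derived_counts: list) -> "PopulationFragment":
        """Fragment summarised by per-site derived-allele counts (infinite
        sites; count 0 or n means the site is monomorphic)."""
        pairs = n * (n - 1) / 2
        S = 0
        pi_sum = 0.0
        for i in derived_counts:
            if 0 < i < n:
                S += 1
                pi_sum += i * (n - i) / pairs
        return cls(n=n, L=L, S=S, pi=pi_sum)


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(fragment: PopulationFragment) -> float:
    """Tajima's D for one fragment; NaN when S = 0 (no variation)."""
    n, S, pi = fragment.n, fragment.S, fragment.pi
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4 sequences")
    if S == 0:
        return float("nan")
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    return (pi - S / a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# Fixed-S coalescent null
# ---------------------------------------------------------------------------

def _pick_pair(k: int, rng: np.random.Generator) -> tuple[int, int]:
    i = int(rng.integers(k))
    j = int(rng.integers(k - 1))
    if j >= i:
        j += 1
    return (i, j) if i < j else (j, i)


def _sample_branch_sizes(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One Kingman genealogy of n lineages, summarised per branch.

    Returns (sizes, lengths): for every branch of the genealogy, the number
    of leaves below it and its length on the standard coalescent time scale
    (only the subtended leaf count matters for placing infinite-site
    mutations, so leaf identities are not tracked).
    """
    ks = np.arange(n, 1, -1)
    durations = rng.exponential(2.0 / (ks * (ks - 1)))
    cum = np.concatenate([[0.0], np.cumsum(durations)])
    lineages = [(1, 0) for _ in range(n)]  # (size, born-at-event-index)
    sizes: list = []
    lengths: list = []
    for e in range(n - 1):
        k = n - e
        i, j = _pick_pair(k, rng)
        si, bi = lineages[i]
        sj, bj = lineages[j]
        sizes.extend([si, sj])
        lengths.extend([cum[e + 1] - cum[bi], cum[e + 1] - cum[bj]])
        lineages = [lineages[m] for m in range(k) if m not in (i, j)]
        lineages.append((si + sj, e + 1))
    return np.asarray(sizes), np.asarray(lengths)


def _sample_branch_leafsets(n: int, rng: np.random.Generator) -> tuple[list, np.ndarray]:
    """As :func:`_sample_branch_sizes` but with explicit leaf sets, needed
    only when mutations must be assigned to recurrent sites (S > L)."""
    ks = np.arange(n, 1, -1)
    durations = rng.exponential(2.0 / (ks * (ks - 1)))
    cum = np.concatenate([[0.0], np.cumsum(durations)])
    lineages = [(frozenset([m]), 0) for m in range(n)]
    leafsets: list = []
    lengths: list = []
    for e in range(n - 1):
        k = n - e
        i, j = _pick_pair(k, rng)
        si, bi = lineages[i]
        sj, bj = lineages[j]
        leafsets.extend([si, sj])
        lengths.extend([cum[e + 1] - cum[bi], cum[e + 1] - cum[bj]])
        lineages = [lineages[m] for m in range(k) if m not in (i, j)]
        lineages.append((si | sj, e + 1))
    return leafsets, np.asarray(lengths)


def simulate_fixed_s_fragment(
    n: int, L: int, S: int, seed: int | np.random.Generator
) -> PopulationFragment:
    """A neutral fragment conditioned on exactly S segregating sites.

    S mutations are placed on branches with probability proportional to
    branch length.  For S <= L each mutation takes a distinct site
    (infinite sites), so the realised segregating-site count equals the
    target by construction.  An observed fragment can never show more
    segregating sites than it has sites, so S > L only makes sense as "S
    mutation events on L sites": sites are then reused and recurrent hits
    can cancel, and the draw is rejected and resampled until all L sites
    are left polymorphic (the fragment's realised S is L).
    """
    if n < 4 or S < 1:
        raise ValueError("need n >= 4 and S >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if S <= L:
        sizes, lengths = _sample_branch_sizes(n, rng)
        probs = lengths / lengths.sum()
        picks = rng.choice(len(sizes), size=S, p=probs)
        return PopulationFragment.from_derived_counts(n, L, sizes[picks])
    while True:
        leafsets, lengths = _sample_branch_leafsets(n, rng)
        probs = lengths / lengths.sum()
        picks = rng.choice(len(leafsets), size=S, p=probs)
        sites = rng.integers(0, L, size=S)
        matrix = np.zeros((n, L), dtype=np.int8)
        for b, s in zip(picks, sites):
            idx = list(leafsets[b])
            matrix[idx, s] ^= 1  # recurrent mutation flips carriers back
        counts_per_site = matrix.sum(axis=0)
        realized = int(np.sum((counts_per_site > 0) & (counts_per_site < n)))
        if realized != L:
            continue
        pairs = n * (n - 1) / 2
        pi = float(sum(i * (n - i) / pairs for i in counts_per_site if 0 < i < n))
        return PopulationFragment(n=n, L=L, S=realized, pi=pi)


class FixedSNull:
    """Cache of fixed-S Tajima's D null draws keyed by (n, L, S)."""

    def __init__(self, n_draws: int = 10_000, seed: int = 0):
        if n_draws < 1000:
            raise ValueError("n_draws must be >= 1000")
        self.n_draws = n_draws
        self.seed = seed
        self._cache: dict = {}

    def draws(self, n: int, L: int, S: int) -> np.ndarray:
        key = (n, L, S)
        if key not in self._cache:
            rng = np.random.default_rng((self.seed, n, L, S))
            ds = np.array([
                tajimas_d(simulate_fixed_s_fragment(n, L, S, rng))
                for _ in range(self.n_draws)
            ])
            self._cache[key] = np.sort(ds)
        return self._cache[key]


def empirical_pvalue(
    d_obs: float,
    null_draws: np.ndarray,
    tail: str = "auto",
    rng: np.random.Generator | None = None,
) -> float:
    """Add-one empirical tail probability of an observed statistic.

    ``tail`` is "lower", "upper", or "auto" (the tail matching the sign of
    the observation; zero goes to the lower tail).  With an ``rng``, ties
    with null draws are broken uniformly, which makes the p-value of a null
    draw against its own distribution exactly uniform even when the null is
    discrete; without one the deterministic (super-uniform, conservative)
    count of as-or-more-extreme draws is used.
    """
    if math.isnan(d_obs):
        raise ValueError("cannot compute a p-value for an undefined statistic")
    arr = np.asarray(null_draws)
    n = len(arr)
    if n < 1000:
        raise ValueError("need at least 1000 null draws")
    if tail == "auto":
        tail = "upper" if d_obs > 0 else "lower"
    if tail == "lower":
        strict = int(np.sum(arr < d_obs))
        ties = int(np.sum(arr == d_obs))
    elif tail == "upper":
        strict = int(np.sum(arr > d_obs))
        ties = int(np.sum(arr == d_obs))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    if rng is None:
        return (1 + strict + ties) / (1 + n)
    return (strict + rng.random() * (ties + 1)) / (1 + n)


def bh_fdr(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at FDR level alpha."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


# ---------------------------------------------------------------------------
# SNP ancestral states
# ---------------------------------------------------------------------------

@dataclass
class SnpRecord:
    """A biallelic SNP with outgroup bases for ancestral-state inference."""

    position: int
    distance_to_lcr: int  # nucleotides
    alleles: tuple  # (ref-like, alt-like); order carries no meaning
    frequencies: dict  # allele -> sample fraction; sums to 1
    chimp_base: str | None = None
    macaque_base: str | None = None
    ancestral: str | None = field(default=None)

    @property
    def derived_frequency(self) -> float:
        if self.ancestral is None:
            return float("nan")
        derived = [a for a in self.alleles if a != self.ancestral]
        if len(derived) != 1:
            return float("nan")
        return self.frequencies[derived[0]]


def ancestral_state(snp: SnpRecord) -> str | None:
    """Maximum-parsimony ancestral allele from chimp and macaque bases.

    Agreeing outgroups matching one segregating allele resolve to that
    allele.  Disagreeing outgroups resolve only when exactly one of them
    matches a segregating allele (the other matching neither); any other
    configuration, or a missing outgroup, is unresolved (None).
    """
    c, m = snp.chimp_base, snp.macaque_base
    alleles = set(snp.alleles)
    if c is None or m is None:
        return None
    if c == m:
        return c if c in alleles else None
    c_in, m_in = c in alleles, m in alleles
    if c_in and not m_in:
        return c
    if m_in and not c_in:
        return m
    return None


def resolve_ancestral(snps: list) -> list:
    """Fill the ``ancestral`` field of each SNP in place; returns the list."""
    for snp in snps:
        snp.ancestral = ancestral_state(snp)
    return snps


def derived_freq_vs_distance(snps: list) -> tuple[float, float]:
    """Spearman rank correlation of derived-allele frequency against
    nucleotide distance from the LCR, over SNPs with resolved ancestry."""
    resolved = [s for s in snps if s.ancestral is not None and not math.isnan(s.derived_frequency)]
    if len(resolved) < 10:
        raise ValueError("need at least 10 SNPs with resolved ancestral states")
    dist = [s.distance_to_lcr for s in resolved]
    freq = [s.derived_frequency for s in resolved]
    if len(set(dist)) < 2:
        raise ValueError("all distances identical; correlation undefined")
    rho, p = stats.spearmanr(dist, freq)
    return float(rho), float(p)
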