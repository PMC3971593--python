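"""Synthetic data generator: five-primate ortholog families with embedded
low-complexity repeat tracts, and human-like population samples.

Every pipeline input is generated with the statistical structure the
analysis is designed to detect:

* a root CDS carrying a repeat tract (e.g. CAG x 20, a poly-Q LCR) between
  two flanks of random sense codons;
* point substitutions proposed down the species tree at rate
  mu * m(d) per codon per unit branch length, where
  m(d) = 1 + a * exp(-d / lambda) is a distance-decaying elevation with
  amplitude ``a`` and length scale ``lambda`` (codons), side-specific;
  nonsynonymous proposals are accepted with probability min(1, omega) and
  synonymous with min(1, 1/omega), giving tunable site-level selection;
* whole-codon deletions at an independently decaying rate (frame
  preserved, so the true alignment is known by construction);
* repeat-length "slippage" variation confined to the tract;
* per-codon coalescent population samples whose scaled mutation rate
  theta * m(d) decays with distance, with outgroup bases for
  ancestral-state calls.

Everything is reproducible: the same config and seed yield byte-identical
outputs.  Coalescent genealogies and mutation placement for the population
sample are delegated to msprime; the rest is generated in-package.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import msprime
import numpy as np

from . import codes
from .popgen import SnpRecord
from .seg import ProteinRecord
from .tree import DEFAULT_NEWICK, SpeciesTree, TreeNode


@dataclass(frozen=True)
class Gradient:
    """Distance-decaying rate elevation m(d) = 1 + amplitude * exp(-d/scale)."""

    amplitude: float = 3.0
    scale: float = 50.0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.scale <= 0:
            raise ValueError("need amplitude >= 0 and scale > 0")

    def factor(self, distance: float) -> float:
        return 1.0 + self.amplitude * math.exp(-distance / self.scale)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_genes: int = 200
    newick: str = DEFAULT_NEWICK
    flank_codons: int = 100  # per side
    lcr_unit: str = "CAG"
    lcr_codons: int = 20
    #: extra codons emitted per side beyond flank_codons: entropy windows
    #: straddling the tract mark a few flanking residues low-complexity, so
    #: without a margin the detected flank would fall short of the nominal
    #: length; one detection window is enough.
    boundary_margin: int = 15
    sub_gradient_upstream: Gradient = Gradient(3.0, 50.0)
    sub_gradient_downstream: Gradient = Gradient(3.0, 50.0)
    mu: float = 1.0  # proposal rate multiplier per codon per unit branch length
    omega: float = 0.5  # acceptance ratio for nonsynonymous proposals
    kappa: float = 2.0  # transition/transversion ratio
    indel_rate: float = 0.05  # whole-codon deletions per codon per unit branch length
    indel_gradient_upstream: Gradient = Gradient(3.0, 50.0)
    indel_gradient_downstream: Gradient = Gradient(3.0, 50.0)
    slippage_max: int = 3  # max codons of tract-length variation per species
    n_samples: int = 178  # haplotype sequences in the population sample
    theta_codon: float = 0.01  # baseline pairwise diversity per codon
    chimp_divergence: float = 0.02  # outgroup divergence per site
    macaque_divergence: float = 0.06

    def __post_init__(self) -> None:
        if len(self.lcr_unit) != 3 or self.lcr_unit in codes.STOP_CODONS:
            raise ValueError("lcr_unit must be one sense codon")
        if self.lcr_codons < 5 or self.flank_codons < 1:
            raise ValueError("lcr_codons >= 5 and flank_codons >= 1 required")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")

    @property
    def tract_start(self) -> int:
        return self.flank_codons + self.boundary_margin

    @property
    def tract_end(self) -> int:
        return self.tract_start + self.lcr_codons

    @property
    def n_columns(self) -> int:
        return 2 * (self.flank_codons + self.boundary_margin) + self.lcr_codons

    def rate_factor(self, column: int, gradient_pair: tuple) -> float:
        """m(d) for the root codon at ``column``; inside the tract the mean
        of the two boundary-adjacent values is used."""
        up, down = gradient_pair
        start, end = self.tract_start, self.tract_end
        if column < start:
            return up.factor(start - column)
        if column >= end:
            return down.factor(column - end + 1)
        return 0.5 * (up.factor(1) + down.factor(1))


@dataclass
class TruthRecord:
    """Generator-side ground truth for one gene family."""

    gene_id: str
    lcr_start: int  # codon/column coordinates of the embedded tract
    lcr_end: int
    events: list = field(default_factory=list)  # accepted substitutions
    deletions: list = field(default_factory=list)  # (branch, column)

    def substitutions_per_column(self) -> dict:
        out: dict = {}
        for ev in self.events:
            out[ev["column"]] = out.get(ev["column"], 0) + 1
        return out


@dataclass
class GeneFamily:
    """One synthetic five-species ortholog group with its true alignment."""

    gene_id: str
    codon_alignment: dict  # species -> list of codons, None = gap
    truth: TruthRecord

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.codon_alignment.values())))

    def cds(self, species: str) -> str:
        return "".join(c for c in self.codon_alignment[species] if c is not None)

    def protein(self, species: str) -> ProteinRecord:
        return ProteinRecord(
            f"{self.gene_id}|{species}", codes.translate_cds(self.cds(species))
        )

    def protein_msa_row(self, species: str) -> str:
        return "".join(
            "-" if c is None else codes.translate_codon(c)
            for c in self.codon_alignment[species]
        )


@dataclass
class PopulationSample:
    """A coalescent sample of one flank, boundary-ordered."""

    gene_id: str
    side: str
    haplotypes: list  # n nucleotide strings, codons ordered by distance
    snps: list  # [SnpRecord]
    true_ancestral: dict  # nt position -> ancestral base
    reference: str


def _random_sense_codons(n: int, rng: np.random.Generator) -> list:
    idx = rng.integers(len(codes.SENSE_CODONS), size=n)
    return [codes.SENSE_CODONS[i] for i in idx]


def _mutate_base(base: str, kappa: float, rng: np.random.Generator) -> str:
    alts = [b for b in "ACGT" if b != base]
    weights = np.array([
        kappa if codes.is_transition(base, b) else 1.0 for b in alts
    ])
    return alts[rng.choice(3, p=weights / weights.sum())]


def simulate_gene_family(config: SimConfig, gene_index: int) -> GeneFamily:
    """Generate one ortholog family by evolving a root CDS down the tree."""
    rng = np.random.default_rng((config.seed, 7919, gene_index))
    tree = SpeciesTree(config.newick)
    gene_id = f"g{gene_index:04d}"
    n_cols = config.n_columns
    start, end = config.tract_start, config.tract_end
    side_len = config.flank_codons + config.boundary_margin

    root = (
        _random_sense_codons(side_len, rng)
        + [config.lcr_unit] * config.lcr_codons
        + _random_sense_codons(side_len, rng)
    )
    truth = TruthRecord(gene_id, start, end)
    sub_grad = (config.sub_gradient_upstream, config.sub_gradient_downstream)
    ind_grad = (config.indel_gradient_upstream, config.indel_gradient_downstream)
    accept_syn = min(1.0, 1.0 / config.omega) if config.omega > 0 else 1.0
    accept_nonsyn = min(1.0, config.omega)

    counter = [0]
    alignment: dict = {}

    def evolve_branch(seq: list, node: TreeNode, label: str) -> None:
        seq = list(seq)
        t = node.length
        for col in range(n_cols):
            codon = seq[col]
            if codon is None:
                continue
            m_sub = config.rate_factor(col, sub_grad)
            n_prop = rng.poisson(config.mu * m_sub * t)
            for _ in range(n_prop):
                pos = int(rng.integers(3))
                new_base = _mutate_base(codon[pos], config.kappa, rng)
                cand = codon[:pos] + new_base + codon[pos + 1 :]
                if cand in codes.STOP_CODONS:
                    continue
                syn = codes.is_synonymous(codon, cand)
                if rng.random() >= (accept_syn if syn else accept_nonsyn):
                    continue
                truth.events.append({
                    "branch": label, "column": col, "position": pos,
                    "from": codon, "to": cand, "synonymous": syn,
                })
                codon = cand
            seq[col] = codon
            # whole-codon deletion, flanks only (tract length varies by slippage)
            if not start <= col < end:
                d_gap = config.rate_factor(col, ind_grad)
                if rng.random() < min(1.0, config.indel_rate * d_gap * t):
                    seq[col] = None
                    truth.deletions.append((label, col))
        if node.is_leaf:
            # slippage: the tract contracts by up to slippage_max codons
            delta = int(rng.integers(config.slippage_max + 1))
            for col in range(end - 1, end - 1 - delta, -1):
                if seq[col] is not None:
                    seq[col] = None
                    truth.deletions.append((node.name, col))
            alignment[node.name] = seq
        else:
            for child in node.children:
                counter[0] += 1
                evolve_branch(seq, child, child.name or f"node{counter[0]}")
        return None

    for child in tree.root.children:
        counter[0] += 1
        evolve_branch(root, child, child.name or f"node{counter[0]}")
    return GeneFamily(gene_id, alignment, truth)


@dataclass
class SimulatedDataset:
    config: SimConfig
    genes: list

    def __iter__(self):
        return iter(self.genes)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    genes = [simulate_gene_family(config, i) for i in range(config.n_genes)]
    return SimulatedDataset(config, genes)


def simulate_population_sample(
    config: SimConfig,
    flank_reference: str,
    side: str,
    gene_id: str = "g0000",
    sample_index: int = 0,
) -> PopulationSample:
    """Sample n haplotypes of one flank under a neutral coalescent whose
    per-codon scaled mutation rate theta * m(d) decays with distance.

    ``flank_reference`` is the human flank CDS ordered from the LCR
    boundary outwards (codon at distance 1 first).  Genealogies and
    mutation placement come from msprime (haploid sample, no
    recombination); derived and outgroup bases are assigned in-package.
    Expected segregating sites per codon are theta * m(d) * a1(n) in the
    Watterson sense.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError("side must be 'upstream' or 'downstream'")
    L_nt = len(flank_reference)
    if L_nt % 3 != 0 or L_nt == 0:
        raise ValueError("flank reference must be a non-empty whole-codon sequence")
    rng = np.random.default_rng((config.seed, 104729, sample_index, 0 if side == "upstream" else 1))
    grad = (
        config.sub_gradient_upstream if side == "upstream" else config.sub_gradient_downstream
    )
    n_codons = L_nt // 3
    positions = np.arange(0, L_nt + 1, 3, dtype=float)
    # theta_site = 2*N*u with N=1, haploid: u = theta_codon*m(d)/6 per site
    rates = np.array([
        config.theta_codon * grad.factor(j + 1) / 6.0 for j in range(n_codons)
    ])
    seeds = rng.integers(1, 2**31 - 1, size=2)
    ts = msprime.sim_ancestry(
        samples=config.n_samples, ploidy=1, population_size=1.0,
        sequence_length=L_nt, random_seed=int(seeds[0]),
    )
    if rates.sum() > 0:
        mts = msprime.sim_mutations(
            ts, rate=msprime.RateMap(position=positions, rate=rates),
            model=msprime.BinaryMutationModel(), random_seed=int(seeds[1]),
            discrete_genome=True,
        )
    else:
        mts = ts
    n = config.n_samples
    hap = [list(flank_reference) for _ in range(n)]
    snps: list = []
    true_ancestral: dict = {}
    for var in mts.variants():
        pos = int(var.site.position)
        derived_mask = var.genotypes != 0
        count = int(derived_mask.sum())
        if count == 0 or count == n:
            continue
        anc_base = flank_reference[pos]
        der_base = _mutate_base(anc_base, config.kappa, rng)
        for i in np.flatnonzero(derived_mask):
            hap[i][pos] = der_base
        freq = count / n
        chimp = anc_base
        if rng.random() < 0.75 * (1.0 - math.exp(-4.0 * config.chimp_divergence / 3.0)):
            chimp = _mutate_base(anc_base, config.kappa, rng)
        macaque = anc_base
        if rng.random() < 0.75 * (1.0 - math.exp(-4.0 * config.macaque_divergence / 3.0)):
            macaque = _mutate_base(anc_base, config.kappa, rng)
        true_ancestral[pos] = anc_base
        snps.append(SnpRecord(
            position=pos,
            distance_to_lcr=pos + 1,  # nt distance from the LCR boundary
            alleles=(anc_base, der_base),
            frequencies={anc_base: 1.0 - freq, der_base: freq},
            chimp_base=chimp,
            macaque_base=macaque,
        ))
    return PopulationSample(
        gene_id, side, ["".join(h) for h in hap], snps, true_ancestral, flank_reference
    )


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

def fixture_configs(seed: int = 0) -> dict:
    """The four named study conditions used throughout the test-suite.

    * flat — no rate elevation anywhere (type-I error checks);
    * gradient — amplitude 3, length scale 50 codons on both sides;
    * asymmetric — stronger elevation on the 5' (upstream) side;
    * gappy — tenfold indel rate (gap-profile stress).
    """
    base = SimConfig(seed=seed)
    none = Gradient(0.0, 50.0)
    return {
        "flat": dataclasses.replace(
            base,
            sub_gradient_upstream=none, sub_gradient_downstream=none,
            indel_gradient_upstream=none, indel_gradient_downstream=none,
            n_genes=40,
        ),
        "gradient": base,
        "asymmetric": dataclasses.replace(
            base,
            sub_gradient_upstream=Gradient(4.0, 50.0),
            sub_gradient_downstream=Gradient(1.5, 50.0),
            n_genes=120,
        ),
        "gappy": dataclasses.replace(base, indel_rate=0.5, n_genes=60),
    }


def make_fixture_suite(seed: int = 0, out_dir=None) -> dict:
    """Simulate all named fixtures; optionally write them to ``out_dir``."""
    from . import io as lcr_io

    datasets = {}
    for name, cfg in fixture_configs(seed).items():
        ds = simulate_dataset(cfg)
        datasets[name] = ds
        if out_dir is not None:
            lcr_io.write_dataset(ds, f"{out_dir}/{name}")
    return datasets
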