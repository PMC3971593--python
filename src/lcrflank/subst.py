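"""Per-codon substitution counting and site dN/dS on the five-taxon tree.

Substitution counts come from Fitch small parsimony applied independently
to the three codon positions.  Synonymous/nonsynonymous partitioning
enumerates all equally parsimonious codon-level ancestral reconstructions
(the product of per-position minimal labelings, restricted to sense codons)
and, for each branch change spanning more than one nucleotide, averages the
classification over all single-step mutational orderings that avoid stop
codons (Nei–Gojobori pathway averaging).  Site omega is the ratio of
per-site nonsynonymous to synonymous rates using Nei–Gojobori site
opportunities averaged over the observed codons.

Selection calls compare site omega with a Monte-Carlo neutral reference:
single codons evolved down the same tree under an omega = 1 Markov codon
model, pushed through the identical estimator chain, and binned by their
realised parsimony count k.  Because omega conditioned on small k is highly
discrete (at k = 1 it can only be 0 or infinite), tail tests use the
randomised (exact) form: observations strictly inside an alpha/2 tail are
always flagged, and observations sitting on the boundary atom are flagged
with the residual probability, which makes the type-I rate exactly alpha
for sites whose k is represented in the reference.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from . import codes
from .tree import SpeciesTree, TreeNode

#: IUPAC ambiguity codes mapped to nucleotide sets
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

LARGE_OMEGA = math.inf  # sentinel for k_syn = 0, k_nonsyn > 0


@dataclass(frozen=True)
class CodonColumn:
    """One aligned codon column across the five species.

    ``codons`` maps species name to a 3-nt sense codon, or ``None`` where
    that species is gapped.  ``codon_distance`` is the 1-based codon
    distance from the LCR boundary; ``side`` is "upstream" or "downstream".
    """

    gene_id: str
    side: str
    codon_distance: int
    codons: dict

    @property
    def usable(self) -> bool:
        """Usable iff no species is gapped and no codon is a stop."""
        return all(
            c is not None and c not in codes.STOP_CODONS for c in self.codons.values()
        )

    @property
    def signed_distance(self) -> int:
        return -self.codon_distance if self.side == "upstream" else self.codon_distance


@dataclass
class SiteEstimate:
    """Per-codon-column substitution and selection estimates."""

    gene_id: str
    side: str
    codon_distance: int
    usable: bool
    k_total: float = float("nan")
    k_syn: float = float("nan")
    k_nonsyn: float = float("nan")
    omega: float = float("nan")  # nan = undefined, inf = "large" sentinel
    selection_call: str = "not_assessable"
    through_stop: bool = False

    @property
    def signed_distance(self) -> int:
        return -self.codon_distance if self.side == "upstream" else self.codon_distance


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def _fitch_sets(node: TreeNode, states: dict) -> tuple[frozenset, int]:
    """Bottom-up Fitch pass; returns (state set, change count) at ``node``."""
    if node.is_leaf:
        base = states[node.name]
        s = IUPAC.get(base.upper()) if isinstance(base, str) else frozenset(base)
        if not s:
            raise ValueError(f"empty state set for leaf {node.name}")
        return s, 0
    left, cl = _fitch_sets(node.children[0], states)
    right, cr = _fitch_sets(node.children[1], states)
    inter = left & right
    if inter:
        return inter, cl + cr
    return left | right, cl + cr + 1


def fitch_count(states: dict, tree: SpeciesTree) -> int:
    """Minimal number of substitutions explaining one nucleotide site.

    ``states`` maps each species name to a nucleotide (IUPAC codes allowed,
    interpreted as state sets).
    """
    missing = [s for s in tree.leaf_names() if s not in states]
    if missing:
        raise ValueError(f"missing states for species: {missing}")
    for sp, base in states.items():
        if isinstance(base, str) and base.upper() not in IUPAC:
            raise ValueError(f"invalid base {base!r} for {sp}")
    _, count = _fitch_sets(tree.binary_root, states)
    return count


def _minimal_labelings(tree: SpeciesTree, states: dict) -> tuple[int, list[dict]]:
    """All internal-node labelings of one nucleotide site achieving the
    parsimony minimum.  Returns (min_cost, [ {node_id: base} ]).

    Internal nodes are identified by their index in the postorder traversal
    of the binary-resolved tree.  With five leaves there are four internal
    nodes, so at most 256 assignments are scored.
    """
    post = tree.binary_root.postorder()
    internals = [n for n in post if not n.is_leaf]
    node_id = {id(n): i for i, n in enumerate(internals)}
    leaf_sets = {
        name: IUPAC[states[name].upper()] if isinstance(states[name], str) else frozenset(states[name])
        for name in tree.leaf_names()
    }

    best_cost = math.inf
    best: list[dict] = []
    for combo in itertools.product("ACGT", repeat=len(internals)):
        assign = {i: b for i, b in enumerate(combo)}
        cost = 0
        for n in internals:
            nb = assign[node_id[id(n)]]
            for c in n.children:
                if c.is_leaf:
                    if nb not in leaf_sets[c.name]:
                        cost += 1
                else:
                    if nb != assign[node_id[id(c)]]:
                        cost += 1
        if cost < best_cost:
            best_cost = cost
            best = [assign]
        elif cost == best_cost:
            best.append(assign)
    return best_cost, best


#: cap on codon-level reconstruction enumeration per column
MAX_RECONSTRUCTIONS = 2000


def partition_syn_nonsyn(column: CodonColumn, tree: SpeciesTree) -> tuple[float, float, bool]:
    """Split the parsimony substitution count of one codon column into
    synonymous and nonsynonymous parts.

    Returns ``(k_syn, k_nonsyn, through_stop)``; the two counts always sum
    to the total parsimony count for the column.
    """
    if not column.usable:
        raise ValueError("cannot partition a gapped or stop-bearing column")
    leaf_names = tree.leaf_names()
    per_pos: list[list[dict]] = []
    total = 0
    for pos in range(3):
        states = {sp: column.codons[sp][pos] for sp in leaf_names}
        cost, labelings = _minimal_labelings(tree, states)
        total += cost
        per_pos.append(labelings)
    if total == 0:
        return 0.0, 0.0, False

    post = tree.binary_root.postorder()
    internals = [n for n in post if not n.is_leaf]

    def edges(assign_codons: dict) -> list[tuple[str, str]]:
        node_codon = {}
        for i, n in enumerate(internals):
            node_codon[id(n)] = assign_codons[i]
        pairs = []
        for n in internals:
            for c in n.children:
                child_codon = (
                    column.codons[c.name] if c.is_leaf else node_codon[id(c)]
                )
                pairs.append((node_codon[id(n)], child_codon))
        return pairs

    combos = itertools.product(*per_pos)
    sense: list[tuple] = []
    fallback: list[tuple] = []
    for count, combo in enumerate(combos):
        if count >= MAX_RECONSTRUCTIONS:
            break
        # combo: one labeling per position; internal codon i = bases at i
        codons_at = tuple(
            combo[0][i] + combo[1][i] + combo[2][i] for i in range(len(internals))
        )
        if all(c not in codes.STOP_CODONS for c in codons_at):
            sense.append(codons_at)
        else:
            fallback.append(codons_at)
    pool = sense if sense else fallback
    stop_flag = not sense

    syn_sum = nonsyn_sum = 0.0
    for codons_at in pool:
        for parent, child in edges(dict(enumerate(codons_at))):
            if parent != child:
                s, n, hit = codes.pathway_syn_nonsyn(parent, child)
                syn_sum += s
                nonsyn_sum += n
                stop_flag = stop_flag or hit
    k_syn = syn_sum / len(pool)
    k_nonsyn = nonsyn_sum / len(pool)
    return k_syn, k_nonsyn, stop_flag


def site_opportunities(column: CodonColumn) -> tuple[float, float]:
    """Mean Nei–Gojobori synonymous / nonsynonymous site counts over the
    observed codons of a usable column; returns (S_bar, N_bar)."""
    syn = []
    non = []
    for c in column.codons.values():
        s, n = codes.ng_site_opportunities(c)
        syn.append(s)
        non.append(n)
    return float(np.mean(syn)), float(np.mean(non))


def site_omega(column: CodonColumn, tree: SpeciesTree) -> SiteEstimate:
    """Full per-column estimate: parsimony counts, syn/nonsyn split, omega.

    omega = (k_nonsyn / N_bar) / (k_syn / S_bar); NaN when there are no
    substitutions, +inf ("large") when all changes are nonsynonymous.
    """
    est = SiteEstimate(column.gene_id, column.side, column.codon_distance, column.usable)
    if not column.usable:
        return est
    leaf_names = tree.leaf_names()
    k_total = sum(
        fitch_count({sp: column.codons[sp][pos] for sp in leaf_names}, tree)
        for pos in range(3)
    )
    est.k_total = float(k_total)
    if k_total == 0:
        est.k_syn = est.k_nonsyn = 0.0
        est.omega = float("nan")
        return est
    k_syn, k_nonsyn, through_stop = partition_syn_nonsyn(column, tree)
    est.k_syn, est.k_nonsyn, est.through_stop = k_syn, k_nonsyn, through_stop
    s_bar, n_bar = site_opportunities(column)
    if k_syn == 0.0:
        est.omega = LARGE_OMEGA if k_nonsyn > 0 else float("nan")
    else:
        est.omega = (k_nonsyn / n_bar) / (k_syn / s_bar)
    return est


# ---------------------------------------------------------------------------
# Neutral null
# ---------------------------------------------------------------------------

_NEIGHBOR_CACHE: dict[float, dict] = {}


def _codon_rates(kappa: float) -> dict:
    """Per-codon single-step neighbor lists and kappa-weighted rates,
    normalised so the mean total rate over sense codons is 1."""
    if kappa in _NEIGHBOR_CACHE:
        return _NEIGHBOR_CACHE[kappa]
    raw = {}
    for c in codes.SENSE_CODONS:
        nbrs = codes.codon_neighbors(c, include_stops=False)
        weights = []
        for nb in nbrs:
            pos = next(i for i in range(3) if c[i] != nb[i])
            weights.append(kappa if codes.is_transition(c[pos], nb[pos]) else 1.0)
        raw[c] = (nbrs, np.array(weights), float(np.sum(weights)))
    mean_rate = float(np.mean([r[2] for r in raw.values()]))
    table = {
        c: (nbrs, w / tot, tot / mean_rate) for c, (nbrs, w, tot) in raw.items()
    }
    _NEIGHBOR_CACHE[kappa] = table
    return table


def evolve_codon(codon: str, branch_length: float, kappa: float, rng: np.random.Generator) -> str:
    """Evolve one codon along a branch under the neutral (omega = 1) codon
    model; stop codons are unreachable."""
    table = _codon_rates(kappa)
    t = branch_length
    state = codon
    while True:
        nbrs, probs, rate = table[state]
        if rate <= 0:
            return state
        wait = rng.exponential(1.0 / rate)
        if wait >= t:
            return state
        t -= wait
        state = nbrs[rng.choice(len(nbrs), p=probs)]


def simulate_neutral_column(
    tree: SpeciesTree, kappa: float, rng: np.random.Generator,
    root_codon: str | None = None,
) -> dict:
    """One codon column evolved neutrally down the tree from a root draw."""
    if root_codon is None:
        root_codon = codes.SENSE_CODONS[rng.integers(len(codes.SENSE_CODONS))]
    leaves = {}

    def descend(node: TreeNode, state: str) -> None:
        state = evolve_codon(state, node.length, kappa, rng)
        if node.is_leaf:
            leaves[node.name] = state
        else:
            for c in node.children:
                descend(c, state)

    for c in tree.root.children:
        descend(c, root_codon)
    return leaves


@dataclass
class NeutralNull:
    """Empirical neutral reference of site omega conditioned on the
    realised substitution count k."""

    omega_by_k: dict = field(default_factory=dict)  # k -> sorted np.ndarray
    alpha: float = 0.05
    min_draws: int = 1000
    kappa: float = 2.0

    def supported(self, k: int) -> bool:
        arr = self.omega_by_k.get(int(k))
        return arr is not None and len(arr) >= self.min_draws

    def cutoffs(self, k: int, alpha: float | None = None) -> tuple[float, float]:
        """Two-tailed empirical quantile cutoffs at alpha (alpha/2 per tail)."""
        a = self.alpha if alpha is None else alpha
        arr = self.omega_by_k[int(k)]
        lo = float(np.quantile(arr, a / 2.0, method="inverted_cdf"))
        hi = float(np.quantile(arr, 1.0 - a / 2.0, method="inverted_cdf"))
        return lo, hi

    def tail_fractions(self, k: int, omega: float) -> tuple[float, float, float, float]:
        """(P(null < omega), P(null <= omega), P(null > omega), P(null >= omega))."""
        arr = self.omega_by_k[int(k)]
        n = len(arr)
        lt = float(np.searchsorted(arr, omega, side="left")) / n
        le = float(np.searchsorted(arr, omega, side="right")) / n
        return lt, le, 1.0 - le, 1.0 - lt


def simulate_neutral_null(
    tree: SpeciesTree,
    n_draws: int = 60_000,
    kappa: float = 2.0,
    codon_frequencies: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    min_draws: int = 1000,
    scale_factors: tuple[float, ...] = (1.0, 4.0, 16.0),
) -> NeutralNull:
    """Build the neutral omega reference by simulation.

    ``n_draws`` single-codon columns are evolved neutrally, split equally
    over ``scale_factors`` copies of the tree with all branches multiplied
    by the factor.  Conditioned on the realised parsimony count k, the
    distribution of omega is essentially invariant to a uniform rescaling
    of the tree (given k, changes fall on branches in proportion to length
    and the jump chain does not depend on the time scale), so the higher
    scales populate the rare high-k bins cheaply.  For each k the reference
    uses draws from the lowest scale that supplies at least ``min_draws``;
    only when no single scale suffices are scales pooled.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if codon_frequencies is not None:
        freqs = np.asarray(codon_frequencies, dtype=float)
        if len(freqs) != len(codes.SENSE_CODONS) or not math.isclose(freqs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("codon_frequencies must sum to 1 over the 61 sense codons")
    else:
        freqs = None

    per_scale = max(1, n_draws // len(scale_factors))
    by_scale_k: dict[float, dict[int, list[float]]] = {}
    for factor in scale_factors:
        stree = tree.scaled(factor)
        bins: dict[int, list[float]] = {}
        for _ in range(per_scale):
            root = None
            if freqs is not None:
                root = codes.SENSE_CODONS[rng.choice(len(freqs), p=freqs)]
            leaves = simulate_neutral_column(stree, kappa, rng, root_codon=root)
            col = CodonColumn("null", "downstream", 1, leaves)
            est = site_omega(col, stree)
            k = int(est.k_total)
            if k > 0:
                bins.setdefault(k, []).append(est.omega)
        by_scale_k[factor] = bins

    omega_by_k: dict[int, np.ndarray] = {}
    all_k = sorted({k for bins in by_scale_k.values() for k in bins})
    for k in all_k:
        chosen = None
        for factor in sorted(scale_factors):
            vals = by_scale_k[factor].get(k, [])
            if len(vals) >= min_draws:
                chosen = vals
                break
        if chosen is None:
            pooled = [v for f in scale_factors for v in by_scale_k[f].get(k, [])]
            chosen = pooled
        omega_by_k[k] = np.sort(np.asarray(chosen, dtype=float))
    return NeutralNull(omega_by_k=omega_by_k, alpha=alpha, min_draws=min_draws, kappa=kappa)


def classify_selection(
    omega: float,
    k: int,
    null: NeutralNull,
    alpha: float | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Call selection at one site against the neutral reference.

    "negative" requires omega below 1 and in the lower alpha/2 tail of the
    per-k reference; "positive" requires omega above 1 and in the upper
    tail.  Because the conditional reference is discrete, the test is
    randomised at boundary atoms when an ``rng`` is supplied (exact
    alpha-level calibration); without an rng the conservative
    non-randomised call is made.
    """
    if math.isnan(omega):
        return "not_assessable"
    if k < 1 or not null.supported(k):
        return "not_assessable"
    a = (null.alpha if alpha is None else alpha) / 2.0
    lt, le, gt, ge = null.tail_fractions(k, omega)

    def tail_flag(strictly_beyond: float, including: float) -> bool:
        # including = P(as or more extreme); strictly_beyond = P(strictly more extreme)
        if including <= a:
            return True
        if strictly_beyond < a and rng is not None:
            atom = including - strictly_beyond
            return bool(rng.random() < (a - strictly_beyond) / atom)
        return False

    if omega < 1.0 and tail_flag(lt, le):
        return "negative"
    if omega > 1.0 and tail_flag(gt, ge):
        return "positive"
    return "neutral"


# ---------------------------------------------------------------------------
# Population pairwise counts
# ---------------------------------------------------------------------------

def pairwise_mean_substitutions(codons: list[str]) -> tuple[float, float, float]:
    """Mean pairwise codon differences over a population sample.

    Averages total, synonymous and nonsynonymous per-pair differences over
    all n(n-1)/2 pairs; multi-nucleotide pairs are split by pathway
    averaging.  Returns (total, syn, nonsyn).
    """
    n = len(codons)
    if n < 2:
        raise ValueError("need at least two sequences")
    for c in codons:
        if c is None or len(c) != 3 or c in codes.STOP_CODONS:
            raise ValueError(f"invalid codon in sample: {c!r}")
    tot = syn = non = 0.0
    pairs = 0
    for a, b in itertools.combinations(codons, 2):
        pairs += 1
        m = sum(x != y for x, y in zip(a, b))
        if m:
            s, ns, _ = codes.pathway_syn_nonsyn(a, b)
            tot += m
            syn += s
            non += ns
    return tot / pairs, syn / pairs, non / pairs
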