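"""Orthologous LCR matching across species and flanking-region extraction.

LCRs detected independently on each species' protein are projected into
the column space of the protein multiple alignment and matched 1-to-1 by
column overlap: a matched group requires exactly one contributing LCR per
species with every pairwise overlap fraction (intersection over the
shorter span) at or above a threshold.  LCRs present in fewer than all
five species yield no group and contribute no flanks.

Flanks are runs of codon columns adjacent to a matched LCR, one object per
side.  The usable length on each side is the shortest of three limits: the
configured maximum, the distance to the protein terminus, and the midpoint
of the gap to the nearest other matched LCR on that side.  Flanks shorter
than a minimum (default 300 nt = 100 codons) are discarded.  Columns where
any species is gapped are retained but flagged; downstream statistics
decide whether to use them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import codes
from .seg import LcrInterval, ProteinRecord


@dataclass(frozen=True)
class FlankParams:
    max_flank_nt: int = 1500
    min_flank_nt: int = 300
    overlap_threshold: float = 0.5
    #: "midpoint": truncate facing flanks at the midpoint between two LCRs;
    #: "exclude": drop a flank entirely when another LCR sits closer than
    #: twice the maximum flank length on that side.
    neighbor_rule: str = "midpoint"

    def __post_init__(self) -> None:
        if not 0 < self.min_flank_nt <= self.max_flank_nt:
            raise ValueError("need 0 < min_flank_nt <= max_flank_nt")
        if not 0 < self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must be in (0, 1]")
        if self.neighbor_rule not in ("midpoint", "exclude"):
            raise ValueError("neighbor_rule must be 'midpoint' or 'exclude'")

    @property
    def max_flank_codons(self) -> int:
        return self.max_flank_nt // 3

    @property
    def min_flank_codons(self) -> int:
        return -(-self.min_flank_nt // 3)


class ResidueColumnMap:
    """Bidirectional map between residue indices and MSA columns of one row."""

    def __init__(self, row: str, gap: str = "-"):
        self.row = row
        self._res_to_col: list[int] = []
        self._col_to_res: list[int | None] = []
        r = 0
        for col, ch in enumerate(row):
            if ch == gap:
                self._col_to_res.append(None)
            else:
                self._res_to_col.append(col)
                self._col_to_res.append(r)
                r += 1

    @property
    def n_residues(self) -> int:
        return len(self._res_to_col)

    def column_of(self, residue_index: int) -> int:
        if not 0 <= residue_index < len(self._res_to_col):
            raise IndexError(f"residue index {residue_index} out of range")
        return self._res_to_col[residue_index]

    def residue_at(self, column: int) -> int | None:
        if not 0 <= column < len(self._col_to_res):
            raise IndexError(f"column {column} out of range")
        return self._col_to_res[column]


@dataclass
class OrthologGroup:
    """Five orthologous coding sequences with their protein alignment."""

    gene_id: str
    cds: dict  # species -> ungapped nucleotide CDS (no trailing stop)
    proteins: dict  # species -> ProteinRecord
    msa: dict  # species -> aligned protein string

    def __post_init__(self) -> None:
        if len(self.msa) != 5:
            raise ValueError("ortholog group must contain exactly 5 species")
        ncols = {len(row) for row in self.msa.values()}
        if len(ncols) != 1:
            raise ValueError("MSA rows differ in length")
        self.n_columns = ncols.pop()
        self.maps = {sp: ResidueColumnMap(row) for sp, row in self.msa.items()}
        for sp, row in self.msa.items():
            ungapped = row.replace("-", "")
            if ungapped != self.proteins[sp].residues:
                raise ValueError(f"{self.gene_id}/{sp}: MSA row does not match protein")
            if codes.translate_cds(self.cds[sp]) != self.proteins[sp].residues:
                raise ValueError(f"{self.gene_id}/{sp}: CDS does not translate to protein")

    def codon_at(self, species: str, column: int) -> str | None:
        """The codon a species contributes at one MSA column, or None (gap)."""
        r = self.maps[species].residue_at(column)
        if r is None:
            return None
        return self.cds[species][3 * r : 3 * r + 3]

    def species(self) -> list[str]:
        return sorted(self.msa)


@dataclass
class OrthologousLcr:
    """One LCR matched 1-to-1 across all five species."""

    gene_id: str
    members: dict  # species -> LcrInterval
    column_span: tuple  # (start, end), 0-based half-open MSA columns

    def __len__(self) -> int:
        return self.column_span[1] - self.column_span[0]


@dataclass
class FlankColumn:
    """One codon column of a flank with per-species codons."""

    column: int
    codon_distance: int  # 1 = adjacent to the LCR boundary
    codons: dict  # species -> codon or None
    gapped: bool = field(init=False)

    def __post_init__(self) -> None:
        self.gapped = any(c is None for c in self.codons.values())


@dataclass
class FlankingRegion:
    """An eligible run of codon columns on one side of a matched LCR."""

    gene_id: str
    side: str  # "upstream" (5') or "downstream" (3')
    start_col: int
    end_col: int
    columns: list  # [FlankColumn] ordered by increasing codon_distance

    @property
    def length_codons(self) -> int:
        return self.end_col - self.start_col

    @property
    def length_nt(self) -> int:
        return 3 * self.length_codons

    @property
    def has_gaps(self) -> bool:
        return any(c.gapped for c in self.columns)

    def distance_of_column(self, column: int) -> int:
        for c in self.columns:
            if c.column == column:
                return c.codon_distance
        raise KeyError(f"column {column} not in flank")


def _column_span(lcr: LcrInterval, cmap: ResidueColumnMap) -> tuple:
    return (cmap.column_of(lcr.start), cmap.column_of(lcr.end - 1) + 1)


def _overlap_fraction(a: tuple, b: tuple) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    shorter = min(a[1] - a[0], b[1] - b[0])
    return inter / shorter


def match_orthologous_lcrs(
    group: OrthologGroup,
    lcrs_by_species: dict,
    params: FlankParams = FlankParams(),
) -> list[OrthologousLcr]:
    """Match per-species LCR lists into 1-to-1 orthologous groups.

    Greedy best-overlap matching in MSA column space: each candidate is
    anchored on one LCR of a reference species (the first in sorted
    species order) and completed with the best-overlapping unused LCR of
    every other species.  Candidates are emitted in order of decreasing
    mean pairwise overlap, skipping any that reuses a member or intersects
    an emitted group's columns.
    """
    species = group.species()
    for sp in species:
        if sp not in lcrs_by_species:
            raise ValueError(f"no LCR list for species {sp!r}")
    spans = {
        sp: [(lcr, _column_span(lcr, group.maps[sp])) for lcr in lcrs_by_species[sp]]
        for sp in species
    }
    anchor_sp = species[0]
    candidates = []
    for anchor, anchor_span in spans[anchor_sp]:
        members = {anchor_sp: (anchor, anchor_span)}
        complete = True
        for sp in species[1:]:
            best = None
            best_frac = 0.0
            for lcr, span in spans[sp]:
                frac = _overlap_fraction(anchor_span, span)
                if frac > best_frac:
                    best, best_frac = (lcr, span), frac
            if best is None or best_frac < params.overlap_threshold:
                complete = False
                break
            members[sp] = best
        if not complete:
            continue
        fracs = []
        sps = list(members)
        for i in range(len(sps)):
            for j in range(i + 1, len(sps)):
                fracs.append(_overlap_fraction(members[sps[i]][1], members[sps[j]][1]))
        if min(fracs) < params.overlap_threshold:
            continue
        score = sum(fracs) / len(fracs)
        start = min(sp_span[1][0] for sp_span in members.values())
        end = max(sp_span[1][1] for sp_span in members.values())
        candidates.append((score, start, end, members))

    candidates.sort(key=lambda c: (-c[0], c[1]))
    emitted: list[OrthologousLcr] = []
    used: set = set()
    claimed: list[tuple] = []
    for score, start, end, members in candidates:
        keys = {(sp, id(m[0])) for sp, m in members.items()}
        if keys & used:
            continue
        if any(start < e and s < end for s, e in claimed):
            continue
        used |= keys
        claimed.append((start, end))
        emitted.append(
            OrthologousLcr(group.gene_id, {sp: m[0] for sp, m in members.items()}, (start, end))
        )
    emitted.sort(key=lambda o: o.column_span)
    return emitted


def extract_flanks(
    group: OrthologGroup,
    lcrs: list[OrthologousLcr],
    params: FlankParams = FlankParams(),
) -> list[FlankingRegion]:
    """Extract eligible 5'/3' flanking codon-column runs for matched LCRs.

    Each side's length is min(max flank, codons to the protein terminus,
    codons to the midpoint of the gap to the nearest LCR on that side) —
    or, under the "exclude" neighbor rule, the flank is dropped when
    another LCR lies closer than twice the maximum flank length.  Flanks
    below the minimum length are discarded.
    """
    lcrs = sorted(lcrs, key=lambda o: o.column_span)
    for a, b in zip(lcrs, lcrs[1:]):
        if a.column_span[1] > b.column_span[0]:
            raise ValueError("orthologous LCR spans must be disjoint and sorted")
    n_cols = group.n_columns
    max_c = params.max_flank_codons
    out: list[FlankingRegion] = []
    for i, olcr in enumerate(lcrs):
        start, end = olcr.column_span
        # upstream (5') side
        terminus = start
        if i > 0:
            gap = start - lcrs[i - 1].column_span[1]
            if params.neighbor_rule == "midpoint":
                limit = min(terminus, gap // 2)
            else:
                limit = terminus if gap >= 2 * max_c else 0
        else:
            limit = terminus
        length = min(max_c, limit)
        if 3 * length >= params.min_flank_nt:
            cols = [
                FlankColumn(c, start - c, {sp: group.codon_at(sp, c) for sp in group.species()})
                for c in range(start - 1, start - length - 1, -1)
            ]
            out.append(FlankingRegion(group.gene_id, "upstream", start - length, start, cols))
        # downstream (3') side
        terminus = n_cols - end
        if i + 1 < len(lcrs):
            gap = lcrs[i + 1].column_span[0] - end
            if params.neighbor_rule == "midpoint":
                limit = min(terminus, gap // 2)
            else:
                limit = terminus if gap >= 2 * max_c else 0
        else:
            limit = terminus
        length = min(max_c, limit)
        if 3 * length >= params.min_flank_nt:
            cols = [
                FlankColumn(c, c - end + 1, {sp: group.codon_at(sp, c) for sp in group.species()})
                for c in range(end, end + length)
            ]
            out.append(FlankingRegion(group.gene_id, "downstream", end, end + length, cols))
    return out


def nt_distance(codon_distance: int, offset: int) -> int:
    """Nucleotide distance of position ``offset`` (1..3) within the codon at
    ``codon_distance`` (1-based) from the LCR boundary."""
    if not 1 <= offset <= 3:
        raise ValueError("offset must be 1..3")
    return 3 * (codon_distance - 1) + offset
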