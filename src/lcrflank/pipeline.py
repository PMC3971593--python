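"""End-to-end orchestration: synthetic dataset -> LCR detection -> ortholog
matching -> flank extraction -> per-codon estimates -> profiles.

The pipeline is deterministic given the dataset config (which carries the
seed): every random choice downstream of the generator (classifier
randomisation, null simulations, coalescent draws) uses a generator
derived from that seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import codes
from .flanks import FlankParams, FlankingRegion, extract_flanks, match_orthologous_lcrs, OrthologGroup
from .popgen import (
    FixedSNull,
    PopulationFragment,
    SnpRecord,
    bh_fdr,
    empirical_pvalue,
    resolve_ancestral,
    tajimas_d,
)
from .profiles import (
    aggregate_by_distance,
    gap_profile,
    no_gap_robustness,
    pearson_with_p,
)
from .seg import SegParams, detect_lcrs
from .simulate import GeneFamily, SimConfig, SimulatedDataset, simulate_dataset, simulate_population_sample
from .subst import CodonColumn, NeutralNull, classify_selection, simulate_neutral_null, site_omega
from .tree import SpeciesTree

SITE_COLUMNS = [
    "gene_id", "side", "codon_distance", "signed_distance", "usable", "gapped",
    "k_total", "k_syn", "k_nonsyn", "omega", "selection_call",
]


def gene_to_group(gene: GeneFamily) -> OrthologGroup:
    species = sorted(gene.codon_alignment)
    return OrthologGroup(
        gene.gene_id,
        {sp: gene.cds(sp) for sp in species},
        {sp: gene.protein(sp) for sp in species},
        {sp: gene.protein_msa_row(sp) for sp in species},
    )


def collect_flanks(
    dataset: SimulatedDataset,
    seg_params: SegParams = SegParams(),
    flank_params: FlankParams = FlankParams(),
) -> list:
    """Detect LCRs per species, match them across species, extract flanks."""
    out: list = []
    for gene in dataset.genes:
        group = gene_to_group(gene)
        lcrs = {
            sp: detect_lcrs(group.proteins[sp], seg_params) for sp in group.species()
        }
        matched = match_orthologous_lcrs(group, lcrs, flank_params)
        out.extend(extract_flanks(group, matched, flank_params))
    return out


def primate_site_table(
    flank_regions: list,
    tree: SpeciesTree,
    null: NeutralNull | None = None,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-codon-column substitution estimates over all flanks."""
    rows = []
    for fr in flank_regions:
        for col in fr.columns:
            column = CodonColumn(fr.gene_id, fr.side, col.codon_distance, col.codons)
            est = site_omega(column, tree)
            call = est.selection_call
            if null is not None and est.usable and est.k_total > 0:
                call = classify_selection(est.omega, int(est.k_total), null, alpha, rng)
            rows.append((
                fr.gene_id, fr.side, col.codon_distance, column.signed_distance,
                est.usable, col.gapped, est.k_total, est.k_syn, est.k_nonsyn,
                est.omega, call,
            ))
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def pairwise_mean_from_counts(counts: Counter) -> tuple[float, float, float]:
    """Mean pairwise codon differences from codon multiplicities."""
    n = sum(counts.values())
    pairs = n * (n - 1) / 2
    if pairs == 0:
        raise ValueError("need at least two sequences")
    tot = syn = non = 0.0
    items = list(counts.items())
    for i in range(len(items)):
        a, ca = items[i]
        for j in range(i + 1, len(items)):
            b, cb = items[j]
            m = sum(x != y for x, y in zip(a, b))
            if m:
                s, ns, _ = codes.pathway_syn_nonsyn(a, b)
                w = ca * cb
                tot += w * m
                syn += w * s
                non += w * ns
    return tot / pairs, syn / pairs, non / pairs


def population_tables(
    config: SimConfig,
    flank_regions: list,
    null: FixedSNull,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    max_flanks: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-codon Tajima's D / pairwise-difference table and SNP table.

    For each flank a coalescent population sample of the human flank
    sequence is generated; columns where human is gapped are skipped.
    Tajima's D significance is an empirical tail p against the fixed-S
    null; Benjamini–Hochberg is applied separately within the negative-D
    and positive-D strata pooled over all codons.
    """
    codon_rows = []
    snp_rows = []
    regions = flank_regions if max_flanks is None else flank_regions[:max_flanks]
    for idx, fr in enumerate(regions):
        cols = [c for c in fr.columns if c.codons.get("human") is not None]
        if not cols:
            continue
        ref = "".join(c.codons["human"] for c in cols)
        sample = simulate_population_sample(config, ref, fr.side, fr.gene_id, sample_index=idx)
        sign = -1 if fr.side == "upstream" else 1
        for j, col in enumerate(cols):
            codons = [h[3 * j : 3 * j + 3] for h in sample.haplotypes]
            frag = PopulationFragment.from_sequences(codons)
            d = tajimas_d(frag)
            p = float("nan")
            if frag.S >= 1 and not np.isnan(d):
                p = empirical_pvalue(d, null.draws(frag.n, 3, frag.S), rng=rng)
            tot, s_, n_ = pairwise_mean_from_counts(Counter(codons))
            codon_rows.append((
                fr.gene_id, fr.side, col.codon_distance, sign * col.codon_distance,
                frag.S, frag.pi, d, p, tot, s_, n_,
            ))
        for snp in sample.snps:
            snp_rows.append((
                fr.gene_id, fr.side, snp.position, sign * snp.distance_to_lcr,
                snp.distance_to_lcr, snp.alleles[0], snp.alleles[1],
                snp.frequencies[snp.alleles[1]], snp.chimp_base, snp.macaque_base,
                sample.true_ancestral[snp.position],
            ))
    codon_df = pd.DataFrame(codon_rows, columns=[
        "gene_id", "side", "codon_distance", "signed_distance", "S", "pi",
        "tajima_d", "p_value", "k_total", "k_syn", "k_nonsyn",
    ])
    codon_df["usable"] = True
    codon_df["gapped"] = False
    codon_df["q_flag"] = False
    for stratum in ("neg", "pos"):
        if stratum == "neg":
            mask = (codon_df["tajima_d"] < 0) & np.isfinite(codon_df["p_value"])
        else:
            mask = (codon_df["tajima_d"] > 0) & np.isfinite(codon_df["p_value"])
        if mask.any():
            codon_df.loc[mask, "q_flag"] = bh_fdr(codon_df.loc[mask, "p_value"], alpha)
    snp_df = pd.DataFrame(snp_rows, columns=[
        "gene_id", "side", "position", "signed_nt_distance", "nt_distance",
        "ancestral_like", "derived_like", "derived_like_freq",
        "chimp_base", "macaque_base", "true_ancestral",
    ])
    return codon_df, snp_df


def snp_records_from_table(snp_df: pd.DataFrame) -> list:
    """Rebuild SnpRecord objects (with parsimony ancestral calls) from the
    SNP table emitted by :func:`population_tables`."""
    records = []
    for r in snp_df.itertuples():
        records.append(SnpRecord(
            position=int(r.position),
            distance_to_lcr=int(r.nt_distance),
            alleles=(r.ancestral_like, r.derived_like),
            frequencies={
                r.ancestral_like: 1.0 - float(r.derived_like_freq),
                r.derived_like: float(r.derived_like_freq),
            },
            chimp_base=r.chimp_base,
            macaque_base=r.macaque_base,
        ))
    return resolve_ancestral(records)


def composition_table(
    dataset: SimulatedDataset,
    seg_params: SegParams = SegParams(),
    flank_params: FlankParams = FlankParams(),
    species: str = "human",
) -> pd.DataFrame:
    """Per-gene nucleotide frequencies in the LCR, its flanks and the whole
    CDS (one row per gene and base), for composition correlations."""

    def freqs(seq: str) -> dict:
        total = len(seq)
        return {b: seq.count(b) / total if total else float("nan") for b in "ACGT"}

    rows = []
    for gene in dataset.genes:
        group = gene_to_group(gene)
        lcrs = {sp: detect_lcrs(group.proteins[sp], seg_params) for sp in group.species()}
        matched = match_orthologous_lcrs(group, lcrs, flank_params)
        regions = extract_flanks(group, matched, flank_params)
        if not matched or not regions:
            continue
        lcr_seq = "".join(
            c
            for m in matched
            for col in range(*m.column_span)
            if (c := group.codon_at(species, col)) is not None
        )
        flank_seq = "".join(
            c.codons[species]
            for fr in regions
            for c in fr.columns
            if c.codons[species] is not None
        )
        cds_seq = group.cds[species]
        if not lcr_seq or not flank_seq:
            continue
        f_l, f_f, f_c = freqs(lcr_seq), freqs(flank_seq), freqs(cds_seq)
        for b in "ACGT":
            rows.append((gene.gene_id, b, f_l[b], f_f[b], f_c[b]))
    return pd.DataFrame(
        rows, columns=["gene_id", "base", "lcr_freq", "flank_freq", "cds_freq"]
    )


@dataclass
class PipelineResult:
    config: SimConfig
    flanks: list
    site_table: pd.DataFrame
    profiles: dict = field(default_factory=dict)
    correlations: pd.DataFrame | None = None
    human_table: pd.DataFrame | None = None
    snp_table: pd.DataFrame | None = None


def _correlation_frame(reports: list) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.statistic, r.side, r.r, r.p, r.n_points, r.weighted) for r in reports],
        columns=["statistic", "side", "r", "p", "n_points", "weighted"],
    )


def run_pipeline(
    config: SimConfig,
    seg_params: SegParams = SegParams(),
    flank_params: FlankParams | None = None,
    neutral_null: NeutralNull | None = None,
    population: bool = False,
    fixed_s_draws: int = 5000,
    alpha: float = 0.05,
    max_population_flanks: int | None = None,
    out_dir=None,
) -> PipelineResult:
    """Run the whole analysis on one simulated dataset.

    With ``neutral_null`` provided, per-site selection calls and their
    distance profiles are included; with ``population=True``, the human
    population stage (pairwise differences, Tajima's D, SNP table) runs
    as well.  Pass ``out_dir`` to write all tables as TSV.

    When ``flank_params`` is not given, the flank window is capped at the
    dataset's nominal flank length, so every profile distance is supported
    by nearly all flanks instead of trailing off into single-flank
    distances contributed only by boundary-detection jitter.
    """
    if flank_params is None:
        flank_params = FlankParams(max_flank_nt=max(300, 3 * config.flank_codons))
    dataset = simulate_dataset(config)
    tree = SpeciesTree(config.newick)
    flank_regions = collect_flanks(dataset, seg_params, flank_params)
    rng = np.random.default_rng((config.seed, 13))
    site = primate_site_table(flank_regions, tree, neutral_null, alpha, rng)

    profiles = {
        stat: aggregate_by_distance(site, stat)
        for stat in ("k_total", "k_syn", "k_nonsyn")
    }
    if neutral_null is not None:
        for stat in ("prop_negative", "prop_positive"):
            profiles[stat] = aggregate_by_distance(site, stat)
    profiles["gap_prop"] = gap_profile(flank_regions)

    reports = []
    for stat, prof in profiles.items():
        for side in ("both", "upstream", "downstream"):
            try:
                reports.append(pearson_with_p(prof, statistic=stat, side=side))
            except ValueError:
                pass
    try:
        reports.append(no_gap_robustness(site, "k_total"))
    except ValueError:
        pass

    result = PipelineResult(
        config, flank_regions, site, profiles, _correlation_frame(reports)
    )

    if population:
        null = FixedSNull(n_draws=fixed_s_draws, seed=config.seed + 1_000_003)
        prng = np.random.default_rng((config.seed, 29))
        human, snps = population_tables(
            config, flank_regions, null, alpha, prng, max_population_flanks
        )
        result.human_table = human
        result.snp_table = snps
        for stat in ("k_total", "k_syn", "k_nonsyn", "prop_negD", "prop_posD"):
            prof = aggregate_by_distance(human, stat)
            result.profiles[f"human_{stat}"] = prof
            for side in ("both",):
                try:
                    reports.append(
                        pearson_with_p(prof, statistic=f"human_{stat}", side=side)
                    )
                except ValueError:
                    pass
        result.correlations = _correlation_frame(reports)

    if out_dir is not None:
        _write_result(result, out_dir)
    return result


def _write_result(result: PipelineResult, out_dir) -> None:
    import os

    from . import io as lcr_io

    os.makedirs(out_dir, exist_ok=True)
    flank_df = pd.DataFrame(
        [
            (f.gene_id, f.side, f.start_col, f.end_col, f.length_nt, f.has_gaps)
            for f in result.flanks
        ],
        columns=["gene_id", "side", "start_col", "end_col", "length_nt", "has_gaps"],
    )
    lcr_io.write_table(flank_df, os.path.join(out_dir, "flanks.tsv"))
    lcr_io.write_table(result.site_table, os.path.join(out_dir, "site_estimates.tsv"))
    for stat, prof in result.profiles.items():
        lcr_io.write_table(prof, os.path.join(out_dir, f"profile_{stat}.tsv"))
    if result.correlations is not None:
        lcr_io.write_table(result.correlations, os.path.join(out_dir, "correlations.tsv"))
    if result.human_table is not None:
        lcr_io.write_table(result.human_table, os.path.join(out_dir, "human_codons.tsv"))
    if result.snp_table is not None:
        lcr_io.write_table(result.snp_table, os.path.join(out_dir, "snps.tsv"))
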