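"""Distance-indexed profiles and their correlation statistics.

Per-site estimates are aggregated by signed codon (or nucleotide) distance
from the LCR boundary — negative distances are upstream — into profiles of
per-distance means with the number of contributing flanks N.  A profile is
then tested for a distance relationship with an unweighted Pearson
product-moment correlation between the per-distance mean and the absolute
distance, with the usual two-sided t-test p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .flanks import FlankingRegion, nt_distance

#: statistics computed over usable (ungapped, stop-free) sites
SUBSTITUTION_STATS = ("k_total", "k_syn", "k_nonsyn")
#: statistics computed over sites where a selection call was possible
PROPORTION_STATS = ("prop_negative", "prop_positive")
#: statistics computed over codons with defined Tajima's D
TAJIMA_STATS = ("prop_negD", "prop_posD")


@dataclass
class CorrelationReport:
    statistic: str
    r: float
    p: float
    n_points: int
    weighted: bool = False
    side: str = "both"


def aggregate_by_distance(site_table: pd.DataFrame, statistic: str) -> pd.DataFrame:
    """Per-distance means of one statistic over contributing flanks.

    ``site_table`` is the tidy per-codon-column table produced by the
    pipeline (one row per gene, side and codon distance).  Returns a frame
    with columns ``distance`` (signed codons), ``mean`` and ``n``.
    Substitution statistics average over usable sites only; selection
    proportions use assessable sites as denominator; Tajima proportions use
    codons with defined D.
    """
    if site_table.empty:
        return pd.DataFrame(columns=["distance", "mean", "n"])
    df = site_table.copy()
    if statistic in SUBSTITUTION_STATS:
        df = df[df["usable"]]
        values = df[statistic]
    elif statistic in PROPORTION_STATS:
        df = df[df["selection_call"].isin(["negative", "neutral", "positive"])]
        target = "negative" if statistic == "prop_negative" else "positive"
        values = (df["selection_call"] == target).astype(float)
    elif statistic in TAJIMA_STATS:
        df = df[np.isfinite(df["tajima_d"])]
        if statistic == "prop_negD":
            values = ((df["tajima_d"] < 0) & df["q_flag"]).astype(float)
        else:
            values = ((df["tajima_d"] > 0) & df["q_flag"]).astype(float)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if df.empty:
        return pd.DataFrame(columns=["distance", "mean", "n"])
    out = (
        pd.DataFrame({"distance": df["signed_distance"], "value": values})
        .groupby("distance")["value"]
        .agg(mean="mean", n="size")
        .reset_index()
        .sort_values("distance", ignore_index=True)
    )
    out["n"] = out["n"].astype(int)
    return out


def gap_profile(flank_regions: list) -> pd.DataFrame:
    """Fraction of flanks with an alignment gap at each nucleotide distance.

    For every nucleotide position a flank provides, the flank counts in the
    denominator; it counts in the numerator when at least one species is
    gapped there.  Indels are codon-aligned upstream of this point, so the
    three positions of one codon share their flag.  Distances are signed
    (negative = upstream).
    """
    rows = []
    for fr in flank_regions:
        sign = -1 if fr.side == "upstream" else 1
        for col in fr.columns:
            for offset in (1, 2, 3):
                d = sign * nt_distance(col.codon_distance, offset)
                rows.append((d, 1.0 if col.gapped else 0.0))
    if not rows:
        return pd.DataFrame(columns=["distance", "mean", "n"])
    df = pd.DataFrame(rows, columns=["distance", "value"])
    out = (
        df.groupby("distance")["value"]
        .agg(mean="mean", n="size")
        .reset_index()
        .sort_values("distance", ignore_index=True)
    )
    out["n"] = out["n"].astype(int)
    return out


def pearson_with_p(
    profile: pd.DataFrame,
    statistic: str = "profile",
    weighted: bool = False,
    side: str = "both",
) -> CorrelationReport:
    """Pearson correlation of per-distance means against absolute distance.

    ``side`` restricts to "upstream" (negative distances) or "downstream"
    (positive) points; "both" pools them, matching a single correlation per
    profile.  ``weighted`` optionally weights points by N.
    """
    df = profile.dropna(subset=["mean"])
    if side == "upstream":
        df = df[df["distance"] < 0]
    elif side == "downstream":
        df = df[df["distance"] > 0]
    elif side != "both":
        raise ValueError(f"unknown side {side!r}")
    if len(df) < 3:
        raise ValueError("need at least 3 distance points")
    x = np.abs(df["distance"].to_numpy(dtype=float))
    y = df["mean"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    if weighted:
        w = df["n"].to_numpy(dtype=float)
        w = w / w.sum()
        mx, my = np.sum(w * x), np.sum(w * y)
        cov = np.sum(w * (x - mx) * (y - my))
        r = cov / math.sqrt(np.sum(w * (x - mx) ** 2) * np.sum(w * (y - my) ** 2))
        m = len(df)
        t = r * math.sqrt((m - 2) / max(1e-300, 1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=m - 2)
    else:
        r, p = stats.pearsonr(x, y)
    return CorrelationReport(statistic, float(r), float(p), len(df), weighted, side)


def composition_correlation(comp_table: pd.DataFrame) -> pd.DataFrame:
    """Across-gene correlations of nucleotide composition.

    ``comp_table`` has one row per gene and base with columns ``gene_id``,
    ``base``, ``lcr_freq``, ``flank_freq``, ``cds_freq`` (frequencies
    renormalised over ungapped positions).  For each base the Pearson r of
    flank composition against LCR composition, and against whole-CDS
    composition, is returned with its p-value.
    """
    n_genes = comp_table["gene_id"].nunique()
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    rows = []
    for base, sub in comp_table.groupby("base"):
        for other, label in (("lcr_freq", "flank_vs_lcr"), ("cds_freq", "flank_vs_cds")):
            x = sub["flank_freq"].to_numpy(dtype=float)
            y = sub[other].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(x, y)
            rows.append((base, label, float(r), float(p), len(sub)))
    return pd.DataFrame(rows, columns=["base", "comparison", "r", "p", "n_genes"])


def no_gap_robustness(
    site_table: pd.DataFrame, statistic: str = "k_total"
) -> CorrelationReport:
    """Distance correlation recomputed on flanks with no alignment gaps.

    Misalignment near indels could inflate apparent substitution counts, so
    the profile correlation is repeated restricted to flanks whose every
    codon column is gap-free.
    """
    clean_keys = (
        site_table.groupby(["gene_id", "side"])["gapped"]
        .any()
        .loc[lambda s: ~s]
        .index
    )
    if len(clean_keys) < 3:
        raise ValueError("fewer than 3 gap-free flanks; not computed")
    idx = site_table.set_index(["gene_id", "side"]).index
    sub = site_table[idx.isin(clean_keys)]
    profile = aggregate_by_distance(sub, statistic)
    return pearson_with_p(profile, statistic=f"{statistic}_no_gap")
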