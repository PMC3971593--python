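# lcrflank

Substitution, selection and diversity gradients in protein-coding sequence
flanking low-complexity regions (LCRs).

About one in seven human proteins carries a low-complexity segment — a
repeat-rich stretch such as a poly-glutamine tract encoded by a
trinucleotide repeat.  These repeats are mutational hotspots (replication
slippage, unequal crossing-over), and their instability appears to leak
into the surrounding coding sequence: point substitutions and indels are
enriched near LCR boundaries and decay with distance, even while the same
sites show clear purifying selection.  `lcrflank` is a tested pipeline for
quantifying that effect on a five-primate ortholog panel (human,
chimpanzee, gorilla, orangutan, macaque) and on a human population sample,
together with a synthetic-data generator that plants known gradients so
every stage can be validated end to end.

## What it computes

* **LCR detection** — sliding-window Shannon entropy on protein sequences
  (window 15 residues, threshold 1.9 bits), mark-and-merge.
* **Orthologous flanks** — 1-to-1 LCR matching across the five species by
  alignment-column overlap; eligible 5′/3′ flanking codon runs truncated
  at protein termini and midpoints between LCRs, minimum 300 nt.
* **Per-codon substitutions and dN/dS** — Fitch parsimony counts on the
  fixed primate tree, synonymous/nonsynonymous partitioning by
  Nei–Gojobori pathway averaging over all equally parsimonious ancestral
  reconstructions, and site ω = (dN per nonsynonymous site)/(dS per
  synonymous site); selection calls against a simulated neutral null
  (ω = 1 codon model) conditioned on the per-site substitution count,
  with an exact (randomised) tail test.
* **Population stage** — per-codon mean pairwise differences and Tajima's
  D over n haplotypes, significance from a fixed-S coalescent null
  (neutral genealogies carrying exactly the observed number of segregating
  sites), Benjamini–Hochberg FDR per sign stratum, and outgroup-parsimony
  ancestral states with a derived-frequency/distance rank correlation.
* **Distance profiles** — per-distance means with contributing-flank
  counts N, gap-proportion profiles per nucleotide, Pearson
  correlations against |distance|, no-gap robustness reruns, and
  nucleotide-composition correlations (flank vs LCR, flank vs whole CDS).

See `docs/methods.md` for models, defaults and limitations.

## Worked example

Run the full primate stage on the "gradient" study condition — 200
synthetic gene families whose substitution and indel rates are elevated
3-fold at the LCR boundary with a 50-codon decay length:

```python
import lcrflank as lf
from lcrflank.pipeline import run_pipeline

config = lf.fixture_configs(seed=1)["gradient"]   # a=3, lambda=50, 200 genes
result = run_pipeline(config)

print(f"flanks: {len(result.flanks)}, codon columns: {len(result.site_table)}")
profile = result.profiles["k_total"]
print("near-LCR mean substitutions:",
      profile[profile.distance.isin([1, 2, 3])]["mean"].round(3).tolist())
print("far mean substitutions:     ",
      profile[profile.distance.isin([98, 99, 100])]["mean"].round(3).tolist())
c = result.correlations.set_index(["statistic", "side"])
for stat in ("k_total", "k_syn", "k_nonsyn", "gap_prop"):
    row = c.loc[(stat, "both")]
    print(f"{stat:9s} r = {row['r']:+.3f}   p = {row['p']:.2e}")
```

prints

```
flanks: 400, codon columns: 40000
near-LCR mean substitutions: [0.146, 0.168, 0.177]
far mean substitutions:      [0.045, 0.05, 0.065]
k_total   r = -0.802   p = 3.90e-46
k_syn     r = -0.715   p = 1.39e-32
k_nonsyn  r = -0.684   p = 6.63e-29
gap_prop  r = -0.391   p = 2.20e-23
```

Codons adjacent to the LCR carry roughly three times as many inferred
substitutions as codons 100 away, and the per-distance means correlate
strongly and negatively with distance for total, synonymous and
nonsynonymous counts; the fraction of flanks with an alignment gap decays
the same way.  On the "flat" condition (no planted gradient) the same
correlations are null at the nominal 5% rate, and on the "asymmetric"
condition the upstream (5′) side shows the higher mean — the directions
of effect the pipeline is designed to resolve.

A thin CLI mirrors the library:

```bash
lcrflank detect-lcr --window 15 --threshold 1.9 --in proteins.fa --out lcrs.tsv
lcrflank fixtures --out fixtures/ --seed 0
lcrflank pipeline --fixture gradient --seed 1 --selection --population --out out/
```

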