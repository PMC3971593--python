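# Methods

`lcrflank` studies how point substitutions, indels and selection behave in
protein-coding sequence as a function of distance from a low-complexity
region (LCR) — a repeat-rich, low-entropy protein segment such as a poly-Q
tract.  The pipeline has five analysis stages plus a synthetic-data
generator; this note records the models, the defaults and why, the
numerical choices, and what the synthetic data does and does not show.

## LCR detection

Proteins are scanned with a sliding window of `W = 15` residues.  Each
window is scored by the Shannon entropy of its residue composition,
`K = -Σ (n_i/W) log2(n_i/W)`, and every residue covered by at least one
window with `K < K0 = 1.9` bits is marked; maximal marked runs become LCR
intervals.  This is a deliberately simplified, single-threshold variant of
the classic SEG filter: SEG's two-threshold trigger/extension scheme and
its probability-minimising boundary refinement are not reimplemented,
because a single window size and threshold fully determine the analysis
and make the detector exactly reproducible by a brute-force window scan
(which the test-suite uses as an oracle).  The window is counted in
residues — SEG operates on amino acids, and a "15 bp" reading of this
parameterisation would not make sense for a protein-level filter.
Ambiguous residues (`X`) count as a 21st symbol so window length is never
shortened.  Detection is windowed, so boundaries smear: a window
containing ~10 tract residues and ~5 flanking residues is itself
low-entropy, which extends the detected interval a few residues into the
flank.  This mirrors the boundary-misidentification caveat familiar from
real SEG output and is accounted for in the generator (below).

## Orthologous LCRs and flanks

Each species' LCRs are projected into the column space of the protein
multiple alignment.  A 1-to-1 orthologous group requires exactly one LCR
from each of the five species with every pairwise column-overlap fraction
(intersection over the shorter span) ≥ 0.5; matching is greedy by mean
overlap.  No separate sequence-identity cutoff is applied: column overlap
after alignment already encodes positional identity, and the aligned
identity of matched spans is available downstream if wanted.

Flanks are codon-column runs adjacent to a matched LCR, one object per
side, truncated at the shortest of: a configured maximum (default 1500 nt),
the protein terminus, and the midpoint of the gap to the nearest other
matched LCR on that side.  Flanks shorter than 300 nt are discarded.  An
alternative "exclude" rule — drop a flank entirely when another LCR lies
closer than twice the maximum flank length — is selectable by a config
switch; the midpoint rule is the default because it retains data without
letting two LCRs' flanks share columns.  Columns where any species is
gapped are kept but flagged; substitution statistics skip them, the gap
profile is computed from them.

Distances are measured in codons from the LCR boundary column, 1-based at
the adjacent codon, negative upstream; nucleotide distance within the
codon at codon distance d is `3(d-1) + offset`, offset 1..3.

## Per-codon substitutions and site dN/dS

Substitution counts per codon column come from Fitch small parsimony on
the fixed species tree `(((human, chimpanzee), gorilla), orangutan,
macaque)`, applied independently to the three codon positions.  This
replaces a full ML branch-model fit: per site, with five taxa at primate
divergences, the parsimony count and the ML expected count nearly
coincide, and the downstream statistic is a per-distance average where the
difference is far below the Monte-Carlo noise.  Default branch lengths
(0.004 each for human and chimpanzee, 0.004 their stem, 0.008 gorilla,
0.012 great-ape stem, 0.02 orangutan, 0.03 macaque; expected substitutions
per codon site) are round primate-scale numbers and configurable.

The synonymous/nonsynonymous split enumerates every equally parsimonious
codon-level ancestral reconstruction (product of per-position minimal
labelings, restricted to sense codons; capped at 2000 reconstructions) and
averages, per branch change of more than one nucleotide, over all
single-step orderings that avoid stop codons (Nei–Gojobori pathway
averaging).  If every pathway transits a stop, stop-transiting pathways
are used and the site flagged.  By construction `k_syn + k_nonsyn` equals
the parsimony count exactly.

Site omega is `(k_nonsyn / N̄) / (k_syn / S̄)` with N̄, S̄ the mean
Nei–Gojobori site opportunities of the observed codons (equal mutation
rates; mutations to stops excluded and fractions renormalised so
S̄ + N̄ = 3 per codon).  Omega is undefined at k = 0 and coded +inf when
all changes are nonsynonymous; +inf competes only in the upper tail of the
null.

## Neutral null and selection calls

The reference distribution of omega is built by evolving single codons
down the same tree under a neutral (omega = 1) Markov codon model with
transition/transversion ratio kappa = 2, stop codons forbidden, uniform
sense-codon root (empirical frequencies optional), and pushing each
simulated column through the identical estimator chain.  Draws are binned
by their realised parsimony count k; a bin supports classification only
with ≥ 1000 draws.  Because high-k columns are rare at primate divergence,
draws are split over tree copies scaled ×1, ×4 and ×16: conditioned on k,
the omega distribution is essentially invariant to a uniform rescaling
(given k, changes fall on branches proportionally to length and the jump
chain is time-scale free), so the higher scales populate high-k bins
cheaply.  Each bin uses the lowest scale that fills it, pooling only as a
last resort; the calibration test verifies the conditioning empirically.

Conditioned on small k the null is highly discrete — at k = 1, omega is 0
or +inf — so fixed quantile cutoffs cannot give an exact test.  Selection
calls therefore use the randomised (exact) form of the empirical tail
test: an observation strictly inside an alpha/2 tail is always flagged,
and an observation on the boundary atom is flagged with the residual
probability, making the type-I rate exactly alpha among assessable sites.
The randomisation consumes a seeded generator, so calls are reproducible;
without a generator the conservative non-randomised call is made.
"negative" additionally requires omega < 1 and "positive" omega > 1.
Two-sided alpha defaults to 0.05 (2.5% per tail).

For the human population sample no tree is available; substitution
profiles instead use the mean over all n(n-1)/2 pairwise codon
comparisons per site, split syn/nonsyn by the same pathway averaging
(computed from codon multiplicities, so the cost is per distinct allele
pair, not per sequence pair).

## Tajima's D and the fixed-S null

Per codon of the population sample, `D = (π − S/a1) / sqrt(e1 S + e2 S
(S−1))` with the standard constants; undefined at S = 0.  Significance is
an add-one empirical tail probability against neutral fragments simulated
with the same n, L and S: a Kingman genealogy (exponential waiting times
at rate k(k−1)/2), then exactly S mutations placed on branches with
probability proportional to branch length, each on a distinct site
(infinite sites).  Genealogies are summarised per branch by subtended leaf
count and length, which is all the placement needs, keeping draws O(n).
An observed fragment can never have S > L, so the S > L code path (sites
reused, draws rejected until all L sites stay polymorphic) exists only
for completeness.  Tail p-values are one-sided in the direction of the
observed D; when calibration itself is being measured, ties with null
draws are broken uniformly at random (seeded), which makes null p-values
exactly uniform despite the discreteness of D given small S.
Benjamini–Hochberg (via statsmodels) is applied at FDR 0.05 separately
within the negative-D and positive-D strata, pooled over genes, since
per-sign proportions are profiled separately.

SNP ancestral states use outgroup parsimony: chimp and macaque bases
agreeing on a segregating allele resolve it; disagreeing outgroups resolve
only when exactly one matches a segregating allele and the other matches
neither; everything else (including any missing outgroup) is unresolved.
The derived-frequency/distance relationship is a Spearman rank correlation
over resolved SNPs.

## Profiles and correlations

Per signed distance (negative = upstream), the mean over contributing
flanks and the count N are tabulated; substitution statistics average over
usable (ungapped, stop-free) sites, selection proportions over assessable
sites, Tajima proportions over codons with defined D.  The gap profile is
the per-nucleotide fraction of flanks with ≥ 1 gapped species, the
denominator being flanks extending that far.  The headline statistic is
an unweighted Pearson r of per-distance mean against |distance|, pooling
both sides (side-stratified and N-weighted variants are also emitted),
with the usual two-sided t-test.  No minimum-N filter is applied per
distance; instead the default analysis window equals the dataset's nominal
flank length, because detection-boundary jitter otherwise contributes a
couple of distances supported by a single flank whose means have enormous
leverage on r.  A no-gap robustness variant repeats the correlation using
only flanks with zero gapped columns.  Nucleotide-composition correlations
compare, across genes, each base's frequency in the flank against the LCR
and against the whole CDS.

## Synthetic data

The generator emits the exact statistical structure the analysis is built
to detect, with full ground truth:

* Each gene is a root CDS of random sense codons around a repeat tract
  (default CAG×20, a detectable poly-Q LCR), evolved down the species
  tree.  Substitutions are proposed per codon at rate `mu · m(d) · t`,
  `m(d) = 1 + a · exp(−d/λ)` (defaults a = 3, λ = 50 codons, per side);
  proposals creating stops are dropped, nonsynonymous proposals accepted
  with probability min(1, omega) and synonymous with min(1, 1/omega)
  (default omega = 0.5, moderate purifying selection).
* Indels are whole-codon deletions at an independently decaying rate
  (default 0.05 per codon per unit branch length, same gradient shape):
  frame-preserving events are enough to exercise the gap statistics and
  keep the true alignment exact by construction.  Tract-length "slippage"
  (up to 3 codons per species) is confined to the tract so flank
  coordinates stay well defined.
* Each side additionally carries one detection window (15 codons) of
  margin beyond the nominal flank length, so that boundary smear does not
  shorten usable flanks below the nominal length.
* Population samples (default n = 178 haplotypes, echoing a large
  African-ancestry cohort) are neutral coalescent draws per codon with
  scaled mutation rate `theta · m(d)` (default theta = 0.01 per codon),
  using msprime for genealogies and mutation placement (binary model,
  no recombination); derived bases, outgroup bases (Jukes–Cantor flips at
  divergence 0.02 chimp / 0.06 macaque) and true ancestral states are
  assigned in-package.  At most one mutation is realised per site per
  codon.

Named study conditions: `flat` (a = 0 everywhere; type-I checks, 40
genes), `gradient` (a = 3, λ = 50, 200 genes, 100-codon nominal flanks),
`asymmetric` (a = 4 upstream vs 1.5 downstream, 120 genes), `gappy`
(tenfold indel rate, 60 genes).  Sizes are chosen so the full pipeline
runs in minutes on one core.

What passing tests show — and what they do not: the generator has
independent codons, no recombination, no demography, no codon-usage or
GC bias, frame-preserving indels only, and a single fixed tract per gene.
Recovery of the planted gradients therefore validates the estimator chain
and its calibration, not the biological conclusions on real genomes;
conversely, the population stage's derived-allele frequencies are
distance-independent by construction (neutral coalescent), so the
derived-frequency/distance correlation is expected near zero on synthetic
data even though the machinery computing it is fully exercised.

## Numerical and degenerate-input choices

* Parsimony enumeration is capped at 2000 reconstructions per column
  (deterministic prefix); at primate divergence the cap is never reached.
* Codon columns containing a gap or stop in any species are unusable;
  sites with k = 0 or an unsupported k are "not_assessable" and excluded
  from selection-proportion denominators.
* Empirical p-values are add-one, so p ∈ (0, 1] and a null draw can never
  be more extreme than itself "for free".
* All randomness flows from explicit seeds; identical config + seed gives
  byte-identical FASTA and TSV output (floats are written with a fixed
  `%.10g` format).
* Problem sizes in tests (e.g. 45,000 neutral-null draws, 5,000 fixed-S
  draws, 2,000 calibration columns) are the package's own choice of
  Monte-Carlo effort: large enough that calibration bands are a few
  percentage points wide, small enough to run interactively.

## Known limitations

* Parsimony undercounts at larger divergence; the tree-scaling trick in
  the neutral null conditions on the *parsimony* count, which keeps the
  classifier calibrated but means "k" is a lower bound on events.
* The single-threshold detector has no hysteresis, so marginal windows
  can fragment long heterogeneous LCRs into several intervals.
* The matcher is greedy; pathological overlap configurations could in
  principle be matched suboptimally (globally optimal matching is not
  attempted).
* Tajima's D codons are treated independently; linkage between codons of
  the same flank (shared genealogy) is real in the generator but ignored
  by the per-codon test, exactly as in per-codon scans of real data.
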