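# Methods

## Gene models and filtering

Records are read from GenBank flat files with Biopython; every CDS feature is
kept as annotated, including compound `join(...)`/`complement(...)` locations
(trans-spliced genes are processed exactly as their joins state) and both
copies of genes duplicated in the inverted repeat — published per-genome gene
totals are only reachable when IR copies count separately, so no
deduplication is attempted. Coordinates are 0-based half-open internally;
GenBank's 1-based inclusive convention exists only at the file boundary.
Origin-spanning genes on circular molecules arrive as two-part joins and need
no special casing.

Filters: pseudo-flagged CDS are excluded everywhere; a spliced length not
divisible by three excludes the model from all counts; both cases land in a
rejection log (accession, gene, reason). Codons containing an ambiguous base
are excluded from tallies but the gene is retained. The first triplet is
classified `typical_ATG` or `atypical:<triplet>`; the final triplet is
typical if in {TAA, TAG, TGA}; in-frame stops strictly between them are
counted as internal stops with their identities.

## Codon eligibility and the 59-SC universe

The analysis universe is the 59 synonymous codons (18 amino-acid families
with ≥ 2 codons; ATG and TGG excluded along with the three stops). For every
filtered gene the first and last codons, internal stops, internal ATG/TGG and
ambiguous codons are excluded from the eligible counts, each into its own
exclusion tally, so count conservation is checkable. The frequency
denominator is the 59-SC total by default, which makes the four
terminal-base frequencies (NNA/NNT/NNC/NNG) sum to exactly 1; a config
switch (`include_internal_atg`) reproduces the looser reading in which
internal Met codons stay in the denominator. This default was chosen for
internal consistency: a universe stated as "59 synonymous codons" cannot
contain ATG.

RSCU uses the standard Sharp–Li definition (count × family size / family
total); a family with zero total reports undefined rather than 0. CAI is the
count-weighted geometric mean of relative-adaptiveness weights; with no
external reference set the weights default to the table's own
`RSCU / RSCU_max` per family (an explicit `weights=` slot accepts an external
reference). Unused codons would give zero weights; they are floored at 0.01
and logged. Reports round to 3 decimals; machine-readable TSV/JSON keep full
precision. Exact ties when reporting extreme RSCU resolve to the
lexicographically smallest codon.

## Split codons and intron/exon resolution

A codon interrupted after its first nucleotide belongs to the downstream
exon; after its second, to the upstream exon. Both rules — and the degenerate
three-way split across a length-1 middle exon — reduce to "the exon
containing the codon's second nucleotide", which is the single rule
implemented and property-tested against a per-nucleotide phase walker.
Intron-class and exon-rank ratios pool raw codon counts across the genes of a
class (matching χ² testing on counts); a `gene_averaged` flag averages
per-gene ratios instead. Exon pooling uses mRNA rank (1st/2nd/3rd exon), not
genome order. Start/stop and otherwise-excluded codons remain in the
partition bookkeeping but never enter ratios.

## Methylation-context ratios

Second-position ratios NXG/NXC and the NCG/NCA ratio are computed on eligible
counts. Junction ratios NC|X/NG|X scan consecutive codon pairs within each
spliced CDS: the focal codon must be internal and one of the 59 SCs; the
successor must be internal but may be any codon (only its first base
matters). Junctions are evaluated in the mRNA frame, so intron-spanning
junctions count as contiguous — a caveat, since genomic CpG context at the
DNA level differs across an intron boundary; no genomic-context variant is
defined. Junctions never cross gene boundaries. All ratios carry raw
numerator/denominator counts so χ² tests run on counts, not ratios.

## Statistics

scipy.stats backs the χ² (no continuity correction by default — the codon
counts at stake are 10³–10⁴, where the correction is negligible; a flag
restores it), one/two-sample t (pooled variance by default, Welch behind a
flag), and Pearson procedures; Cronbach's α and the coefficient of variation
are direct formula implementations with sample (n−1) variances. All p-values
are two-sided and reported raw, without multiple-testing correction. A
one-sample t on an exactly constant vector equal to the reference mean
returns (0, p = 1); constant off the mean is an error.

## Ordination

Species are rows of 59-SC relative frequencies (each SC over the total SC
count; rows sum to 1) or RSCU values. Clustering: average linkage on
d = 1 − Pearson r via scipy, exported as newick through scikit-bio; scipy's
deterministic lowest-index tie-breaking applies. PCA: column-centred SVD
(covariance PCA) by default with a correlation-PCA flag, since ordination
claims should not depend on the choice; component signs are fixed so the
largest-magnitude loading is positive, and any separation claim in tests is
phrased sign-invariantly.

## Synthetic plastome generator

The generator emulates what matters to SCUB inference and nothing more:

* **Gene architecture** — configurable counts of 0/1/2-intron genes; the
  cotton preset uses {0: 70, 1: 11, 2: 4} (85 genes) and the wheat preset
  {0: 71, 1: 7, 2: 1} (79 genes), matching sequenced plastomes of those
  genera. Gene lengths are uniform on [0.6, 1.4] × 250 codons (~820 nt,
  the plastome average). Intron insertion points avoid 3 nt at each CDS end
  so termini stay clean while split-codon phases are exercised; intron
  sequences are random (40–120 nt). Roughly half the genes land on the minus
  strand; an optional origin-spanning gene exercises circular wrap-around.
* **Third-position bias** — codons are drawn amino acid first (uniform over
  the 18 families), then the synonymous choice ends in A/T with probability
  θ, uniformly within the chosen side. Every family has members on both
  sides, so the pooled NNC/G-to-NNA/T ratio converges to (1 − θ)/θ exactly.
  θ may be global, per exon rank (tuple), or per family (mapping).
  `heterogeneous_theta()` spreads θ evenly over 0.65–0.80 across families,
  giving per-family ratios ~0.25–0.54 around a pooled ~0.38 — the spread and
  magnitude real cotton/wheat plastomes show. The wheat preset shifts the
  spread slightly higher (0.66–0.82) and rotates which family gets which
  value, emulating both the genus-level difference in pooled SCUB frequency
  (~0.38 vs ~0.36) and the re-ranking of amino-acid preferences between taxa
  that makes correlation-distance ordination separate them.
* **Termini** — starts are ATG except with probability 0.012 (≈ one atypical
  start per genome, drawn from ACG/GTG, as annotated plastomes show); stops
  are uniform over TAA/TAG/TGA; internal stops are Poisson-inserted at a
  configurable per-gene rate (default 0 — they are rare in real plastomes).
* **CpG depletion** — after drawing, each internal C-ending SC followed by a
  G-starting internal codon is synonymously recoded C→T (same prefix, always
  synonymous by pyrimidine wobble) with the configured probability, thinning
  NC|G junctions by exactly that factor in expectation without touching
  anything else.

What the generator does **not** emulate: realistic intergenic sequence or IR
structure, tRNA/rRNA genes, empirical amino-acid composition (uniform by
default, configurable), RNA editing, or within-genus phylogenetic
autocorrelation — replicate synthetic genomes are independent draws, so
between-replicate Pearson r (~0.94) is lower than between real congeners
(~0.999), whose sequences are nearly identical by descent. Passing tests
therefore demonstrate correct computation and calibrated inference under the
stated sampling model, not that real plastomes satisfy that model.

## Problem sizes and numerical choices

The test suite and acceptance script run genus trios at full preset size
(~85 genes × 250 codons ≈ 20k eligible codons per genome), bias-recovery
sweeps with 10 replicate genomes per θ (~9k codons each), and depletion
contrasts with 10 replicates per level; all complete in seconds. Monte-Carlo
assertions use 3 standard errors across replicates. Undefined ratios (zero
denominators) are reported as undefined with their raw counts, never as 0 or
infinity; degenerate inputs (empty tables, zero-length exons, zero-variance
vectors) raise errors naming the offence.

## Known limitations

* CAI parity with CodonW depends on its reference set, which is not
  reproducible from a published table alone; self-derived weights are the
  default, so absolute CAI values are comparable within a run, not across
  tools.
* Whether published per-class ratios were codon-pooled or gene-averaged is
  ambiguous in the field; codon-pooled is the default here (it matches χ²
  on counts), gene-averaged is a flag.
* Junction ratios in the mRNA frame treat intron-spanning junctions as
  contiguous (see above).
* An origin-spanning single-exon gene is annotated as a two-part join and is
  therefore indistinguishable from a one-intron gene in intron-class tallies;
  real plastome annotations share this ambiguity.
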