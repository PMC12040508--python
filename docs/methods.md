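# Methods

## Scope and model

`repeatscope` genotypes short tandem repeats (STRs) from long reads that
span the repeat, interprets the calls against a locus catalog for the
spastic-ataxia spectrum, and triages annotated small variants. It assumes
the targeted-assay regime: reads of roughly fragment length (~30 kb)
centred loosely on a locus a few kilobases wide, so most reads cover the
repeat and both of its unique 150-bp flanking anchors. Assembly, polishing,
SNV-based phasing, methylation and structural-variant calling are outside
its scope; where a production pipeline would assemble and polish
haplotype contigs, this package substitutes deterministic desk-scale
equivalents described below.

## Locus catalog

A catalog row holds one locus: motif(s), copy-number bands, inheritance
mode, interpretation style and the two 150-nt anchors. Two interpretation
styles exist. *Purity-rule* loci (FGF14-like) are judged on the maximal
uninterrupted run of the canonical motif; *motif-catalog* loci (RFC1-like)
on which catalog motif the allele is built from and its total copy number.

The packaged catalog contains 21 loci: 15 named ataxia STR genes (ATXN1,
ATXN2, ATXN3, CACNA1A, ATXN7, PPP2R2B, TBP, FXN, ATN1, FMR1, FGF14, RFC1,
ATXN8OS, THAP11, ZFHX3) plus six further literature-standard ataxia STR
loci (ATXN10, NOP56, BEAN1, DAB1, NOTCH2NLC, GLS). The FGF14 bands are
normal ≤ 199, intermediate 200–249, pathogenic ≥ 250 pure GAA copies; all
other thresholds are standard diagnostic defaults, flagged as literature
defaults in the file header, including the RFC1 pathogenic minimum of
400 motif copies. The anchors in the packaged file are synthetic
deterministic 150-mers (seeded per locus id) standing in for
reference-extracted flanks; real anchors can be supplied in a user catalog.

## Read simulation

The simulator is the package's study-condition generator, not a nanopore
signal model. Per allele, the locus sequence is
`flank (5 kb random) | left anchor | repeat | right anchor | flank`; reads
are windows of length `min(read_length_mean, locus length)` (default
30 000 nt, so whole-locus by default; `round(coverage_per_allele)` reads
per allele in that case), strand uniform, with iid per-base errors:
mutually exclusive substitution (to a uniformly different base), single
base insertion and single-base deletion. Default error rates are zero;
robustness experiments use 0.4% substitutions + 0.3% insertions + 0.3%
deletions (~1% total, consensus-quality long-read territory). Output is a
pure function of (allele specs, config): a fixed seed reproduces FASTQ
bytes exactly. Not emulated: homopolymer-length biases, quality-correlated
errors, chimeras, coverage ramps — so passing simulations demonstrate
correctness of the estimator under idealised noise, not performance on raw
ONT data.

Packaged allele layouts pin the worked cases used in tests: `MIX616`
(GAA/GCA mixture, 616 units, longest pure GAA run 195 — interruption
positions are a package choice, every 100 units after the leading 195),
`FMR1_85` (85 CGG units with two single-AGG interruptions after units 10
and 21), `RFC1_P8` (AAGGG 651/693), `RFC1_P9` (AAGGG 1000 / ACAGG 2000)
and `FGF14_HET` (GAA 348/9).

## Size estimation from flank anchors

Anchors are located with edlib semi-global ("infix") alignment on both
strands; identity is `(150 − edit distance)/150` and hits under 0.80
identity are discarded (tolerant of ~15% read error while 150-mers stay
effectively unique). Edit-distance identity counts indels as mismatches,
which is marginally stricter than a match-count identity from unit-score
local alignment; at the 0.80 floor the difference is immaterial. Ties on
edit distance take the smallest start coordinate. A read is used when both
anchors are found forward-stranded and ordered in one of its two
orientations; the copy estimate is `round_half_away((right.start −
left.end)/k)`. Substitutions never move the estimate; insertion and
deletion errors shift a single read's distance by a few bases
(mean zero, sd ≈ √(L·(p_ins+p_del)) nt), which the per-cluster median
absorbs.

## Haplotype partitioning and consensus

Clustering is deliberately minimal: 1-D two-means on copy estimates,
centroids initialised at the observed min and max, ties to the lower
centroid — deterministic and order-independent. The split is collapsed to
one homozygous-appearing call when the cluster means differ by at most
`max(merge_min_gap, merge_rel × overall mean)` copies, defaults 5 and
0.05. The absolute term prevents noise-splitting of short homozygous
alleles; the relative term scales with expansion size. The relative
default (5%) is set between two constraints: a forced split of homozygous
indel noise separates means by well under 5% (indel scatter grows as
√length, not length), while the closest genuinely distinct allele pairs a
diagnostic assay must resolve differ by ~6% (651/693 pentamer copies;
213/201 GAA copies). Both parameters are exposed in the API. Equal-length
distinct alleles collapse to one call — a limitation of length-only
phasing, which does not use flank SNVs.

Each cluster's reported size is the rounded median of its copy estimates;
its consensus sequence is the medoid read segment (copy estimate closest
to the cluster median; ties to higher summed anchor identity, then
smallest read id). A medoid is deterministic and assembly-free, but it is
still a single read: at ~1% read error a truly pure expansion's maximal
pure run is underestimated on the medoid (expected pure stretches of
~1/(3·0.01) ≈ 33 units between error-broken runs). Consequently size and
motif calls are robust to read error, while purity-rule *categories* are
guaranteed only on error-free or consensus-quality input — matching
practice, where classification follows polishing.

## Motif decomposition

The reading frame (offset 0..k−1) maximises the count of units exactly
equal to a catalog motif as written, putting units in the catalog's
reporting form (GAA, not AAG); ties take the smallest offset. Units are
labelled with priority canonical motif → other catalog motifs (file
order) → `interrupt:<unit>` for units one substitution off the canonical
motif → `other`. Any non-canonical unit breaks a pure run (conservative:
an interrupted expansion can never satisfy a purity threshold through its
interruptions). Interruption runs are non-canonical runs flanked by
canonical runs on both sides. Conservation holds by construction:
`total_units·k + leftover + frame_offset = len(sequence)`.

For loci whose catalog mixes motif lengths (RFC1: pentamers plus the
AAAGGG hexamer) the sequence is parsed once per length and the parse with
the highest exact-match fraction wins; ties prefer fewer runs (a pure
AAAGGG tract also tiles perfectly as alternating AAAGG/AAGGG pentamers,
but in many runs), then the canonical motif length. The winning parse's
dominant motif is the allele's motif call. Interrupting units count toward
total units, so a mixed expansion's total length includes its
interruptions.

## Classification

Purity-rule loci: pathogenic at `max_pure_canonical_run ≥ pathogenic_min`;
intermediate inside the locus band; otherwise, a total length above the
normal maximum with noncanonical content is non-pathogenic noncanonical;
else normal. Severity is monotone in the pure run. Motif-catalog loci:
pathogenic motif at/above the locus threshold → pathogenic; benign motif →
benign regardless of size (except AAAGG, benign only up to 500 copies and
flagged unknown above — its larger expansions are of unresolved
significance); non-catalog motif → unknown. Locus level: dominant loci are
positive with one pathogenic allele and intermediate-uncertain when the
best remaining allele is intermediate; recessive loci are positive only
with two pathogenic alleles, carrier with one, otherwise negative. A
homozygous-appearing call counts as two alleles of its classification.

## Variant triage

Retention criteria and gates are as listed in the README; numeric
boundaries are strict (`REVEL > 0.5`, `AF < 0.1`), ClinVar strings are
normalised case-insensitively with conflicting-interpretation records
mapped to uncertain, and the MANE/frequency gates are applied after the
criteria so a decision records which criteria would have matched. Phase
relations require a shared phase set: trans when haplotype assignments
differ, cis when equal, unknown otherwise (including unphased genotypes).

## Numerical and degenerate-input choices

Copy rounding is half-away-from-zero (symmetric under ±1-base indel
noise). Empty sequences decompose to zero runs; sequences shorter than k
are all leftover. Zero spanning reads, or fewer than `min_support = 3`,
produce a no-call report (exit 0 in the CLI) rather than an error.
Reported problem sizes throughout the tests and the acceptance script —
40× per allele, seeds 1..5, 1000-case property sweeps — are desk-scale
choices that keep every run deterministic and fast while giving the
medians and proportions enough support to be stable.

## Known limitations

Length-only phasing cannot separate equal-length alleles or detect
somatic mosaicism; the medoid consensus limits purity classification on
noisy input (above); anchors are assumed unique within the analysed
window, as targeted retrieval guarantees in practice; cohort-level
quantities (diagnostic yield, per-cohort coverage) depend on patient data
and are not computable from this package.
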