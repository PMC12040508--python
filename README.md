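# repeatscope

Targeted long-read STR genotyping and small-variant triage for
spastic-ataxia spectrum disorders.

Hereditary cerebellar ataxias and spastic paraplegias are frequently caused
by short-tandem-repeat (STR) expansions — most commonly the GAA repeat in
*FGF14* (SCA27B) and the biallelic pentamer expansion in *RFC1* (CANVAS) —
whose pathogenicity depends not only on repeat length but on motif
composition and interruptions. Long reads that span an entire repeat let
both be read directly. `repeatscope` implements that analysis for reads
from a targeted long-read assay (or its built-in simulator):

- **Size from flank anchors.** Each catalog locus carries two unique 150-bp
  flanking anchors. Both anchors are located on each read by semi-global
  alignment (both strands); for a spanning read the intervening distance
  *d* between the anchors gives the per-read copy estimate
  `round(d / k)` for motif length *k*.
- **Haplotype partitioning.** Per-read estimates are split into up to two
  allele clusters by 1-D two-means; a merge rule collapses splits smaller
  than `max(5, 0.05 × mean)` copies into a homozygous-appearing call. Each
  cluster reports the rounded median as the allele size and its medoid read
  segment as the consensus sequence.
- **Motif decomposition.** The consensus is cut into k-nt units in the
  best reading frame, each unit labelled rotation-invariantly with a catalog
  motif, an `interrupt:<unit>` label (one substitution off the canonical
  motif) or `other`, and run-length encoded — the encoding is exactly a
  sequence bar chart. Derived quantities: total units, per-motif
  composition, and the maximal uninterrupted canonical run.
- **Classification.** Purity-rule loci (*FGF14*): pathogenic when the max
  pure GAA run ≥ 250, uncertain in 200–249, and a long but interrupted
  expansion (e.g. a 616-unit GAA/GCA mixture with a 195-copy pure run) is
  non-pathogenic noncanonical. Motif-catalog loci (*RFC1*): pathogenic
  motifs (AAGGG, ACAGG) above the locus threshold vs benign motifs (AAAAG,
  AAGAG, AAAGGG); disease requires both alleles pathogenic (recessive), one
  suffices for dominant loci.
- **Variant triage.** Annotated small variants are retained when they meet
  any of: (i) ClinVar pathogenic/likely pathogenic/uncertain, (ii)
  frameshift, (iii) missense with REVEL > 0.5, (iv) HIGH/MODERATE impact —
  gated on MANE Select membership and population allele frequency < 0.1.
  Phased genotypes give the trans/cis relation of candidate compound
  heterozygotes.

## Worked example

```bash
python examples/genotype_simulated_sample.py
```

simulates a heterozygous *FGF14* sample (348 and 9 GAA copies, 40 spanning
reads per allele) and genotypes it:

```
locus FGF14: heterozygous, 80/80 spanning reads
  allele 1: 9 copies (median 9.0, MAD 0.0, 40 reads), motif GAA, category normal
  allele 2: 348 copies (median 348.0, MAD 0.0, 40 reads), motif GAA, category pathogenic
diagnostic status: positive
```

The 348-copy pure GAA allele exceeds the 250-copy threshold, so this
dominant locus is called positive. `examples/decompose_mixed_expansion.py`
shows the opposite case — a 616-unit mixed GAA/GCA expansion whose longest
pure run is only 195 copies, hence *not* pathogenic — plus an 85-unit
*FMR1* CGG tract with two AGG interruptions; and
`examples/prioritize_variants.py` walks the variant-triage rules and calls
a phased pathogenic pair *in trans*.

The same workflow is available as a CLI:

```bash
repeatscope simulate --locus RFC1 --fixture RFC1_P9 --coverage 40 --seed 1 \
    --sub-rate 0.004 --ins-rate 0.003 --del-rate 0.003 \
    --out-fastq reads.fastq --out-truth truth.json
repeatscope genotype --locus RFC1 --reads reads.fastq --out genotype.json
repeatscope prioritize --vcf annotated.vcf --out-decisions decisions.tsv
```

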