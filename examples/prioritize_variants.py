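"""Filter a handful of annotated variants and phase a compound heterozygote.

Applies the four retention criteria (ClinVar significance, frameshift,
missense with REVEL > 0.5, HIGH/MODERATE impact) plus the MANE Select and
allele-frequency (< 0.1) gates, then reads the trans/cis relation of the
two retained pathogenic variants off their phased genotypes.
"""

from repeatscope import AnnotatedVariant, filter_variants, phase_relation

variants = [
    # missense + nonsense pair in one gene, phased onto opposite haplotypes
    AnnotatedVariant("16", 89574804, "G", "A", consequence="missense_variant",
                     impact="MODERATE", is_missense=True, revel=0.83,
                     clinvar_significance="pathogenic", mane_select=True,
                     genotype_phase="haplotype1", phase_set="89500000"),
    AnnotatedVariant("16", 89576898, "C", "CA", consequence="frameshift_variant",
                     impact="HIGH", is_frameshift=True,
                     clinvar_significance="pathogenic", mane_select=True,
                     genotype_phase="haplotype2", phase_set="89500000"),
    # common missense: killed by the frequency gate despite REVEL 0.9
    AnnotatedVariant("2", 500, "T", "C", is_missense=True, revel=0.9,
                     allele_frequency=0.2, mane_select=True, impact="MODERATE"),
    # benign synonymous change: no criterion matches
    AnnotatedVariant("3", 900, "G", "A", consequence="synonymous_variant",
                     impact="LOW", clinvar_significance="benign", mane_select=True),
]

retained, decisions = filter_variants(variants)
for v, d in zip(variants, decisions):
    verdict = "retained via (" + ",".join(d.matched_criteria) + ")" if d.retained \
        else f"excluded: {d.exclusion_reason}"
    print(f"{v.chrom}:{v.pos} {v.ref}>{v.alt}  {verdict}")

v1, v2 = retained
print(f"phase relation of the retained pair: {phase_relation(v1, v2)}")
# "trans" means the two variants sit on different haplotypes of one phase
# set — together they inactivate both copies of a recessive gene.
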