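"""Motif-decompose two interrupted repeat alleles and print their bar-chart runs.

The first allele is a mixed GAA/GCA expansion of 616 total units whose
longest pure GAA stretch is 195 copies — expanded far past the FGF14
pathogenic threshold in total length, yet not pathogenic because no
uninterrupted GAA run reaches 250. The second is an 85-unit FMR1 CGG tract
with two single-AGG interruptions.
"""

from repeatscope import (barplot_encoding, build_allele_sequence, classify_allele,
                         decompose, get_locus, load_default_catalog)
from repeatscope.simulate import FIXTURES

catalog = load_default_catalog()

for fixture, locus_id in (("MIX616", "FGF14"), ("FMR1_85", "FMR1")):
    locus = get_locus(catalog, locus_id)
    seq = build_allele_sequence(FIXTURES[fixture])
    result = decompose(seq, locus)
    cls = classify_allele(locus, result)
    print(f"{fixture} ({locus_id}): {result.total_units} units, "
          f"max pure {locus.canonical_motif} run {result.max_pure_canonical_run}, "
          f"{result.interruption_runs} interruption run(s) -> {cls.category}")
    print("  runs:", " | ".join(f"{label}x{copies}"
                                for label, copies in barplot_encoding(result)))
# Each "motif x copies" element is one bar of the sequence bar chart; the
# interrupt: prefix marks units one substitution away from the canonical motif.
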