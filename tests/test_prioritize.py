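"""Variant retention criteria, gates and phase relations."""

import textwrap

import pytest
from hypothesis import given, settings, strategies as st

from repeatscope import (AnnotatedVariant, filter_variants, phase_relation,
                         qualifies, read_annotated_vcf)
from repeatscope.prioritize import normalize_clinvar


def variant(**kw):
    base = dict(chrom="1", pos=100, ref="A", alt="G", mane_select=True)
    base.update(kw)
    return AnnotatedVariant(**base)


def test_clinvar_criterion_i():
    for sig in ("pathogenic", "likely_pathogenic", "uncertain"):
        d = qualifies(variant(clinvar_significance=sig))
        assert d.retained and "i" in d.matched_criteria
    d = qualifies(variant(clinvar_significance="benign"))
    assert not d.retained and d.exclusion_reason == "no criterion matched"


def test_frameshift_criterion_ii():
    d = qualifies(variant(is_frameshift=True, allele_frequency=0.0001))
    assert d.retained and d.matched_criteria == ("ii",)


def test_missense_revel_criterion_iii():
    d = qualifies(variant(is_missense=True, revel=0.6))
    assert d.retained and "iii" in d.matched_criteria
    # REVEL strictly greater than 0.5: the boundary itself does not qualify
    d = qualifies(variant(is_missense=True, revel=0.5, impact="MODERATE"))
    assert d.retained and d.matched_criteria == ("iv",)
    # benign ClinVar blocks (iii) even with a high REVEL
    d = qualifies(variant(is_missense=True, revel=0.9, clinvar_significance="benign"))
    assert not d.retained


def test_impact_criterion_iv():
    for impact in ("HIGH", "MODERATE"):
        d = qualifies(variant(impact=impact))
        assert d.retained and "iv" in d.matched_criteria
    assert not qualifies(variant(impact="LOW")).retained


def test_af_gate_strictly_below_point_one():
    assert qualifies(variant(is_frameshift=True, allele_frequency=0.0999)).retained
    d = qualifies(variant(is_frameshift=True, allele_frequency=0.1))
    assert not d.retained and d.exclusion_reason == "allele_frequency"
    assert not qualifies(variant(is_missense=True, revel=0.9, allele_frequency=0.2)).retained
    # absent from the population database passes the gate
    assert qualifies(variant(is_frameshift=True, allele_frequency=None)).retained


def test_mane_gate_applied_after_criteria():
    d = qualifies(variant(is_frameshift=True, mane_select=False))
    assert not d.retained
    assert d.matched_criteria == ("ii",)  # criteria still reported
    assert "MANE" in d.exclusion_reason


def test_revel_grid_boundary():
    grid = [round(i * 0.01, 2) for i in range(101)]
    excluded = [r for r in grid
                if not qualifies(variant(is_missense=True, impact="LOW", revel=r)).retained]
    assert max(excluded) == 0.5


def test_af_grid_boundary():
    grid = [round(i * 0.001, 3) for i in range(201)]
    excluded = [a for a in grid
                if not qualifies(variant(is_frameshift=True, allele_frequency=a)).retained]
    assert min(excluded) == 0.1


def test_filter_preserves_order_and_idempotent():
    records = [
        variant(pos=10, is_frameshift=True),
        variant(pos=20, clinvar_significance="benign"),
        variant(pos=30, is_missense=True, revel=0.8),
        variant(pos=40, impact="LOW"),
    ]
    retained, decisions = filter_variants(records)
    assert [v.pos for v in retained] == [10, 30]
    assert len(decisions) == 4
    again, _ = filter_variants(retained)
    assert again == retained
    assert filter_variants([]) == ([], [])


@given(st.floats(min_value=0.0, max_value=0.0999))
@settings(derandomize=True, max_examples=50)
def test_af_monotonicity(af):
    # lowering the frequency of a retained variant never causes exclusion
    assert qualifies(variant(is_frameshift=True, allele_frequency=af)).retained


@pytest.mark.parametrize("raw,expected", [
    ("Pathogenic", "pathogenic"),
    ("Likely pathogenic", "likely_pathogenic"),
    ("Uncertain_significance", "uncertain"),
    ("Conflicting_interpretations_of_pathogenicity", "uncertain"),
    ("Benign/Likely_benign", "likely_benign"),
    (None, "none"),
])
def test_clinvar_normalization(raw, expected):
    assert normalize_clinvar(raw) == expected


def test_phase_relation():
    v1 = variant(genotype_phase="haplotype1", phase_set="PS1")
    v2 = variant(pos=200, genotype_phase="haplotype2", phase_set="PS1")
    v3 = variant(pos=300, genotype_phase="haplotype1", phase_set="PS1")
    v4 = variant(pos=400, genotype_phase="haplotype1", phase_set="PS2")
    v5 = variant(pos=500, genotype_phase="unphased", phase_set=None)
    assert phase_relation(v1, v2) == "trans"
    assert phase_relation(v1, v3) == "cis"
    assert phase_relation(v1, v4) == "unknown"
    assert phase_relation(v1, v5) == "unknown"
    for a in (v1, v2, v3, v4, v5):
        for b in (v1, v2, v3, v4, v5):
            assert phase_relation(a, b) == phase_relation(b, a)


VCF_TEMPLATE = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=16>
    ##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar significance">
    ##INFO=<ID=REVEL,Number=1,Type=Float,Description="REVEL score">
    ##INFO=<ID=AF,Number=1,Type=Float,Description="gnomAD allele frequency">
    ##INFO=<ID=IMPACT,Number=1,Type=String,Description="consequence impact">
    ##INFO=<ID=Consequence,Number=1,Type=String,Description="consequence term">
    ##INFO=<ID=MANE,Number=1,Type=String,Description="MANE Select flag">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
    {rows}
    """)

# the SPG7-style compound heterozygote: a missense and a nonsense change in
# one phase set on opposite haplotypes
SPG7_ROWS = "\n".join([
    "16\t89574804\t.\tG\tA\t50\tPASS\t"
    "CLNSIG=Pathogenic;REVEL=0.83;IMPACT=MODERATE;Consequence=missense_variant;MANE=1\t"
    "GT:PS\t1|0:89500000",
    "16\t89576898\t.\tC\tCA\t50\tPASS\t"
    "CLNSIG=Pathogenic;IMPACT=HIGH;Consequence=frameshift_variant;MANE=1\t"
    "GT:PS\t0|1:89500000",
])


def test_vcf_round_trip_and_trans_phasing(tmp_path):
    path = tmp_path / "spg7.vcf"
    path.write_text(VCF_TEMPLATE.format(rows=SPG7_ROWS))
    variants = read_annotated_vcf(path)
    assert len(variants) == 2
    v1, v2 = variants
    assert v1.is_missense and v1.revel == pytest.approx(0.83)
    assert v2.is_frameshift and v2.impact == "HIGH"
    assert v1.clinvar_significance == "pathogenic"
    retained, decisions = filter_variants(variants)
    assert len(retained) == 2
    assert phase_relation(v1, v2) == "trans"


def test_vcf_missing_annotations_tolerated(tmp_path):
    rows = "16\t100\t.\tA\tT\t50\tPASS\tIMPACT=LOW;Consequence=synonymous_variant\tGT:PS\t0/1:."
    path = tmp_path / "sparse.vcf"
    path.write_text(VCF_TEMPLATE.format(rows=rows))
    (v,) = read_annotated_vcf(path)
    assert v.revel is None and v.allele_frequency is None
    assert v.genotype_phase == "unphased"
    assert not qualifies(v).retained


def test_invalid_record_rejected():
    with pytest.raises(ValueError):
        variant(ref="")
    with pytest.raises(ValueError):
        variant(pos=0)
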