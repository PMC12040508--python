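"""Allele- and locus-level interpretation rules."""

import pytest

from repeatscope import (build_allele_sequence, classify_allele, classify_locus,
                         decompose)
from repeatscope.classify import AlleleClassification, severity
from repeatscope.simulate import FIXTURES, AlleleSpec


def gaa(n):
    return AlleleSpec((("GAA", n),)) if n else AlleleSpec((), label="null_allele")


def classify_pure_gaa(fgf14, n):
    return classify_allele(fgf14, decompose("GAA" * n, fgf14))


@pytest.mark.parametrize("copies,expected", [
    (274, "pathogenic"),     # smallest expansion in the diagnosed series
    (425, "pathogenic"),
    (250, "pathogenic"),
    (249, "intermediate"),
    (240, "intermediate"),   # positive-control case near the threshold
    (200, "intermediate"),
    (199, "normal"),
    (9, "normal"),
])
def test_fgf14_pure_gaa_bands(fgf14, copies, expected):
    assert classify_pure_gaa(fgf14, copies).category == expected


def test_threshold_sweep_boundaries(fgf14):
    """Category boundaries over 1..400 pure GAA copies fall exactly at the bands."""
    categories = {n: classify_pure_gaa(fgf14, n).category for n in range(1, 401)}
    assert min(n for n, c in categories.items() if c == "pathogenic") == 250
    inter = [n for n, c in categories.items() if c == "intermediate"]
    assert (min(inter), max(inter)) == (200, 249)
    assert all(categories[n] == "normal" for n in range(1, 200))
    assert all(categories[n] == "pathogenic" for n in range(250, 401))


def test_monotone_in_pure_run(fgf14):
    # severity never decreases as the pure run grows
    prev = -1
    for n in range(1, 401, 7):
        s = severity(classify_pure_gaa(fgf14, n).category)
        assert s >= prev
        prev = s


def test_mixed_expansion_not_pathogenic(fgf14):
    d = decompose(build_allele_sequence(FIXTURES["MIX616"]), fgf14)
    c = classify_allele(fgf14, d)
    assert c.category == "non_pathogenic_noncanonical"
    assert c.basis_value == 195


def test_rfc1_allele_rules(rfc1):
    cases = [
        ("AAGGG", 651, "pathogenic"),
        ("ACAGG", 2000, "pathogenic"),
        ("AAGGG", 100, "normal"),       # pathogenic motif below size threshold
        ("AAAAG", 800, "benign_motif"),
        ("AAGAG", 900, "benign_motif"),
        ("AAAGGG", 700, "benign_motif"),
        ("AAAGG", 300, "benign_motif"),
    ]
    for motif, copies, expected in cases:
        d = decompose(motif * copies, rfc1)
        c = classify_allele(rfc1, d)
        assert (c.category, c.motif_call) == (expected, motif), (motif, copies)


def test_rfc1_large_aaagg_is_unresolved(rfc1):
    d = decompose("AAAGG" * 800, rfc1)
    with pytest.warns(UserWarning):
        c = classify_allele(rfc1, d)
    assert c.category == "unknown_motif"


def test_rfc1_noncatalog_motif_unknown(rfc1):
    d = decompose("CCGGT" * 300, rfc1)
    assert classify_allele(rfc1, d).category == "unknown_motif"


def allele(category, motif="GAA"):
    return AlleleClassification(category, "max_pure_canonical_run", 0, motif)


def test_biallelic_rfc1_genotypes(rfc1):
    path, benign = allele("pathogenic", "AAGGG"), allele("benign_motif", "AAAAG")
    assert classify_locus(rfc1, [path, path], "heterozygous").diagnostic_status == "positive"
    assert classify_locus(rfc1, [path, benign], "heterozygous").diagnostic_status == "carrier"
    assert classify_locus(rfc1, [benign, benign], "heterozygous").diagnostic_status == "negative"
    # homozygous-appearing pathogenic counts as two pathogenic alleles
    assert classify_locus(rfc1, [path], "homozygous_appearing").diagnostic_status == "positive"


def test_monoallelic_fgf14_genotypes(fgf14):
    path, normal = allele("pathogenic"), allele("normal")
    inter = allele("intermediate")
    assert classify_locus(fgf14, [path, normal], "heterozygous").diagnostic_status == "positive"
    assert classify_locus(fgf14, [inter, inter], "heterozygous").diagnostic_status == \
        "intermediate_uncertain"
    assert classify_locus(fgf14, [normal, normal], "heterozygous").diagnostic_status == "negative"
    assert classify_locus(fgf14, [], "no_call").diagnostic_status == "no_call"


def test_classify_locus_symmetric_in_allele_order(fgf14, rfc1):
    for locus in (fgf14, rfc1):
        for a, b in [(allele("pathogenic"), allele("normal")),
                     (allele("intermediate"), allele("pathogenic")),
                     (allele("benign_motif"), allele("pathogenic"))]:
            assert classify_locus(locus, [a, b], "heterozygous").diagnostic_status == \
                classify_locus(locus, [b, a], "heterozygous").diagnostic_status


def test_end_to_end_biallelic_intermediate(fgf14):
    # the 213/201 genotype: both alleles in the uncertain band
    d1 = decompose("GAA" * 213, fgf14)
    d2 = decompose("GAA" * 201, fgf14)
    res = classify_locus(fgf14, [classify_allele(fgf14, d1), classify_allele(fgf14, d2)],
                         "heterozygous")
    assert res.diagnostic_status == "intermediate_uncertain"
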