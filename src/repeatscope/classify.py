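"""Locus-specific interpretation of allele calls and diploid genotypes.

Purity-rule loci (FGF14-style) are classified on the maximal uninterrupted
canonical run of the allele: at or above the pathogenic threshold the
allele is pathogenic; inside the locus's intermediate band it is of
uncertain significance; an expanded allele (total units above the normal
maximum) whose pure run stays below the bands is a non-pathogenic
noncanonical expansion (e.g. a long GAA/GCA mixture); anything else is
normal.

Motif-catalog loci (RFC1-style) are classified on which motif the allele
is built from: a pathogenic motif (AAGGG, ACAGG) expanded past the locus
threshold is pathogenic, a benign motif (AAAAG, AAGAG, AAAGGG) is benign
regardless of length, and a motif absent from the catalog is reported as
unknown. AAAGG is treated as benign only up to a size cap; larger AAAGG
expansions are of unresolved significance and are flagged unknown.

At the locus level, dominant (monoallelic) diseases need one pathogenic
allele for a positive call; recessive (biallelic) diseases need two, with
a single pathogenic allele reported as carrier status. A homozygous-
appearing call counts as two alleles of the same classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .catalog import StrLocusDefinition
from .decompose import DecompositionResult

# AAAGG expansions are benign when modest; large ones are unresolved.
AAAGG_BENIGN_MAX_COPIES = 500

CATEGORIES = ("normal", "intermediate", "pathogenic",
              "non_pathogenic_noncanonical", "benign_motif", "unknown_motif")

_SEVERITY = {"normal": 0, "benign_motif": 0, "non_pathogenic_noncanonical": 0,
             "unknown_motif": 0, "intermediate": 1, "pathogenic": 2}


@dataclass(frozen=True)
class AlleleClassification:
    category: str
    basis: str        # which quantity drove the call
    basis_value: int
    motif_call: str


@dataclass(frozen=True)
class LocusGenotypeResult:
    locus_id: str
    alleles: tuple[AlleleClassification, ...]
    zygosity: str  # heterozygous | homozygous_appearing | single_allele
    diagnostic_status: str  # positive | carrier | intermediate_uncertain | negative | no_call


def classify_allele(locus: StrLocusDefinition,
                    decomposition: DecompositionResult) -> AlleleClassification:
    """Classify one allele from the motif parse of its consensus sequence."""
    if locus.purity_rule:
        pure = decomposition.max_pure_canonical_run
        total = decomposition.total_units
        if locus.pathogenic_min_copies is None and locus.intermediate_range is None:
            warnings.warn(f"{locus.locus_id}: no thresholds defined; allele unclassified")
            return AlleleClassification("unknown_motif", "max_pure_canonical_run",
                                        pure, decomposition.motif_call)
        if locus.pathogenic_min_copies is not None and pure >= locus.pathogenic_min_copies:
            category = "pathogenic"
        elif (locus.intermediate_range is not None
              and locus.intermediate_range[0] <= pure <= locus.intermediate_range[1]):
            category = "intermediate"
        elif total > locus.normal_max_copies and pure < total:
            # expanded overall, but interrupted/noncanonical content keeps the
            # pure canonical run below the disease bands
            category = "non_pathogenic_noncanonical"
        else:
            category = "normal"
        return AlleleClassification(category, "max_pure_canonical_run", pure,
                                    decomposition.motif_call)

    # Motif-catalog locus: judged on the called motif and its total copies.
    motif = decomposition.motif_call
    copies = decomposition.composition.get(motif, 0)
    if motif == "other" or motif not in locus.catalog_motifs:
        return AlleleClassification("unknown_motif", "motif_copies", copies, motif)
    if motif == "AAAGG" and copies > AAAGG_BENIGN_MAX_COPIES:
        warnings.warn(f"{locus.locus_id}: AAAGG expansion of {copies} copies exceeds "
                      f"the benign size cap; significance unresolved")
        return AlleleClassification("unknown_motif", "motif_copies", copies, motif)
    if motif in locus.benign_motifs:
        return AlleleClassification("benign_motif", "motif_copies", copies, motif)
    if motif in locus.pathogenic_motifs:
        if locus.pathogenic_min_copies is not None and copies >= locus.pathogenic_min_copies:
            return AlleleClassification("pathogenic", "motif_copies", copies, motif)
        return AlleleClassification("normal", "motif_copies", copies, motif)
    return AlleleClassification("unknown_motif", "motif_copies", copies, motif)


def classify_locus(locus: StrLocusDefinition,
                   alleles: Sequence[AlleleClassification],
                   zygosity: str) -> LocusGenotypeResult:
    """Combine allele classifications into a diploid diagnostic status."""
    if not alleles:
        return LocusGenotypeResult(locus.locus_id, (), zygosity, "no_call")
    effective = list(alleles)
    if zygosity == "homozygous_appearing" and len(effective) == 1:
        effective = effective * 2
    n_pathogenic = sum(1 for a in effective if a.category == "pathogenic")
    n_intermediate = sum(1 for a in effective if a.category == "intermediate")
    if locus.inheritance == "monoallelic":
        if n_pathogenic >= 1:
            status = "positive"
        elif n_intermediate >= 1:
            status = "intermediate_uncertain"
        else:
            status = "negative"
    else:  # biallelic: disease requires pathogenic expansions on both alleles
        if n_pathogenic >= 2:
            status = "positive"
        elif n_pathogenic == 1:
            status = "carrier"
        else:
            status = "negative"
    return LocusGenotypeResult(locus.locus_id, tuple(alleles), zygosity, status)


def severity(category: str) -> int:
    """Ordering used by the monotonicity contract: normal < intermediate < pathogenic."""
    return _SEVERITY[category]
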