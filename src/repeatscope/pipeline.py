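"""End-to-end genotyping of one STR locus from reads to diagnostic status."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional, Sequence

from .catalog import StrLocusDefinition
from .classify import AlleleClassification, LocusGenotypeResult, classify_allele, classify_locus
from .decompose import DecompositionResult, barplot_encoding, decompose
from .extraction import DEFAULT_MIN_IDENTITY, ExtractionSummary, extract_all
from .haplotyping import DEFAULT_MIN_SUPPORT, HaplotypeCluster, NoCallError, call_haplotypes


@dataclass
class AlleleReport:
    cluster: HaplotypeCluster
    decomposition: DecompositionResult
    classification: AlleleClassification

    @property
    def barplot(self) -> list[tuple[str, int]]:
        return barplot_encoding(self.decomposition)


@dataclass
class GenotypeReport:
    locus_id: str
    alleles: list[AlleleReport]
    zygosity: str
    diagnostic_status: str
    extraction: ExtractionSummary
    no_call_reason: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "locus_id": self.locus_id,
            "zygosity": self.zygosity,
            "diagnostic_status": self.diagnostic_status,
            "no_call_reason": self.no_call_reason,
            "extraction": dataclasses.asdict(self.extraction),
            "alleles": [
                {
                    "allele_index": a.cluster.allele_index,
                    "support": a.cluster.support,
                    "copies_median": a.cluster.copies_median,
                    "copies_mad": a.cluster.copies_mad,
                    "reported_copies": a.cluster.reported_copies,
                    "motif_call": a.classification.motif_call,
                    "category": a.classification.category,
                    "basis": a.classification.basis,
                    "basis_value": a.classification.basis_value,
                    "total_units": a.decomposition.total_units,
                    "max_pure_canonical_run": a.decomposition.max_pure_canonical_run,
                    "interruption_runs": a.decomposition.interruption_runs,
                    "barplot": a.barplot,
                }
                for a in self.alleles
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def genotype_locus(reads: Sequence[tuple[str, str]], locus: StrLocusDefinition,
                   min_identity: float = DEFAULT_MIN_IDENTITY,
                   min_support: int = DEFAULT_MIN_SUPPORT) -> GenotypeReport:
    """Genotype one locus: extract -> partition -> consensus -> parse -> classify.

    Zero spanning reads (or fewer than ``min_support``) yield a no_call
    report rather than an error.
    """
    segments, summary = extract_all(reads, locus, min_identity=min_identity)
    try:
        clusters = call_haplotypes(segments, locus, min_support=min_support)
    except NoCallError as exc:
        return GenotypeReport(locus.locus_id, [], "no_call", "no_call",
                              summary, no_call_reason=str(exc))
    allele_reports: list[AlleleReport] = []
    for cluster in clusters:
        decomposition = decompose(cluster.consensus_sequence, locus)
        classification = classify_allele(locus, decomposition)
        allele_reports.append(AlleleReport(cluster, decomposition, classification))
    zygosity = "heterozygous" if len(clusters) == 2 else "homozygous_appearing"
    locus_result = classify_locus(locus, [a.classification for a in allele_reports], zygosity)
    return GenotypeReport(locus.locus_id, allele_reports, zygosity,
                          locus_result.diagnostic_status, summary)
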