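"""Prioritisation of annotated small variants and phase-relation testing.

Candidate variants from an annotated VCF are retained when they satisfy at
least one of four criteria:

  (i)   ClinVar significance pathogenic, likely pathogenic or uncertain;
  (ii)  predicted frameshift;
  (iii) missense with REVEL > 0.5 and ClinVar pathogenic / likely
        pathogenic / uncertain / unassigned;
  (iv)  HIGH or MODERATE impact with the same ClinVar condition as (iii);

and then pass two gates applied to every retained variant: the variant
must lie in a MANE Select transcript, and its population allele frequency
must be absent (not seen in the population database) or strictly below
0.1. Criteria (iii) and (iv) overlap heavily for missense variants; both
memberships are reported.

For recessive genes, two heterozygous candidate variants only explain
disease when they sit on different haplotypes. With phased genotypes the
relation is read off directly: variants sharing a phase set are *in trans*
when their haplotype assignments differ and *in cis* when they agree;
variants in different phase sets (or unphased) are unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_CLINVAR_QUALIFYING = {"pathogenic", "likely_pathogenic", "uncertain"}
_CLINVAR_QUALIFYING_OR_NONE = _CLINVAR_QUALIFYING | {"none"}

AF_MAX = 0.1
REVEL_MIN = 0.5

DEFAULT_KEY_MAP = {
    "clinvar": "CLNSIG",
    "revel": "REVEL",
    "af": "AF",
    "impact": "IMPACT",
    "consequence": "Consequence",
    "mane": "MANE",
}


@dataclass(frozen=True)
class AnnotatedVariant:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    consequence: str = ""
    impact: str = "MODIFIER"
    is_missense: bool = False
    is_frameshift: bool = False
    clinvar_significance: str = "none"
    revel: Optional[float] = None
    allele_frequency: Optional[float] = None
    mane_select: bool = False
    genotype_phase: str = "unphased"  # haplotype1 | haplotype2 | unphased
    phase_set: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        for allele in (self.ref, self.alt):
            if not allele or any(c not in "ACGT" for c in allele.upper()):
                raise ValueError(f"ref/alt must be non-empty ACGT strings, got {allele!r}")


@dataclass(frozen=True)
class PrioritizationDecision:
    retained: bool
    matched_criteria: tuple[str, ...]
    exclusion_reason: Optional[str] = None


def normalize_clinvar(raw: Optional[str]) -> str:
    """Map a raw ClinVar significance string onto the five-level scale."""
    if not raw:
        return "none"
    s = raw.strip().lower().replace(" ", "_")
    if "conflicting" in s:
        return "uncertain"
    if "likely_pathogenic" in s:
        return "likely_pathogenic"
    if "likely_benign" in s:
        return "likely_benign"
    if "pathogenic" in s:
        return "pathogenic"
    if "benign" in s:
        return "benign"
    if "uncertain" in s or s == "vus":
        return "uncertain"
    return "none"


def qualifies(v: AnnotatedVariant) -> PrioritizationDecision:
    """Apply the four retention criteria and the MANE / frequency gates."""
    sig = normalize_clinvar(v.clinvar_significance)
    matched: list[str] = []
    if sig in _CLINVAR_QUALIFYING:
        matched.append("i")
    if v.is_frameshift:
        matched.append("ii")
    if v.is_missense and v.revel is not None and v.revel > REVEL_MIN \
            and sig in _CLINVAR_QUALIFYING_OR_NONE:
        matched.append("iii")
    if v.impact in ("HIGH", "MODERATE") and sig in _CLINVAR_QUALIFYING_OR_NONE:
        matched.append("iv")
    if not matched:
        return PrioritizationDecision(False, (), "no criterion matched")
    if not v.mane_select:
        return PrioritizationDecision(False, tuple(matched), "not in MANE Select transcript")
    if v.allele_frequency is not None and not v.allele_frequency < AF_MAX:
        return PrioritizationDecision(False, tuple(matched), "allele_frequency")
    return PrioritizationDecision(True, tuple(matched))


def filter_variants(records: Iterable[AnnotatedVariant],
                    ) -> tuple[list[AnnotatedVariant], list[PrioritizationDecision]]:
    """Order-preserving filter; one decision per input record."""
    retained: list[AnnotatedVariant] = []
    decisions: list[PrioritizationDecision] = []
    for v in records:
        d = qualifies(v)
        decisions.append(d)
        if d.retained:
            retained.append(v)
    return retained, decisions


def phase_relation(v1: AnnotatedVariant, v2: AnnotatedVariant) -> str:
    """Phase relation of two variants from one sample: trans, cis or unknown."""
    if (v1.phase_set is None or v2.phase_set is None
            or v1.phase_set != v2.phase_set
            or "unphased" in (v1.genotype_phase, v2.genotype_phase)):
        return "unknown"
    return "trans" if v1.genotype_phase != v2.genotype_phase else "cis"


# ---------------------------------------------------------------------------
# VCF I/O


def _info_str(rec, key: str) -> Optional[str]:
    val = rec.info.get(key)
    if val is None:
        return None
    if isinstance(val, (tuple, list)):
        val = val[0] if val else None
    return None if val is None else str(val)


def read_annotated_vcf(path: str | Path,
                       key_map: Optional[dict[str, str]] = None,
                       sample: Optional[str] = None) -> list[AnnotatedVariant]:
    """Read annotated variant records from a VCF.

    Annotations are taken from INFO fields named by ``key_map`` (defaults:
    CLNSIG, REVEL, AF, IMPACT, Consequence, MANE). Phase comes from the
    first (or named) sample's phased GT plus the PS tag.
    """
    import pysam

    keys = {**DEFAULT_KEY_MAP, **(key_map or {})}
    out: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_name = sample
        if sample_name is None and list(vcf.header.samples):
            sample_name = list(vcf.header.samples)[0]
        for rec in vcf:
            consequence = (_info_str(rec, keys["consequence"]) or "").lower()
            impact = (_info_str(rec, keys["impact"]) or "MODIFIER").upper()
            revel_raw = _info_str(rec, keys["revel"])
            af_raw = _info_str(rec, keys["af"])
            mane_raw = (_info_str(rec, keys["mane"]) or "").lower()
            phase, phase_set = "unphased", None
            if sample_name is not None:
                s = rec.samples[sample_name]
                gt = s.get("GT")
                if gt is not None and None not in gt and s.phased:
                    if tuple(gt) == (1, 0):
                        phase = "haplotype1"
                    elif tuple(gt) == (0, 1):
                        phase = "haplotype2"
                    ps = s.get("PS")
                    if phase != "unphased" and ps is not None:
                        phase_set = str(ps)
                    elif phase != "unphased":
                        phase_set = "default"
            for alt in rec.alts or ():
                out.append(AnnotatedVariant(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    consequence=consequence,
                    impact=impact if impact in IMPACTS else "MODIFIER",
                    is_missense="missense" in consequence,
                    is_frameshift="frameshift" in consequence,
                    clinvar_significance=normalize_clinvar(_info_str(rec, keys["clinvar"])),
                    revel=float(revel_raw) if revel_raw not in (None, ".", "") else None,
                    allele_frequency=float(af_raw) if af_raw not in (None, ".", "") else None,
                    mane_select=mane_raw in ("1", "true", "yes", "mane_select"),
                    genotype_phase=phase,
                    phase_set=phase_set,
                ))
    return out


def decisions_table(variants: Sequence[AnnotatedVariant],
                    decisions: Sequence[PrioritizationDecision]) -> str:
    """TSV report of per-variant decisions."""
    lines = ["chrom\tpos\tref\talt\tretained\tmatched_criteria\texclusion_reason"]
    for v, d in zip(variants, decisions):
        lines.append("\t".join([
            v.chrom, str(v.pos), v.ref, v.alt,
            "true" if d.retained else "false",
            ",".join(d.matched_criteria) or ".",
            d.exclusion_reason or ".",
        ]))
    return "\n".join(lines) + "\n"
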