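"""Parse a repeat sequence into motif runs.

A repeat segment is cut into consecutive k-nt units from a chosen reading
frame; each unit is labelled with the catalog motif it matches (rotation
invariantly), with an ``interrupt:<unit>`` label when it is one substitution
away from the canonical motif, or ``other``. Consecutive same-label units
merge into runs — the run list is exactly the run-length encoding drawn as
a sequence bar chart, one coloured bar per run.

Two derived quantities drive interpretation: ``total_units`` (the total
repeat length in units, interruptions included) and
``max_pure_canonical_run`` (the longest stretch of consecutive exactly
canonical units — pathogenicity at purity-rule loci such as FGF14 hangs on
this number, because interrupted expansions of several hundred total units
are not considered pathogenic when no pure canonical stretch reaches the
threshold).

For loci whose catalog motifs differ in length (RFC1 carries pentamers and
the AAAGGG hexamer), the sequence is decomposed once per candidate motif
length and the parse with the most exact catalog-motif matches wins; the
dominant motif of the winning parse is the allele's motif call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from ._util import hamming, rotations
from .catalog import StrLocusDefinition


@dataclass(frozen=True)
class MotifRun:
    motif_label: str
    copies: int
    unit_start_index: int


@dataclass(frozen=True)
class DecompositionResult:
    runs: tuple[MotifRun, ...]
    total_units: int
    leftover_nt: int
    frame_offset: int
    max_pure_canonical_run: int
    interruption_runs: int
    composition: dict[str, int]
    motif_length: int
    exact_match_units: int

    @property
    def motif_call(self) -> str:
        """Dominant catalog motif of the parse, or "other"."""
        catalog_counts = {m: c for m, c in self.composition.items()
                          if not m.startswith("interrupt:") and m != "other"}
        if not catalog_counts:
            return "other"
        return max(catalog_counts, key=lambda m: (catalog_counts[m],))


def _label_unit(unit: str, locus: StrLocusDefinition, motifs: tuple[str, ...],
                canonical: str) -> str:
    """Label one unit: catalog motif > interrupt (Hamming 1 off canonical) > other."""
    for motif in motifs:
        if unit in rotations(motif):
            return motif
    if len(unit) == len(canonical) and hamming(unit, canonical) == 1:
        return f"interrupt:{unit}"
    return "other"


def choose_frame(sequence: str, locus: StrLocusDefinition,
                 motif_length: Optional[int] = None) -> int:
    """Choose the reading-frame offset (0..k-1) for cutting units.

    The offset maximising the number of units exactly equal to a catalog
    motif as written (its reporting form — so the frame lands units on GAA
    rather than a rotation of it) wins; ties go to the smallest offset.
    """
    k = motif_length or locus.motif_length_k
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than motif length {k}")
    motifs = set(locus.motifs_of_length(k)) or {locus.canonical_motif}
    best_offset, best_count = 0, -1
    for offset in range(k):
        count = sum(1 for i in range(offset, len(sequence) - k + 1, k)
                    if sequence[i:i + k] in motifs)
        if count > best_count:
            best_offset, best_count = offset, count
    return best_offset


def _decompose_at_length(sequence: str, locus: StrLocusDefinition, k: int,
                         ) -> DecompositionResult:
    sequence = sequence.upper()
    motifs = locus.motifs_of_length(k)
    canonical = locus.canonical_motif if len(locus.canonical_motif) == k else (
        motifs[0] if motifs else locus.canonical_motif)
    if len(sequence) < k:
        return DecompositionResult(runs=(), total_units=0, leftover_nt=len(sequence),
                                   frame_offset=0, max_pure_canonical_run=0,
                                   interruption_runs=0, composition={},
                                   motif_length=k, exact_match_units=0)
    offset = choose_frame(sequence, locus, motif_length=k)
    labels: list[str] = []
    n_units = (len(sequence) - offset) // k
    for i in range(n_units):
        unit = sequence[offset + i * k: offset + (i + 1) * k]
        labels.append(_label_unit(unit, locus, motifs or (canonical,), canonical))
    leftover = len(sequence) - offset - n_units * k

    runs: list[MotifRun] = []
    for idx, label in enumerate(labels):
        if runs and runs[-1].motif_label == label:
            runs[-1] = MotifRun(label, runs[-1].copies + 1, runs[-1].unit_start_index)
        else:
            runs.append(MotifRun(label, 1, idx))

    composition: dict[str, int] = {}
    for run in runs:
        composition[run.motif_label] = composition.get(run.motif_label, 0) + run.copies

    max_pure = 0
    for run in runs:
        if run.motif_label == canonical:
            max_pure = max(max_pure, run.copies)

    interruptions = sum(
        1 for i, run in enumerate(runs)
        if run.motif_label != canonical
        and 0 < i < len(runs) - 1
        and runs[i - 1].motif_label == canonical
        and runs[i + 1].motif_label == canonical
    )

    exact = sum(c for m, c in composition.items()
                if not m.startswith("interrupt:") and m != "other")
    return DecompositionResult(
        runs=tuple(runs), total_units=n_units, leftover_nt=leftover,
        frame_offset=offset, max_pure_canonical_run=max_pure,
        interruption_runs=interruptions, composition=composition,
        motif_length=k, exact_match_units=exact,
    )


def decompose(sequence: str, locus: StrLocusDefinition) -> DecompositionResult:
    """Decompose a repeat sequence into motif runs for a locus.

    When the catalog motifs for the locus span several lengths, each length
    is tried and the parse with the highest fraction of exact catalog-motif
    units is reported (ties to the canonical motif length).
    """
    lengths = locus.motif_lengths
    if len(lengths) == 1:
        return _decompose_at_length(sequence, locus, lengths[0])
    results = [_decompose_at_length(sequence, locus, k) for k in lengths]

    def score(r: DecompositionResult) -> tuple[float, int, int]:
        # highest exact-match fraction wins; a parse with fewer runs beats a
        # same-fraction parse that alternates between motifs (a pure AAAGGG
        # tract also tiles perfectly as alternating pentamers); final tie
        # goes to the canonical motif length
        frac = r.exact_match_units / r.total_units if r.total_units else 0.0
        return (frac, -len(r.runs), 1 if r.motif_length == locus.motif_length_k else 0)

    return max(results, key=score)


def barplot_encoding(result: DecompositionResult) -> list[tuple[str, int]]:
    """Run-length encoding of the parse, as drawn in a sequence bar chart."""
    return [(run.motif_label, run.copies) for run in result.runs]
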