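"""STR locus catalog: definitions, validation, file I/O and motif matching.

A catalog row describes one short-tandem-repeat locus implicated in the
spastic-ataxia spectrum: its repeat motif(s), the copy-number bands used for
interpretation (normal / intermediate / pathogenic), the inheritance mode
(one pathogenic allele suffices for dominant loci; recessive loci such as
RFC1 require two), and the 150-bp unique flanking anchors used to locate
the repeat within a read.

Two interpretation styles exist:

* ``purity_rule`` loci (e.g. the FGF14 GAA repeat) are judged on the
  longest *uninterrupted* run of the canonical motif;
* motif-catalog loci (e.g. RFC1) are judged on which motif the allele is
  built from (pathogenic AAGGG/ACAGG vs benign AAAAG/AAGAG/AAAGGG) and its
  total copy number.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from ._util import is_dna, rotations

ANCHOR_LENGTH = 150

_TSV_COLUMNS = [
    "locus_id", "gene", "disease", "k", "canonical_motif",
    "pathogenic_motifs", "benign_motifs", "normal_max",
    "intermediate_lo", "intermediate_hi", "pathogenic_min",
    "inheritance", "purity_rule", "reference_copies",
    "left_flank", "right_flank",
]


class CatalogValidationError(ValueError):
    """Raised when a catalog file or locus definition fails validation."""


@dataclass(frozen=True)
class StrLocusDefinition:
    """One STR locus and its interpretation rules."""

    locus_id: str
    gene: str
    disease: str
    motif_length_k: int
    canonical_motif: str
    pathogenic_motifs: tuple[str, ...]
    benign_motifs: tuple[str, ...]
    normal_max_copies: int
    inheritance: str  # "monoallelic" | "biallelic"
    purity_rule: bool
    reference_copies: int
    left_flank_anchor: str
    right_flank_anchor: str
    pathogenic_min_copies: Optional[int] = None
    intermediate_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        k = self.motif_length_k
        if k <= 0:
            raise CatalogValidationError(f"{self.locus_id}: motif length must be positive")
        if len(self.canonical_motif) != k:
            raise CatalogValidationError(
                f"{self.locus_id}: canonical motif {self.canonical_motif!r} is not {k} nt"
            )
        for m in (self.canonical_motif, *self.pathogenic_motifs, *self.benign_motifs):
            if not is_dna(m):
                raise CatalogValidationError(
                    f"{self.locus_id}: motif {m!r} contains non-ACGT characters"
                )
        # Motifs usually share the canonical length; RFC1-style loci may mix
        # lengths (AAAGGG is a hexamer among pentamers) and are handled
        # per-motif downstream, so no cross-motif length check here.
        for anchor, side in ((self.left_flank_anchor, "left"), (self.right_flank_anchor, "right")):
            if len(anchor) != ANCHOR_LENGTH or not is_dna(anchor):
                raise CatalogValidationError(
                    f"{self.locus_id}: {side} flank anchor must be {ANCHOR_LENGTH} nt of ACGT"
                )
        if self.inheritance not in ("monoallelic", "biallelic"):
            raise CatalogValidationError(
                f"{self.locus_id}: inheritance must be monoallelic or biallelic"
            )
        if self.intermediate_range is not None:
            lo, hi = self.intermediate_range
            if lo > hi:
                raise CatalogValidationError(f"{self.locus_id}: intermediate range inverted")
            if lo <= self.normal_max_copies:
                raise CatalogValidationError(
                    f"{self.locus_id}: intermediate range must lie above normal_max"
                )
            if self.pathogenic_min_copies is not None and hi >= self.pathogenic_min_copies:
                raise CatalogValidationError(
                    f"{self.locus_id}: intermediate range must lie below pathogenic_min"
                )

    @property
    def catalog_motifs(self) -> tuple[str, ...]:
        """All catalog motifs in priority order: canonical, pathogenic, benign."""
        seen: list[str] = [self.canonical_motif]
        for m in (*self.pathogenic_motifs, *self.benign_motifs):
            if m not in seen:
                seen.append(m)
        return tuple(seen)

    def motifs_of_length(self, length: int) -> tuple[str, ...]:
        return tuple(m for m in self.catalog_motifs if len(m) == length)

    @property
    def motif_lengths(self) -> tuple[int, ...]:
        return tuple(sorted({len(m) for m in self.catalog_motifs}))


def canonical_form(unit: str, locus: StrLocusDefinition) -> str:
    """Map a repeat unit to its catalog motif label, rotation-invariantly.

    Repeat units are read in an arbitrary frame, so AAG, AGA and GAA are the
    same motif; the catalog's reporting form (GAA for FGF14) is returned.
    The canonical motif takes priority over other catalog motifs when a unit
    matches rotations of more than one; non-catalog units map to ``"other"``.
    """
    unit = unit.upper()
    for motif in locus.catalog_motifs:
        if len(motif) == len(unit) and unit in rotations(motif):
            return motif
    return "other"


# ---------------------------------------------------------------------------
# File I/O


def _parse_row(row: dict[str, str], line_no: int) -> StrLocusDefinition:
    def opt_int(key: str) -> Optional[int]:
        v = row.get(key, "").strip()
        return int(v) if v else None

    try:
        lo, hi = opt_int("intermediate_lo"), opt_int("intermediate_hi")
        if (lo is None) != (hi is None):
            raise CatalogValidationError(
                f"line {line_no}: intermediate_lo/hi must be both present or both absent"
            )
        return StrLocusDefinition(
            locus_id=row["locus_id"].strip(),
            gene=row["gene"].strip(),
            disease=row["disease"].strip(),
            motif_length_k=int(row["k"]),
            canonical_motif=row["canonical_motif"].strip().upper(),
            pathogenic_motifs=tuple(
                m.strip().upper() for m in row["pathogenic_motifs"].split(",") if m.strip()
            ),
            benign_motifs=tuple(
                m.strip().upper() for m in row["benign_motifs"].split(",") if m.strip()
            ),
            normal_max_copies=int(row["normal_max"]),
            intermediate_range=(lo, hi) if lo is not None else None,
            pathogenic_min_copies=opt_int("pathogenic_min"),
            inheritance=row["inheritance"].strip(),
            purity_rule=row["purity_rule"].strip().lower() in ("1", "true", "yes"),
            reference_copies=int(row["reference_copies"]),
            left_flank_anchor=row["left_flank"].strip().upper(),
            right_flank_anchor=row["right_flank"].strip().upper(),
        )
    except (KeyError, ValueError) as exc:
        if isinstance(exc, CatalogValidationError):
            raise
        raise CatalogValidationError(f"line {line_no}: {exc}") from exc


def load_catalog(path: str | Path) -> list[StrLocusDefinition]:
    """Load and validate a locus catalog from TSV or JSON.

    TSV files may contain ``#`` comment lines; the JSON form is a list of
    objects with the same field names as the TSV columns.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        rows = json.loads(text)
        defs = [_parse_row({k: str(v) if v is not None else "" for k, v in r.items()}, i + 1)
                for i, r in enumerate(rows)]
    else:
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        reader = csv.DictReader(io.StringIO("\n".join(lines)), delimiter="\t")
        missing = set(_TSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise CatalogValidationError(f"catalog missing columns: {sorted(missing)}")
        defs = [_parse_row(row, i + 2) for i, row in enumerate(reader)]
    seen: set[str] = set()
    for d in defs:
        if d.locus_id in seen:
            raise CatalogValidationError(f"duplicate locus_id {d.locus_id!r}")
        seen.add(d.locus_id)
    return defs


def write_catalog(defs: Sequence[StrLocusDefinition], path: str | Path) -> None:
    """Write a catalog to TSV (or JSON when the path ends in .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps([_def_to_row(d) for d in defs], indent=1) + "\n")
        return
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_TSV_COLUMNS, delimiter="\t")
        writer.writeheader()
        for d in defs:
            writer.writerow(_def_to_row(d))


def _def_to_row(d: StrLocusDefinition) -> dict[str, str]:
    lo, hi = d.intermediate_range if d.intermediate_range else ("", "")
    return {
        "locus_id": d.locus_id,
        "gene": d.gene,
        "disease": d.disease,
        "k": str(d.motif_length_k),
        "canonical_motif": d.canonical_motif,
        "pathogenic_motifs": ",".join(d.pathogenic_motifs),
        "benign_motifs": ",".join(d.benign_motifs),
        "normal_max": str(d.normal_max_copies),
        "intermediate_lo": str(lo),
        "intermediate_hi": str(hi),
        "pathogenic_min": "" if d.pathogenic_min_copies is None else str(d.pathogenic_min_copies),
        "inheritance": d.inheritance,
        "purity_rule": "true" if d.purity_rule else "false",
        "reference_copies": str(d.reference_copies),
        "left_flank": d.left_flank_anchor,
        "right_flank": d.right_flank_anchor,
    }


def default_catalog_path() -> Path:
    """Path of the packaged 21-locus spastic-ataxia catalog."""
    return Path(str(resources.files("repeatscope").joinpath("data/default_catalog.tsv")))


def load_default_catalog() -> list[StrLocusDefinition]:
    return load_catalog(default_catalog_path())


def get_locus(defs: Iterable[StrLocusDefinition], locus_id: str) -> StrLocusDefinition:
    for d in defs:
        if d.locus_id == locus_id:
            return d
    raise KeyError(f"locus {locus_id!r} not in catalog")
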