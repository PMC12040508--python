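"""Regenerate src/repeatscope/data/default_catalog.tsv.

Flank anchors are deterministic 150-nt pseudo-random sequences seeded per
locus (stand-ins for reference-extracted flanks; synthetic by construction).
Copy-number thresholds for loci other than FGF14 are literature-standard
defaults, flagged as literature defaults in the file header.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from repeatscope.catalog import StrLocusDefinition, write_catalog, ANCHOR_LENGTH

# locus_id, gene, disease, k, canonical, pathogenic, benign,
# normal_max, inter_lo, inter_hi, path_min, inheritance, purity, ref_copies
LOCI = [
    ("ATXN1", "ATXN1", "SCA1", 3, "CAG", (), (), 35, 36, 38, 39, "monoallelic", True, 30),
    ("ATXN2", "ATXN2", "SCA2", 3, "CAG", (), (), 31, 32, 32, 33, "monoallelic", True, 22),
    ("ATXN3", "ATXN3", "SCA3", 3, "CAG", (), (), 44, 45, 59, 60, "monoallelic", True, 20),
    ("CACNA1A", "CACNA1A", "SCA6", 3, "CAG", (), (), 18, None, None, 20, "monoallelic", True, 12),
    ("ATXN7", "ATXN7", "SCA7", 3, "CAG", (), (), 33, 34, 36, 37, "monoallelic", True, 10),
    ("PPP2R2B", "PPP2R2B", "SCA12", 3, "CAG", (), (), 32, 33, 50, 51, "monoallelic", True, 13),
    ("TBP", "TBP", "SCA17", 3, "CAG", (), (), 40, 41, 48, 49, "monoallelic", True, 37),
    ("FXN", "FXN", "Friedreich ataxia", 3, "GAA", (), (), 33, 34, 65, 66, "biallelic", True, 9),
    ("ATN1", "ATN1", "DRPLA", 3, "CAG", (), (), 35, 36, 47, 48, "monoallelic", True, 15),
    ("FMR1", "FMR1", "FXTAS", 3, "CGG", (), (), 44, 45, 54, 55, "monoallelic", True, 30),
    ("FGF14", "FGF14", "SCA27B", 3, "GAA", (), (), 199, 200, 249, 250, "monoallelic", True, 9),
    ("RFC1", "RFC1", "CANVAS", 5, "AAGGG", ("AAGGG", "ACAGG"),
     ("AAAAG", "AAGAG", "AAAGGG", "AAAGG"), 11, None, None, 400, "biallelic", False, 11),
    ("ATXN8OS", "ATXN8OS", "SCA8", 3, "CTG", (), (), 50, 51, 79, 80, "monoallelic", True, 15),
    ("THAP11", "THAP11", "THAP11 ataxia", 3, "CAG", (), (), 32, None, None, 45, "monoallelic", True, 29),
    ("ZFHX3", "ZFHX3", "SCA4", 3, "GGC", (), (), 21, None, None, 46, "monoallelic", True, 21),
    ("ATXN10", "ATXN10", "SCA10", 5, "ATTCT", (), (), 32, 33, 799, 800, "monoallelic", False, 14),
    ("NOP56", "NOP56", "SCA36", 6, "GGCCTG", (), (), 14, 15, 649, 650, "monoallelic", False, 8),
    ("BEAN1", "BEAN1", "SCA31", 5, "TGGAA", (), (), 10, None, None, 45, "monoallelic", False, 0),
    ("DAB1", "DAB1", "SCA37", 5, "ATTTC", (), (), 16, None, None, 31, "monoallelic", False, 0),
    ("NOTCH2NLC", "NOTCH2NLC", "NIID ataxia", 3, "GGC", (), (), 40, 41, 59, 60, "monoallelic", True, 16),
    ("GLS", "GLS", "GLS ataxia", 3, "GCA", (), (), 29, None, None, 600, "biallelic", True, 14),
]

HEADER_COMMENT = """\
# Spastic-ataxia STR locus catalog (21 loci).
# FGF14 bands (normal <=199, intermediate 200-249, pathogenic >=250) follow the
# published SCA27B interpretation. All other thresholds are literature defaults
# taken from standard diagnostic references, not validated by this package.
# BEAN1/DAB1 reference_copies of 0 encode insertion-type repeats absent from
# the reference allele.
# Flank anchors are synthetic deterministic 150-nt sequences standing in for
# reference-extracted unique flanks.
"""


def anchor(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=ANCHOR_LENGTH))


def build() -> list[StrLocusDefinition]:
    defs = []
    for row in LOCI:
        (lid, gene, disease, k, canon, patho, benign,
         nmax, ilo, ihi, pmin, inh, purity, refc) = row
        rng = np.random.default_rng(int.from_bytes(lid.encode(), "little") % (2**31))
        defs.append(StrLocusDefinition(
            locus_id=lid, gene=gene, disease=disease, motif_length_k=k,
            canonical_motif=canon, pathogenic_motifs=tuple(patho) or (canon,),
            benign_motifs=tuple(benign),
            normal_max_copies=nmax,
            intermediate_range=(ilo, ihi) if ilo is not None else None,
            pathogenic_min_copies=pmin, inheritance=inh, purity_rule=purity,
            reference_copies=refc,
            left_flank_anchor=anchor(rng), right_flank_anchor=anchor(rng),
        ))
    return defs


if __name__ == "__main__":
    out = Path(__file__).resolve().parents[1] / "src/repeatscope/data/default_catalog.tsv"
    write_catalog(build(), out)
    text = out.read_text()
    out.write_text(HEADER_COMMENT + text)
    print(f"wrote {out} ({len(LOCI)} loci)")
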