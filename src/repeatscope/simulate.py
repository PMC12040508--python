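"""Diploid repeat-allele construction and ONT-like read simulation.

The generator stands in for a targeted long-read sequencing run over one
STR locus. Each allele is an explicit layout of motif runs (so mixed
GAA/GCA expansions and AGG-interrupted CGG tracts can be written down
exactly); the locus sequence for an allele is

    random flank | left anchor (150 nt) | repeat | right anchor | random flank

and reads are windows of that sequence carrying iid substitution /
insertion / deletion errors. With the default ~30-kb read length every
read spans both anchors, emulating the targeted assay regime in which
fragments are sheared to ~30 kb.

Packaged allele layouts reproduce the worked cases used throughout the
package: a mixed GAA/GCA expansion of 616 total units whose longest pure
GAA run is 195, an 85-unit CGG tract with two AGG interruptions, two
biallelic RFC1 genotypes (AAGGG 651/693 and AAGGG 1000 / ACAGG 2000) and
a heterozygous FGF14 expansion (GAA 348/9).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ._util import reverse_complement
from .catalog import StrLocusDefinition

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class AlleleSpec:
    """Ordered motif-run layout of one repeat allele."""

    runs: tuple[tuple[str, int], ...]
    label: str = "allele"

    def __post_init__(self) -> None:
        if not self.runs and self.label != "null_allele":
            raise ValueError("runs may be empty only for a null_allele")
        for motif, copies in self.runs:
            if copies <= 0:
                raise ValueError(f"run ({motif},{copies}): copies must be positive")
            if not motif or any(c not in "ACGT" for c in motif):
                raise ValueError(f"invalid motif {motif!r}: must be non-empty ACGT")

    @property
    def total_units(self) -> int:
        return sum(c for _, c in self.runs)

    @property
    def total_nt(self) -> int:
        return sum(len(m) * c for m, c in self.runs)

    @staticmethod
    def from_json(obj: list | str) -> "AlleleSpec":
        if isinstance(obj, str):
            obj = json.loads(obj)
        return AlleleSpec(runs=tuple((m, int(c)) for m, c in obj))


@dataclass(frozen=True)
class SimulationConfig:
    coverage_per_allele: float = 40.0
    read_length_mean: int = 30000
    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    seed: int = 0
    flank_nt: int = 5000

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0 <= r < 1:
                raise ValueError("error rates must lie in [0, 1)")
        if self.coverage_per_allele <= 0:
            raise ValueError("coverage_per_allele must be positive")


@dataclass
class TruthRecord:
    """Ground truth for one simulated diploid sample."""

    locus_id: str
    allele1: AlleleSpec
    allele2: AlleleSpec
    read_allele: dict[str, int] = field(default_factory=dict)  # read_id -> 1|2
    read_spans: dict[str, bool] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "locus_id": self.locus_id,
            "allele1": {"label": self.allele1.label, "runs": list(self.allele1.runs)},
            "allele2": {"label": self.allele2.label, "runs": list(self.allele2.runs)},
            "read_allele": self.read_allele,
            "read_spans": self.read_spans,
        }, indent=1)


# Packaged fixture layouts (interruption positions are a documented choice;
# totals and maximal pure runs match the worked cases above).
FIXTURES: dict[str, AlleleSpec] = {
    "MIX616": AlleleSpec((("GAA", 195), ("GCA", 1), ("GAA", 100), ("GCA", 1),
                          ("GAA", 100), ("GCA", 1), ("GAA", 100), ("GCA", 1),
                          ("GAA", 117)), label="MIX616"),
    "FMR1_85": AlleleSpec((("CGG", 10), ("AGG", 1), ("CGG", 10), ("AGG", 1),
                           ("CGG", 63)), label="FMR1_85"),
    "RFC1_P8_A1": AlleleSpec((("AAGGG", 651),), label="RFC1_P8_A1"),
    "RFC1_P8_A2": AlleleSpec((("AAGGG", 693),), label="RFC1_P8_A2"),
    "RFC1_P9_A1": AlleleSpec((("AAGGG", 1000),), label="RFC1_P9_A1"),
    "RFC1_P9_A2": AlleleSpec((("ACAGG", 2000),), label="RFC1_P9_A2"),
    "FGF14_LONG": AlleleSpec((("GAA", 348),), label="FGF14_LONG"),
    "FGF14_SHORT": AlleleSpec((("GAA", 9),), label="FGF14_SHORT"),
}

# Diploid genotypes built from the fixtures.
DIPLOID_FIXTURES: dict[str, tuple[str, str, str]] = {
    # name -> (locus_id, allele1 fixture, allele2 fixture)
    "FGF14_HET": ("FGF14", "FGF14_LONG", "FGF14_SHORT"),
    "FGF14_MIX616": ("FGF14", "MIX616", "FGF14_SHORT"),
    "RFC1_P8": ("RFC1", "RFC1_P8_A1", "RFC1_P8_A2"),
    "RFC1_P9": ("RFC1", "RFC1_P9_A1", "RFC1_P9_A2"),
}


def build_allele_sequence(spec: AlleleSpec) -> str:
    """Concatenate the motif runs of an allele into its DNA sequence."""
    return "".join(motif * copies for motif, copies in spec.runs)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def build_locus_reference(locus: StrLocusDefinition, flank_nt: int = 5000,
                          seed: int = 0) -> tuple[str, str]:
    """Build a toy reference region for a locus.

    Returns ``(name, sequence)`` where the sequence is random context, the
    left anchor, ``reference_copies`` canonical motifs, the right anchor and
    random context again. Random context is regenerated until neither anchor
    occurs a second time, so each anchor is unique in the output.
    """
    core = (locus.left_flank_anchor
            + locus.canonical_motif * locus.reference_copies
            + locus.right_flank_anchor)
    rng = np.random.default_rng(seed)
    while True:
        seq = _random_dna(rng, flank_nt) + core + _random_dna(rng, flank_nt)
        if seq.count(locus.left_flank_anchor) == 1 and seq.count(locus.right_flank_anchor) == 1:
            return f"{locus.locus_id}_ref", seq


def _allele_locus_sequence(locus: StrLocusDefinition, spec: AlleleSpec,
                           flank_nt: int, rng: np.random.Generator) -> str:
    return (_random_dna(rng, flank_nt)
            + locus.left_flank_anchor
            + build_allele_sequence(spec)
            + locus.right_flank_anchor
            + _random_dna(rng, flank_nt))


def _apply_errors(seq: str, cfg: SimulationConfig, rng: np.random.Generator) -> str:
    """Apply iid per-base substitution/insertion/deletion errors.

    Events are mutually exclusive per input base: substitution replaces the
    base with a uniformly chosen different base, insertion adds one uniform
    base after it, deletion drops it.
    """
    total = cfg.substitution_rate + cfg.insertion_rate + cfg.deletion_rate
    if total == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = arr.size
    u = rng.random(n)
    sub = u < cfg.substitution_rate
    ins = (~sub) & (u < cfg.substitution_rate + cfg.insertion_rate)
    dele = (~sub) & (~ins) & (u < total)
    out = arr.copy()
    if sub.any():
        # shift by 1..3 positions in base order: always a different base
        idx = np.searchsorted(_BASES, out[sub])
        out[sub] = _BASES[(idx + rng.integers(1, 4, size=int(sub.sum()))) % 4]
    if not ins.any() and not dele.any():
        return out.tobytes().decode()
    pieces: list[bytes] = []
    ins_pos = np.flatnonzero(ins)
    ins_bases = rng.choice(_BASES, size=ins_pos.size)
    keep = ~dele
    # build output respecting insertions after their base
    prev = 0
    for pos, base in zip(ins_pos, ins_bases):
        chunk = out[prev:pos + 1][keep[prev:pos + 1]]
        pieces.append(chunk.tobytes())
        pieces.append(bytes([base]))
        prev = pos + 1
    pieces.append(out[prev:][keep[prev:]].tobytes())
    return b"".join(pieces).decode()


def simulate_reads(locus: StrLocusDefinition, allele1: AlleleSpec, allele2: AlleleSpec,
                   cfg: SimulationConfig) -> tuple[list[tuple[str, str, str]], TruthRecord]:
    """Simulate a diploid targeted-sequencing sample over one locus.

    Returns ``(reads, truth)`` where each read is ``(read_id, sequence,
    quality)`` ready for FASTQ writing, and the truth records each read's
    source allele and whether its window spans both flank anchors. Output is
    a pure function of the arguments; the same config yields identical reads.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = TruthRecord(locus_id=locus.locus_id, allele1=allele1, allele2=allele2)
    reads: list[tuple[str, str, str]] = []
    for allele_idx, spec in ((1, allele1), (2, allele2)):
        locus_seq = _allele_locus_sequence(locus, spec, cfg.flank_nt, rng)
        n_total = len(locus_seq)
        window = min(cfg.read_length_mean, n_total)
        if window >= n_total:
            n_reads = int(round(cfg.coverage_per_allele))
        else:
            n_reads = int(round(cfg.coverage_per_allele * n_total / window))
        left_anchor_end = cfg.flank_nt + 150
        right_anchor_start = n_total - cfg.flank_nt - 150
        for i in range(n_reads):
            if window >= n_total:
                start = 0
            else:
                start = int(rng.integers(0, n_total - window + 1))
            fragment = locus_seq[start:start + window]
            spans = start <= cfg.flank_nt and start + window >= right_anchor_start + 150
            seq = _apply_errors(fragment, cfg, rng)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            read_id = f"{locus.locus_id}_a{allele_idx}_r{i:04d}"
            reads.append((read_id, seq, "5" * len(seq)))  # constant Q20
            truth.read_allele[read_id] = allele_idx
            truth.read_spans[read_id] = bool(spans)
    return reads, truth


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def read_fastx(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTQ or FASTA."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        return [(entry.name, entry.sequence) for entry in fh]
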