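"""Small shared helpers."""

from __future__ import annotations

import math

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

DNA_ALPHABET = "ACGT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero.

    Python's built-in round() is banker's rounding; repeat-copy estimates
    use the symmetric convention so that a half-unit insertion and a
    half-unit deletion are treated alike.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def is_dna(seq: str) -> bool:
    return bool(seq) and all(c in DNA_ALPHABET for c in seq)


def rotations(motif: str) -> list[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))
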