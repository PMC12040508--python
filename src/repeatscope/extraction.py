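"""Flank-anchor location and per-read repeat-size estimation.

Each locus carries two 150-bp unique flanking anchors. A read that contains
both anchors ("spanning") pins down the repeat exactly: the intervening
distance between the end of the left anchor and the start of the right
anchor, divided by the motif length, estimates the repeat copy number, and
the intervening sequence itself is the repeat segment handed to motif
decomposition.

Anchor search is semi-global edit-distance alignment (the anchor aligned as
an infix of the read, via edlib) on both strands; identity is
``(anchor_length - edit_distance) / anchor_length`` and hits below a
configurable identity floor (default 0.80) are rejected. Reads are oriented
so the left anchor precedes the right anchor before coordinates are taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib

from ._util import reverse_complement, round_half_away
from .catalog import StrLocusDefinition

DEFAULT_MIN_IDENTITY = 0.80


@dataclass(frozen=True)
class AnchorHit:
    read_id: str
    side: str  # "left" | "right"
    start: int  # 0-based half-open, in the oriented read
    end: int
    orientation: str  # "forward" | "reverse"
    identity: float


@dataclass(frozen=True)
class RepeatSegment:
    read_id: str
    sequence: str
    copies_estimate: int
    spanning: bool
    distance_nt: int = 0
    orientation: str = "forward"
    left_identity: float = 0.0
    right_identity: float = 0.0


def _best_location(anchor: str, read: str) -> Optional[tuple[int, int, int]]:
    """Best infix alignment of anchor in read: (edit_distance, start, end).

    Ties on edit distance are broken by the smallest start coordinate.
    """
    if not read:
        return None
    res = edlib.align(anchor, read, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    # edlib reports locations in ascending end order; recover starts and
    # take the smallest (a missing start means the alignment begins at 0).
    locs = [((s if s is not None else 0), e + 1) for s, e in res["locations"]]
    start, end = min(locs)
    return res["editDistance"], start, end


def locate_anchor(read: str, anchor: str, min_identity: float = DEFAULT_MIN_IDENTITY,
                  read_id: str = "", side: str = "left") -> Optional[AnchorHit]:
    """Locate one anchor on either strand of a read.

    Both the anchor and its reverse complement are aligned; the hit with the
    higher identity wins (forward preferred on ties) and is reported only if
    identity >= min_identity. Coordinates refer to the read as given.
    """
    if not read:
        return None
    n = len(anchor)
    best: Optional[tuple[float, int, int, str]] = None
    for orientation, query in (("forward", anchor), ("reverse", reverse_complement(anchor))):
        loc = _best_location(query, read)
        if loc is None:
            continue
        dist, start, end = loc
        identity = (n - dist) / n
        if best is None or identity > best[0]:
            best = (identity, start, end, orientation)
    if best is None or best[0] < min_identity:
        return None
    identity, start, end, orientation = best
    return AnchorHit(read_id=read_id, side=side, start=start, end=end,
                     orientation=orientation, identity=identity)


def extract_segment(read: str, left_hit: AnchorHit, right_hit: AnchorHit,
                    k: int) -> RepeatSegment:
    """Cut the repeat segment between two oriented anchor hits.

    The caller must supply hits on an already-oriented read (left anchor on
    the forward strand, preceding the right anchor). The copy estimate is
    the intervening distance over the motif length, rounded half away from
    zero. Overlapping anchors yield a rejected (non-spanning) segment.
    """
    if right_hit.start < left_hit.end:
        return RepeatSegment(read_id=left_hit.read_id, sequence="", copies_estimate=0,
                             spanning=False, orientation=left_hit.orientation,
                             left_identity=left_hit.identity, right_identity=right_hit.identity)
    distance = right_hit.start - left_hit.end
    return RepeatSegment(
        read_id=left_hit.read_id,
        sequence=read[left_hit.end:right_hit.start],
        copies_estimate=round_half_away(distance / k),
        spanning=True,
        distance_nt=distance,
        orientation=left_hit.orientation,
        left_identity=left_hit.identity,
        right_identity=right_hit.identity,
    )


@dataclass
class ExtractionSummary:
    n_reads: int = 0
    n_spanning: int = 0
    n_left_only: int = 0
    n_right_only: int = 0
    n_no_anchor: int = 0

    @property
    def warning(self) -> Optional[str]:
        if self.n_spanning == 0:
            return "no spanning reads"
        return None


def extract_all(reads: Sequence[tuple], locus: StrLocusDefinition,
                min_identity: float = DEFAULT_MIN_IDENTITY,
                ) -> tuple[list[RepeatSegment], ExtractionSummary]:
    """Extract one repeat segment per read carrying both anchors.

    Each read is tried in both orientations; the orientation in which both
    anchors are found forward-stranded and correctly ordered is used (the
    as-given orientation preferred when both work). Non-spanning reads are
    excluded from the segment list but tallied in the summary.
    """
    segments: list[RepeatSegment] = []
    summary = ExtractionSummary()
    k = locus.motif_length_k
    for rec in reads:
        read_id, seq = rec[0], rec[1]  # (id, seq) or (id, seq, qual)
        summary.n_reads += 1
        chosen: Optional[RepeatSegment] = None
        left_seen = right_seen = False
        for orientation, oriented in (("forward", seq), ("reverse", reverse_complement(seq))):
            lh = locate_anchor(oriented, locus.left_flank_anchor, min_identity,
                               read_id=read_id, side="left")
            rh = locate_anchor(oriented, locus.right_flank_anchor, min_identity,
                               read_id=read_id, side="right")
            left_seen = left_seen or (lh is not None)
            right_seen = right_seen or (rh is not None)
            if lh is None or rh is None:
                continue
            if lh.orientation != "forward" or rh.orientation != "forward":
                continue
            lh = AnchorHit(read_id, "left", lh.start, lh.end, orientation, lh.identity)
            rh = AnchorHit(read_id, "right", rh.start, rh.end, orientation, rh.identity)
            seg = extract_segment(oriented, lh, rh, k)
            if seg.spanning:
                chosen = seg
                break
        if chosen is not None:
            segments.append(chosen)
            summary.n_spanning += 1
        elif left_seen and not right_seen:
            summary.n_left_only += 1
        elif right_seen and not left_seen:
            summary.n_right_only += 1
        else:
            summary.n_no_anchor += 1
    return segments, summary
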