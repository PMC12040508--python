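"""Length-based allele clustering, merge rule and medoid consensus."""

import random

import numpy as np
import pytest

from repeatscope import (SimulationConfig, build_consensus, call_haplotypes,
                         extract_all, partition_by_length, simulate_reads)
from repeatscope.extraction import RepeatSegment
from repeatscope.haplotyping import NoCallError
from repeatscope.simulate import AlleleSpec, FIXTURES


def seg(read_id, copies, lid=1.0, rid=1.0, sequence=None):
    return RepeatSegment(read_id=read_id, sequence=sequence or "GAA" * copies,
                         copies_estimate=copies, spanning=True,
                         distance_nt=copies * 3, left_identity=lid, right_identity=rid)


def segs(copies_list):
    return [seg(f"r{i:03d}", c) for i, c in enumerate(copies_list)]


def test_well_separated_alleles_split():
    groups = call_haplotypes(segs([9, 9, 9, 347, 348, 349]))
    assert len(groups) == 2
    assert groups[0].copies_median == 9
    assert groups[1].copies_median == 348
    assert groups[0].allele_index == 1  # shorter allele first


def test_single_mode_is_homozygous_appearing():
    groups = partition_by_length(segs([100, 100, 101, 99, 100, 100]))
    assert len(groups) == 1


def test_merge_rule_arithmetic():
    # gap 10 between cluster means 200 and 210 falls inside the merge band
    groups = partition_by_length(segs([199, 200, 201, 209, 210, 211]))
    assert len(groups) == 1


def test_close_but_distinct_expansions_resolved():
    # 651 vs 693 pentamer alleles (6% apart) must stay separate
    groups = call_haplotypes(segs([650, 651, 652, 692, 693, 694]))
    assert len(groups) == 2
    assert [g.copies_median for g in groups] == [651, 693]


def test_min_support_no_call():
    with pytest.raises(NoCallError):
        partition_by_length(segs([100, 101]))


def test_permutation_invariance():
    base = segs([9, 10, 9, 348, 350, 349, 347, 9])
    expected = [(g.copies_median, g.read_ids) for g in call_haplotypes(base)]
    rng = random.Random(0)
    for _ in range(10):
        shuffled = base[:]
        rng.shuffle(shuffled)
        got = [(g.copies_median, g.read_ids) for g in call_haplotypes(shuffled)]
        assert got == expected


def test_consensus_is_identical_segment_for_identical_cluster():
    cluster = segs([50] * 10)
    assert build_consensus(cluster).sequence == "GAA" * 50


def test_reported_copies_is_rounded_median():
    groups = call_haplotypes(segs([346, 347, 348, 349, 350]))
    assert groups[0].reported_copies == 348


def test_medoid_tie_breaks():
    # two candidates equally close to the median: higher summed anchor
    # identity wins; equal identity falls back to smallest read_id
    cluster = [seg("b", 100, lid=0.9, rid=0.9),
               seg("a", 102, lid=0.99, rid=0.99),
               seg("c", 101, lid=0.95, rid=0.95)]
    # median 101 -> "c" closest
    assert build_consensus(cluster).read_id == "c"
    cluster = [seg("b", 100, lid=0.99, rid=0.99),
               seg("a", 102, lid=0.9, rid=0.9),
               seg("x", 101, lid=0.9, rid=0.9),
               seg("y", 101, lid=0.9, rid=0.9)]
    # "x" and "y" tie on distance and identity -> lexicographically smallest
    assert build_consensus(cluster).read_id == "x"


def test_homozygous_simulation_never_splits(fgf14):
    spec = FIXTURES["FGF14_LONG"]
    for s in range(1, 11):
        cfg = SimulationConfig(coverage_per_allele=15, substitution_rate=0.01,
                               insertion_rate=0.005, deletion_rate=0.005,
                               seed=s, flank_nt=300)
        reads, _ = simulate_reads(fgf14, spec, spec, cfg)
        segments, _ = extract_all(reads, fgf14)
        assert len(partition_by_length(segments)) == 1


def test_parameter_recovery_on_heterozygous_simulations(fgf14):
    # alleles differing by >20% in length, 2% error, 20x per allele:
    # both medians within 2% of truth over >= 95% of seeds
    truth = (120, 348)
    ok = 0
    for s in range(1, 21):
        cfg = SimulationConfig(coverage_per_allele=20, substitution_rate=0.01,
                               insertion_rate=0.005, deletion_rate=0.005,
                               seed=s, flank_nt=300)
        reads, _ = simulate_reads(fgf14, AlleleSpec((("GAA", truth[0]),)),
                                  AlleleSpec((("GAA", truth[1]),)), cfg)
        segments, _ = extract_all(reads, fgf14)
        groups = call_haplotypes(segments)
        if len(groups) == 2 and all(
                abs(g.copies_median - t) <= 0.02 * t for g, t in zip(groups, truth)):
            ok += 1
    assert ok >= 19
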