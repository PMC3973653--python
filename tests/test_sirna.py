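import numpy as np
import pytest

from canesrna.io import CollapsedRead, reverse_complement
from canesrna.profiler import MiRNAHit
from canesrna.sirna import (
    RawHit,
    SiRNACandidate,
    cleavage_concordance,
    filter_abundance,
    merge_variants,
    presence_overlap,
    scan_target,
    select_triggers,
)
from canesrna.targets import TargetSite, align_duplex


def make_hit(seq):
    return MiRNAHit(seq, "miRx", "syn-miRx", 0, False)


def make_site(transcript_id, start, end, mirna="M" * 19):
    # only geometry matters for concordance; duplex content is unused
    return TargetSite(
        mirna_id="miR159 I",
        mirna_seq=mirna,
        transcript_id=transcript_id,
        start=start,
        end=end,
        duplex=None,
        mfe_duplex=-20.0,
        mfe_perfect=-25.0,
        mfe_ratio=0.8,
        cleavage_position=end - 9,
        passed_rules={},
    )


def test_select_triggers_takes_only_22mers():
    hits = [make_hit("A" * n) for n in (20, 21, 22, 24)] + [make_hit("C" * 22)]
    assert select_triggers(hits) == ["A" * 22, "C" * 22]
    assert select_triggers([make_hit("A" * 21)]) == []


@pytest.fixture
def transcript(rng):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, 600))


def test_sense_hit_coordinates(transcript):
    read = CollapsedRead(transcript[299:320], {"L1": 5})  # 300..320 (1-based)
    hits = scan_target("T1", transcript, [read], 18)
    assert [(h.start, h.end, h.strand) for h in hits] == [(300, 320, "+")]
    assert (hits[0].display_start, hits[0].display_end) == (300, 320)


def test_antisense_hit_prints_high_to_low(transcript):
    read = CollapsedRead(reverse_complement(transcript[138:157]), {"L1": 5})
    hits = scan_target("T1", transcript, [read], 18)
    assert [(h.start, h.end, h.strand) for h in hits] == [(139, 157, "-")]
    assert (hits[0].display_start, hits[0].display_end) == (157, 139)


def test_short_match_rejected(transcript):
    read = CollapsedRead(transcript[100:117], {"L1": 5})  # 17 nt
    assert scan_target("T1", transcript, [read], 18) == []


def test_scan_equals_brute_force_all_substrings(rng):
    """Oracle: longest common exact substring >= 18 on either strand."""
    transcript = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
    pool = []
    for _ in range(30):
        if rng.random() < 0.5:
            s = int(rng.integers(0, 375))
            seq = transcript[s : s + 21]
            if rng.random() < 0.3:  # corrupt one end
                seq = seq[:10] + "".join("ACGT"[i] for i in rng.integers(0, 4, 11))
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
        else:
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 21))
        pool.append(CollapsedRead(seq, {"L1": 1}))

    def brute_longest(query):
        best = 0
        for L in range(len(query), 17, -1):
            for j in range(len(query) - L + 1):
                if query[j : j + L] in transcript:
                    return L
        return 0

    got = {(h.sequence, h.strand) for h in scan_target("T", transcript, pool, 18)}
    for read in pool:
        for strand, query in (
            ("+", read.sequence),
            ("-", reverse_complement(read.sequence)),
        ):
            expected = brute_longest(query) >= 18
            assert ((read.sequence, strand) in got) == expected, read.sequence


def _pool_counts(counts):
    return {s: CollapsedRead(s, c) for s, c in counts.items()}


def test_end_variants_merge_within_two_nt():
    counts = {
        "A" * 19: {"L1": 10},
        "C" * 18: {"L1": 50},
        "G" * 21: {"L1": 5},
    }
    hits = [
        RawHit("A" * 19, "T1", 139, 157, "-"),
        RawHit("C" * 18, "T1", 140, 157, "-"),
        RawHit("G" * 21, "T1", 139, 159, "-"),
    ]
    cands = merge_variants(hits, _pool_counts(counts))
    assert len(cands) == 1
    assert cands[0].representative == "C" * 18  # highest summed count
    assert cands[0].counts == {"L1": 65}
    assert cands[0].display_coords("T1") == "157-140"


def test_distant_hits_stay_separate():
    counts = {"A" * 19: {"L1": 1}, "C" * 19: {"L1": 1}}
    hits = [
        RawHit("A" * 19, "T1", 139, 157, "+"),
        RawHit("C" * 19, "T1", 170, 190, "+"),
    ]
    assert len(merge_variants(hits, _pool_counts(counts))) == 2


def test_identical_representative_reported_jointly():
    """The same siRNA from two targets becomes one joint candidate."""
    counts = {"A" * 19: {"L1": 30, "L2": 40}}
    hits = [
        RawHit("A" * 19, "CA229394", 139, 157, "-"),
        RawHit("A" * 19, "TC134732", 551, 568, "-"),
    ]
    cands = merge_variants(hits, _pool_counts(counts))
    assert len(cands) == 1
    assert set(cands[0].loci) == {"CA229394", "TC134732"}
    assert cands[0].counts == {"L1": 30, "L2": 40}  # not double-counted


def test_abundance_filter_is_strictly_greater_than():
    libs = ["L1", "L2", "L3", "L4"]
    core_cand = SiRNACandidate("A" * 19, {"T": (1, 19, "+")}, {"A" * 19},
                               {"L1": 51, "L2": 60, "L3": 55, "L4": 70})
    edge_cand = SiRNACandidate("C" * 19, {"T": (1, 19, "+")}, {"C" * 19},
                               {"L1": 50, "L2": 60, "L3": 55, "L4": 70})
    presence, core = filter_abundance([core_cand, edge_cand], libs, 50)
    assert core == [core_cand]
    assert presence["C" * 19] == {"L1": False, "L2": True, "L3": True, "L4": True}


def test_core_and_exclusive_partition():
    libs = ["L1", "L2", "L3", "L4"]
    cands = [
        SiRNACandidate("A" * 19, {}, set(), {l: 100 for l in libs}),  # ubiquitous
    ] + [
        SiRNACandidate(b * 19, {}, set(), {lib: 100})
        for b, lib in zip("CGT", ["L1", "L2", "L3"])
    ]
    presence, core = filter_abundance(cands, libs, 50)
    assert len(core) == 1 and core[0].representative == "A" * 19
    venn = presence_overlap(presence)
    assert venn[("L1", "L2", "L3", "L4")] == 1
    assert venn[("L1",)] == venn[("L2",)] == venn[("L3",)] == 1


def test_concordance_requires_covering_the_cleavage_site():
    site = make_site("CA229394", 139, 157)  # cleavage at 148
    spanning = SiRNACandidate("A" * 19, {"CA229394": (139, 157, "-")}, set())
    assert cleavage_concordance(spanning, site)
    secondary = SiRNACandidate("C" * 18, {"CA229394": (294, 311, "+")}, set())
    assert not cleavage_concordance(secondary, site)
    downstream = SiRNACandidate("G" * 19, {"CA229394": (178, 196, "+")}, set())
    assert not cleavage_concordance(downstream, site)
    other = SiRNACandidate("T" * 19, {"TC000001": (139, 157, "+")}, set())
    with pytest.raises(ValueError):
        cleavage_concordance(other, site)


def test_planted_tasirna_is_sole_core_candidate(synth_small, result_small):
    truth = synth_small.truth.tasirna
    assert len(result_small.sirna_core) == 1
    cand = result_small.sirna_core[0]
    assert cand.representative == truth.representative
    assert cand.cleavage_concordant
    start, end, strand = cand.loci[truth.transcript_id]
    assert start == truth.cleavage and strand == "+"
    assert cand.phase_register == 0
    # abundance filter satisfied in every library by construction
    for lib_id, lt in synth_small.truth.per_library.items():
        assert cand.counts[lib_id] == sum(lt.tasirna_member_counts.values())
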