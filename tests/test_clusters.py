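import numpy as np
import pytest

from canesrna.clusters import (
    TC_EST,
    UNANNOTATED_CLUSTER,
    UNANNOTATED_REPEAT,
    Placement,
    annotate_and_tabulate,
    build_clusters,
    categorize_reference,
    map_reads,
)
from canesrna.io import CollapsedRead, reverse_complement


def test_single_placement_full_weight(rng):
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    read = CollapsedRead(ref[100:121], {"L1": 4})
    placements, unmapped = map_reads([read], [("R1", ref)])
    assert unmapped == []
    assert len(placements) == 1
    p = placements[0]
    assert (p.reference_id, p.start, p.end, p.weight) == ("R1", 101, 121, 1.0)


def test_multi_mapping_splits_weight(rng):
    ref1 = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
    ref2 = "TTTT" + ref1[50:80] + "GGGG"
    read = CollapsedRead(ref1[55:75], {"L1": 1})
    placements, _ = map_reads([read], [("A", ref1), ("B", ref2)])
    assert sorted(p.reference_id for p in placements) == ["A", "B"]
    assert all(p.weight == 0.5 for p in placements)
    assert sum(p.weight for p in placements) == 1.0


def test_antisense_placement_and_unmapped(rng):
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
    anti = CollapsedRead(reverse_complement(ref[10:31]), {"L1": 1})
    lost = CollapsedRead("ACGTACGTACGTACGTACGTA", {"L1": 2})
    placements, unmapped = map_reads([anti, lost], [("R", ref)])
    assert [p.strand for p in placements] == ["-"]
    assert unmapped == [lost.sequence]


def test_gap_merge_examples():
    pls = [
        Placement("a" * 21, "R", 1, 21, "+", 1.0),
        Placement("b" * 21, "R", 60, 80, "+", 1.0),
    ]
    (cl,) = build_clusters(pls, merge_gap=100)
    assert (cl.start, cl.end) == (1, 80)
    two = build_clusters(
        [pls[0], Placement("b" * 21, "R", 200, 220, "+", 1.0)], merge_gap=100
    )
    assert [(c.start, c.end) for c in two] == [(1, 21), (200, 220)]


def test_cluster_count_matches_interval_merge_oracle(rng):
    """Oracle: transitive interval merging by union-find."""
    starts = sorted(int(s) for s in rng.integers(1, 5000, 80))
    pls = [Placement(f"s{i}", "R", s, s + 20, "+", 1.0) for i, s in enumerate(starts)]

    parent = list(range(len(pls)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pls)):
        for j in range(i + 1, len(pls)):
            gap = max(pls[j].start, pls[i].start) - min(pls[j].end, pls[i].end)
            if gap <= 100:
                parent[find(i)] = find(j)
    expected = len({find(i) for i in range(len(pls))})
    assert len(build_clusters(pls, merge_gap=100)) == expected


def test_category_priority_and_collision():
    ann = {"R1": "retrotransposon/LTR-gypsy", "R2": "unannotated"}
    assert categorize_reference("R1", ann, set()) == "retrotransposon/LTR-gypsy"
    assert categorize_reference("R2", ann, set()) == UNANNOTATED_REPEAT
    assert categorize_reference("TC1", {}, {"TC1"}) == TC_EST
    assert categorize_reference("X", {}, set()) == UNANNOTATED_CLUSTER
    with pytest.raises(ValueError):
        categorize_reference("R1", ann, {"R1"})


def _tabulate(reads_by_cat, rng):
    """Build refs/reads realizing an exact planted category mixture."""
    refs, ann, est_ids, pool = [], {}, set(), []
    for i, (cat, n_reads) in enumerate(reads_by_cat.items()):
        rid = f"REF{i}"
        ref = "".join("ACGT"[j] for j in rng.integers(0, 4, 500))
        refs.append((rid, ref))
        if cat == TC_EST:
            est_ids.add(rid)
        elif cat != UNANNOTATED_CLUSTER:
            ann[rid] = cat
        for k in range(n_reads):
            if cat == UNANNOTATED_CLUSTER:
                seq = "".join("ACGT"[j] for j in rng.integers(0, 4, 24))
            else:
                s = int(rng.integers(0, 470))
                seq = ref[s : s + 21]
            pool.append(CollapsedRead(seq, {"L1": 1}))
    merged = {}
    for r in pool:
        m = merged.setdefault(r.sequence, CollapsedRead(r.sequence, {"L1": 0}))
        m.counts["L1"] += 1
    pool = list(merged.values())
    placements, unmapped = map_reads(pool, refs)
    clusters = build_clusters(placements)
    return annotate_and_tabulate(
        clusters, ann, est_ids, {r.sequence: r for r in pool}, ["L1"], unmapped
    )


def test_planted_mixture_recovered_within_one_percent(rng):
    frac, _ = _tabulate(
        {"retrotransposon/LTR-gypsy": 400, TC_EST: 300, UNANNOTATED_CLUSTER: 300},
        rng,
    )
    frac = frac.set_index("category")["fraction_L1"]
    assert frac["retrotransposon/LTR-gypsy"] == pytest.approx(0.4, abs=0.01)
    assert frac[TC_EST] == pytest.approx(0.3, abs=0.01)
    assert frac[UNANNOTATED_CLUSTER] == pytest.approx(0.3, abs=0.01)
    assert frac.sum() == pytest.approx(1.0, abs=1e-9)


def test_empty_library_yields_zero_fractions():
    frac, hist = annotate_and_tabulate([], {}, set(), {}, ["L1"], [])
    assert frac.empty or (frac["fraction_L1"] == 0).all()
    assert hist.empty


def test_weight_conservation_through_tabulation(synth_small, result_small):
    """Total read weight equals the non-miRNA pool size per library."""
    frac = result_small.category_fractions
    for lib in synth_small.truth.per_library:
        lt = synth_small.truth.per_library[lib]
        pool_total = sum(lt.category_counts.values())
        got = frac[f"weight_{lib}"].sum()
        assert got == pytest.approx(pool_total, abs=1e-6)


def test_planted_category_fractions_match_truth(synth_small, result_small):
    frac = result_small.category_fractions.set_index("category")
    for lib, lt in synth_small.truth.per_library.items():
        total = sum(lt.category_counts.values())
        for cat, n in lt.category_counts.items():
            assert frac.loc[cat, f"fraction_{lib}"] == pytest.approx(
                n / total, abs=0.01
            ), (lib, cat)


def test_ltr_gypsy_size_shift_visible(synth_small, result_small):
    """The planted 24->21 nt LTR-gypsy shift shows in the length histogram."""
    hist = result_small.category_length_hist
    gypsy = hist[hist.category == "retrotransposon/LTR-gypsy"]

    def modal_length(lib):
        sub = gypsy[gypsy.library == lib]
        return int(sub.loc[sub.weight.idxmax(), "length"])

    assert modal_length("T0h") == 24
    assert modal_length("T24h") == 21
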