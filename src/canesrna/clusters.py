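"""siRNA cluster construction and repeat-category annotation.

The non-miRNA read fraction is placed on a reference set (repeat
sequences with class labels plus gene-derived TC EST transcripts) by
exact full-length ungapped matching on either strand.  Placements
within a merge gap are joined into clusters; every cluster inherits one
category from its reference with priority

    named repeat class > TC EST > unannotated repeat >
    unannotated-siRNA-cluster

and reads that place nowhere fall into the unannotated-siRNA-cluster
pool.  Multi-mapping reads contribute fractionally (1/k over their k
placements) so total read weight is conserved from placement through
tabulation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io import CollapsedRead, reverse_complement

UNANNOTATED_REPEAT = "unannotated repeat"
UNANNOTATED_CLUSTER = "unannotated-siRNA-cluster"
TC_EST = "TC EST"


@dataclass(frozen=True)
class Placement:
    sequence: str
    reference_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    weight: float  # 1/k for a read with k placements


@dataclass
class SiRNACluster:
    cluster_id: str
    reference_id: str
    start: int
    end: int
    category: str = ""
    placements: list[Placement] = field(default_factory=list)


def _occurrences(needle: str, haystack: str) -> list[int]:
    out, p = [], haystack.find(needle)
    while p != -1:
        out.append(p)
        p = haystack.find(needle, p + 1)
    return out


def map_reads(
    pool: Sequence[CollapsedRead], references: Sequence[tuple[str, str]]
) -> tuple[list[Placement], list[str]]:
    """Exact full-length placements on either strand, fractional weights.

    Returns (placements, unmapped sequences).  A read occurring k times
    across all references and strands gets weight 1/k per occurrence.
    """
    if not references:
        raise ValueError("reference set must be non-empty")
    placements: list[Placement] = []
    unmapped: list[str] = []
    for read in pool:
        seq = read.sequence
        found: list[tuple[str, int, str]] = []
        rc = reverse_complement(seq)
        for rid, rseq in references:
            for p in _occurrences(seq, rseq):
                found.append((rid, p, "+"))
            for p in _occurrences(rc, rseq):
                found.append((rid, p, "-"))
        if not found:
            unmapped.append(seq)
            continue
        w = 1.0 / len(found)
        for rid, p, strand in found:
            placements.append(
                Placement(seq, rid, p + 1, p + len(seq), strand, w)
            )
    placements.sort(key=lambda pl: (pl.reference_id, pl.start, pl.end, pl.sequence))
    return placements, sorted(set(unmapped))


def build_clusters(
    placements: Sequence[Placement], merge_gap: int = 100
) -> list[SiRNACluster]:
    """Transitively merge placements within ``merge_gap`` on one reference.

    Cluster span is the union hull of its member intervals; both strands
    contribute to the same cluster (siRNA loci are double-stranded).
    """
    by_ref: dict[str, list[Placement]] = defaultdict(list)
    for pl in placements:
        by_ref[pl.reference_id].append(pl)

    clusters: list[SiRNACluster] = []
    for rid in sorted(by_ref):
        group = sorted(by_ref[rid], key=lambda pl: (pl.start, pl.end))
        current: list[Placement] = []
        hull_end = None
        for pl in group:
            if current and pl.start - hull_end > merge_gap:
                clusters.append(_close_cluster(rid, current, len(clusters)))
                current = []
                hull_end = None
            current.append(pl)
            hull_end = pl.end if hull_end is None else max(hull_end, pl.end)
        if current:
            clusters.append(_close_cluster(rid, current, len(clusters)))
    return clusters


def _close_cluster(rid: str, members: list[Placement], index: int) -> SiRNACluster:
    return SiRNACluster(
        cluster_id=f"cl{index + 1}",
        reference_id=rid,
        start=min(pl.start for pl in members),
        end=max(pl.end for pl in members),
        placements=members,
    )


def categorize_reference(
    reference_id: str,
    repeat_annotation: Mapping[str, str],
    est_ids: frozenset[str] | set[str],
) -> str:
    if reference_id in repeat_annotation and reference_id in est_ids:
        raise ValueError(f"reference {reference_id} annotated as both repeat and EST")
    if reference_id in repeat_annotation:
        cls = repeat_annotation[reference_id]
        return UNANNOTATED_REPEAT if cls.lower() in ("", "unannotated") else cls
    if reference_id in est_ids:
        return TC_EST
    return UNANNOTATED_CLUSTER


def annotate_and_tabulate(
    clusters: Sequence[SiRNACluster],
    repeat_annotation: Mapping[str, str],
    est_ids: set[str],
    pool_counts: Mapping[str, CollapsedRead],
    library_ids: Sequence[str],
    unmapped: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-library category read-weight fractions and length histograms.

    A read's per-library weight is its count multiplied by the
    placement's fractional weight; unmapped reads count fully toward
    the unannotated-siRNA-cluster category.  Fractions per library sum
    to 1 over categories (when the library has any non-miRNA reads).
    """
    weight: dict[tuple[str, str], float] = defaultdict(float)  # (category, lib)
    length_w: dict[tuple[str, str, int], float] = defaultdict(float)

    for cl in clusters:
        cl.category = categorize_reference(cl.reference_id, repeat_annotation, est_ids)
        for pl in cl.placements:
            read = pool_counts[pl.sequence]
            for lib, n in read.counts.items():
                w = n * pl.weight
                weight[(cl.category, lib)] += w
                length_w[(cl.category, lib, read.length)] += w
    for seq in unmapped:
        read = pool_counts[seq]
        for lib, n in read.counts.items():
            weight[(UNANNOTATED_CLUSTER, lib)] += n
            length_w[(UNANNOTATED_CLUSTER, lib, read.length)] += n

    categories = sorted({cat for cat, _ in weight})
    rows = []
    for cat in categories:
        row: dict[str, object] = {"category": cat}
        for lib in library_ids:
            row[f"weight_{lib}"] = weight.get((cat, lib), 0.0)
        rows.append(row)
    frac = pd.DataFrame(rows)
    for lib in library_ids:
        total = frac[f"weight_{lib}"].sum() if not frac.empty else 0.0
        frac[f"fraction_{lib}"] = (
            frac[f"weight_{lib}"] / total if total > 0 else 0.0
        )

    hist_rows = [
        {"category": cat, "library": lib, "length": length, "weight": w}
        for (cat, lib, length), w in sorted(length_w.items())
    ]
    hist = pd.DataFrame(hist_rows, columns=["category", "library", "length", "weight"])
    return frac, hist
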