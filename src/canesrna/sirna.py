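"""Secondary-siRNA discovery downstream of 22-nt miRNA triggers.

22-nt miRNAs can initiate secondary (trans-acting-type) siRNA
production from the cleaved target transcript.  The scan takes the
predicted targets of the 22-nt miRNAs, aligns the non-miRNA read pool
against them (ungapped exact matches of >= 18 nt, both strands), merges
5'/3' end variants into candidates, applies the per-library abundance
filter, and tests whether a candidate is anchored at the miRNA cleavage
site.

Antisense alignments are reported with end < start (printed high->low),
matching the usual convention for minus-strand siRNA coordinates.
Phasing in the canonical 21-nt register is reported but never used as a
filter: the discrete, not-in-phase candidates are precisely the
interesting outcome here.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import CollapsedRead, reverse_complement
from .profiler import MiRNAHit
from .targets import TargetSite


def select_triggers(hits: Iterable[MiRNAHit], length: int = 22) -> list[str]:
    """Distinct matched miRNA sequences of exactly ``length`` nt."""
    return sorted({h.sequence for h in hits if len(h.sequence) == length})


@dataclass(frozen=True)
class RawHit:
    """One ungapped exact match of a pool read on a target transcript."""

    sequence: str
    transcript_id: str
    start: int  # 1-based inclusive, start <= end always (strand is separate)
    end: int
    strand: str  # '+' or '-'

    @property
    def display_start(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def display_end(self) -> int:
        return self.end if self.strand == "+" else self.start


def scan_target(
    transcript_id: str,
    transcript: str,
    pool: Iterable[CollapsedRead],
    a_min: int = 18,
) -> list[RawHit]:
    """All pool reads with a contiguous exact match >= ``a_min`` nt.

    Both strands are scanned; for each (read, strand) the longest
    maximal match is reported (leftmost on ties).  Seeding uses an
    ``a_min``-mer index of the transcript with maximal extension, which
    is equivalent to a brute-force all-substrings comparison.
    """
    index: dict[str, list[int]] = defaultdict(list)
    for p in range(len(transcript) - a_min + 1):
        index[transcript[p : p + a_min]].append(p)

    hits: list[RawHit] = []
    for read in pool:
        for strand in "+-":
            query = read.sequence if strand == "+" else reverse_complement(read.sequence)
            if len(query) < a_min:
                continue
            seen: set[tuple[int, int]] = set()
            best: tuple[int, int] | None = None  # (-length, tstart0)
            for j in range(len(query) - a_min + 1):
                for tpos in index.get(query[j : j + a_min], ()):
                    left_q, left_t = j, tpos
                    while left_q > 0 and left_t > 0 and query[left_q - 1] == transcript[left_t - 1]:
                        left_q -= 1
                        left_t -= 1
                    right_q, right_t = j + a_min, tpos + a_min
                    while (
                        right_q < len(query)
                        and right_t < len(transcript)
                        and query[right_q] == transcript[right_t]
                    ):
                        right_q += 1
                        right_t += 1
                    key = (tpos - j, left_t)
                    if key in seen:
                        continue
                    seen.add(key)
                    cand = (-(right_t - left_t), left_t)
                    if best is None or cand < best:
                        best = cand
            if best is not None:
                length, tstart0 = -best[0], best[1]
                hits.append(
                    RawHit(read.sequence, transcript_id, tstart0 + 1, tstart0 + length, strand)
                )
    hits.sort(key=lambda h: (h.start, h.end, h.strand, h.sequence))
    return hits


@dataclass
class SiRNACandidate:
    """A merged group of end-variant reads at one target locus.

    ``loci`` maps transcript id -> (start, end, strand); a candidate can
    span several transcripts when distinct targets shed the identical
    representative sequence (they are then reported jointly).
    """

    representative: str
    loci: dict[str, tuple[int, int, str]]
    members: set[str]
    counts: dict[str, int] = field(default_factory=dict)
    trigger_mirna: str = ""
    cleavage_concordant: bool = False
    phase_register: int | None = None

    def rpm(self, library_totals: Mapping[str, int]) -> dict[str, float]:
        return {
            lib: round(self.counts.get(lib, 0) * 1e6 / total, 2)
            for lib, total in library_totals.items()
        }

    def display_coords(self, transcript_id: str) -> str:
        start, end, strand = self.loci[transcript_id]
        return f"{start}-{end}" if strand == "+" else f"{end}-{start}"


def merge_variants(
    hits: Sequence[RawHit],
    pool_counts: Mapping[str, CollapsedRead],
    end_tolerance: int = 2,
) -> list[SiRNACandidate]:
    """Group hits whose start and end each differ by <= ``end_tolerance``.

    Grouping is transitive within one (transcript, strand); the
    representative is the member with the maximal summed count across
    libraries (ties to the lexicographically smallest sequence).
    Groups from distinct transcripts that produce the same
    representative sequence are merged into one joint candidate.
    """
    by_locus: dict[tuple[str, str], list[RawHit]] = defaultdict(list)
    for h in hits:
        by_locus[(h.transcript_id, h.strand)].append(h)

    prelim: list[SiRNACandidate] = []
    for (tid, strand), group in sorted(by_locus.items()):
        group = sorted(group, key=lambda h: (h.start, h.end, h.sequence))
        parent = list(range(len(group)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if (
                    abs(group[i].start - group[j].start) <= end_tolerance
                    and abs(group[i].end - group[j].end) <= end_tolerance
                ):
                    parent[find(i)] = find(j)
        clusters: dict[int, list[RawHit]] = defaultdict(list)
        for i, h in enumerate(group):
            clusters[find(i)].append(h)
        for members in clusters.values():
            seqs = sorted({h.sequence for h in members})
            top = max(pool_counts[s].total_count() for s in seqs)
            rep = min(s for s in seqs if pool_counts[s].total_count() == top)
            rep_hit = min(
                (h for h in members if h.sequence == rep),
                key=lambda h: (h.start, h.end),
            )
            counts: dict[str, int] = defaultdict(int)
            for s in seqs:
                for lib, n in pool_counts[s].counts.items():
                    counts[lib] += n
            prelim.append(
                SiRNACandidate(
                    representative=rep,
                    loci={tid: (rep_hit.start, rep_hit.end, strand)},
                    members=set(seqs),
                    counts=dict(counts),
                )
            )

    # joint reporting: identical representative from distinct transcripts
    joined: dict[str, SiRNACandidate] = {}
    out: list[SiRNACandidate] = []
    for cand in prelim:
        prev = joined.get(cand.representative)
        if prev is not None and not (set(prev.loci) & set(cand.loci)):
            prev.loci.update(cand.loci)
            prev.members |= cand.members
        else:
            joined[cand.representative] = cand
            out.append(cand)
    # recompute joint counts from the union of members
    for cand in out:
        counts: dict[str, int] = defaultdict(int)
        for s in sorted(cand.members):
            for lib, n in pool_counts[s].counts.items():
                counts[lib] += n
        cand.counts = dict(counts)
    return sorted(out, key=lambda c: (min(c.loci), c.representative))


def filter_abundance(
    candidates: Sequence[SiRNACandidate],
    library_ids: Sequence[str],
    c_min: int = 50,
) -> tuple[dict[str, dict[str, bool]], list[SiRNACandidate]]:
    """Per-library presence (raw count strictly > ``c_min``) and core set.

    The core set contains candidates present in every library; the
    presence map drives the per-library exclusive/shared partition.
    """
    presence: dict[str, dict[str, bool]] = {}
    core: list[SiRNACandidate] = []
    for cand in candidates:
        flags = {lib: cand.counts.get(lib, 0) > c_min for lib in library_ids}
        presence[cand.representative] = flags
        if all(flags.values()):
            core.append(cand)
    return presence, core


def presence_overlap(presence: Mapping[str, Mapping[str, bool]]) -> dict[tuple[str, ...], int]:
    """Venn-region counts of candidates over libraries (exclusive/shared)."""
    from .profiler import set_overlap

    libraries = sorted({lib for flags in presence.values() for lib in flags})
    groups = {
        lib: {rep for rep, flags in presence.items() if flags.get(lib)}
        for lib in libraries
    }
    return set_overlap(groups)


def cleavage_concordance(
    candidate: SiRNACandidate, site: TargetSite, tolerance: int = 1
) -> bool:
    """True iff the candidate's alignment covers the cleavage position (+-tolerance).

    Secondary siRNAs anchored at the scissile bond overlap it by
    construction (the first 3' fragment species starts there), whereas
    candidates from downstream secondary loci do not.
    """
    locus = candidate.loci.get(site.transcript_id)
    if locus is None:
        raise ValueError(
            f"candidate and site are on different transcripts "
            f"({sorted(candidate.loci)} vs {site.transcript_id})"
        )
    start, end, _ = locus
    cleav = site.cleavage_position
    return start - tolerance <= cleav <= end + tolerance


def discover_sirna(
    trigger_sites: Sequence[TargetSite],
    transcripts: Mapping[str, str],
    pool: Sequence[CollapsedRead],
    library_ids: Sequence[str],
    a_min: int = 18,
    c_min: int = 50,
    end_tolerance: int = 2,
    phase_length: int = 21,
) -> tuple[list[SiRNACandidate], list[SiRNACandidate]]:
    """Full trigger-target scan: (all candidates, core candidates).

    ``pool`` must already exclude every sequence with a miRNA hit.
    Candidates anchored at a trigger cleavage site get the trigger id
    and their phase register relative to the cleavage position.
    """
    pool_counts = {r.sequence: r for r in pool}
    sites_by_tid: dict[str, list[TargetSite]] = defaultdict(list)
    for site in trigger_sites:
        sites_by_tid[site.transcript_id].append(site)

    hits: list[RawHit] = []
    for tid in sorted(sites_by_tid):
        hits.extend(scan_target(tid, transcripts[tid], pool, a_min))

    candidates = merge_variants(hits, pool_counts, end_tolerance)
    for cand in candidates:
        for tid, (start, end, _) in sorted(cand.loci.items()):
            for site in sites_by_tid.get(tid, ()):
                if cleavage_concordance(cand, site):
                    cand.cleavage_concordant = True
                    cand.trigger_mirna = cand.trigger_mirna or site.mirna_id
                    cand.phase_register = (start - site.cleavage_position) % phase_length
    _, core = filter_abundance(candidates, library_ids, c_min)
    return candidates, core
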