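"""Conserved-miRNA identification and the "electronic northern".

Unique reads are matched ungapped, end-to-end, against a mature-miRNA
reference set (miRBase-style ``>osa-miR159a`` headers) allowing up to
three mismatches; matched reads are tabulated as raw counts and
reads-per-million per library, with length/5'-nucleotide composition
summaries and shared/unique set overlaps between library groups.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CollapsedRead, Library

_FAMILY_RE = re.compile(r"(miR|MIR)[-]?(\d+)", re.IGNORECASE)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


@dataclass
class MiRNAHit:
    """Assignment of a unique read to a mature miRNA family/variant."""

    sequence: str
    family: str
    reference_id: str
    mismatches: int
    is_star: bool
    variant_label: str = ""


def mirna_family(reference_id: str) -> str:
    """``osa-miR159a.1`` -> ``miR159``; star references keep the ``*``."""
    m = _FAMILY_RE.search(reference_id)
    if not m:
        raise ValueError(f"cannot parse miRNA family from '{reference_id}'")
    family = f"miR{m.group(2)}"
    if "*" in reference_id:
        family += "*"
    return family


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def match_read(
    read: str, reference: Sequence[tuple[str, str]], m_max: int = 3
) -> MiRNAHit | None:
    """Best ungapped match of ``read`` against the mature reference set.

    The read is compared end-to-end against every reference of equal
    length and against every equal-length window of longer references.
    The hit with minimal mismatches wins; ties break on the
    lexicographically smallest reference id.  ``None`` if no reference
    window is within ``m_max`` mismatches.
    """
    if not reference:
        raise ValueError("reference set must be non-empty")
    best: tuple[int, str] | None = None
    L = len(read)
    for ref_id, ref_seq in reference:
        if len(ref_seq) < L:
            continue
        d_ref = min(
            hamming(read, ref_seq[off : off + L])
            for off in range(len(ref_seq) - L + 1)
        )
        if d_ref <= m_max and (best is None or (d_ref, ref_id) < best):
            best = (d_ref, ref_id)
    if best is None:
        return None
    mism, ref_id = best
    return MiRNAHit(
        sequence=read,
        family=mirna_family(ref_id),
        reference_id=ref_id,
        mismatches=mism,
        is_star="*" in ref_id,
    )


def match_reads(
    reads: Iterable[str], reference: Sequence[tuple[str, str]], m_max: int = 3
) -> dict[str, MiRNAHit]:
    """Vectorized batch form of :func:`match_read` (same results).

    Reads are grouped by length into byte matrices and compared against
    each equal-length reference window in one numpy pass; the scalar
    tie-break rules are preserved.
    """
    if not reference:
        raise ValueError("reference set must be non-empty")
    by_len: dict[int, list[str]] = defaultdict(list)
    for seq in reads:
        by_len[len(seq)].append(seq)

    hits: dict[str, MiRNAHit] = {}
    ref_sorted = sorted(reference)  # id order fixes the tie-break
    for L, seqs in by_len.items():
        mat = np.vstack([encode(s) for s in seqs])
        best_d = np.full(len(seqs), m_max + 1, dtype=np.int32)
        best_ref = np.full(len(seqs), -1, dtype=np.int32)
        for ridx, (ref_id, ref_seq) in enumerate(ref_sorted):
            if len(ref_seq) < L:
                continue
            ref_enc = encode(ref_seq)
            for off in range(len(ref_seq) - L + 1):
                d = (mat != ref_enc[off : off + L]).sum(axis=1)
                better = d < best_d
                best_d[better] = d[better]
                best_ref[better] = ridx
        for i, seq in enumerate(seqs):
            if best_ref[i] >= 0 and best_d[i] <= m_max:
                ref_id = ref_sorted[best_ref[i]][0]
                hits[seq] = MiRNAHit(
                    sequence=seq,
                    family=mirna_family(ref_id),
                    reference_id=ref_id,
                    mismatches=int(best_d[i]),
                    is_star="*" in ref_id,
                )
    return hits


_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def roman(n: int) -> str:
    if n <= 0:
        raise ValueError("roman numerals start at 1")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def assign_variant_labels(hits: Iterable[MiRNAHit]) -> list[MiRNAHit]:
    """Label distinct sequences within each family I, II, III, ...

    Labels are assigned by lexicographic order of the distinct mature
    sequences, so they are reproducible across runs and machines.
    """
    hits = list(hits)
    per_family: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        per_family[h.family].add(h.sequence)
    label: dict[tuple[str, str], str] = {}
    for family, seqs in per_family.items():
        for i, seq in enumerate(sorted(seqs), 1):
            label[(family, seq)] = roman(i)
    for h in hits:
        h.variant_label = label[(h.family, h.sequence)]
    return hits


def build_expression_table(
    hits: Iterable[MiRNAHit],
    reads: Mapping[str, CollapsedRead],
    libraries: Sequence[Library],
) -> pd.DataFrame:
    """Electronic northern: one row per matched unique read.

    Columns: family, variant, sequence, length, reference_id, mismatches,
    is_star, then ``raw_<lib>`` and ``rpm_<lib>`` per library.  RPM is
    count x 1e6 / library total_filtered_reads.
    """
    for lib in libraries:
        if lib.total_filtered_reads == 0:
            raise ValueError(f"library {lib.id} has total_filtered_reads == 0")
    hits = assign_variant_labels(hits)
    rows = []
    for h in sorted(hits, key=lambda h: (h.family, h.variant_label, h.sequence)):
        read = reads[h.sequence]
        row = {
            "family": h.family,
            "variant": h.variant_label,
            "sequence": h.sequence,
            "length": len(h.sequence),
            "reference_id": h.reference_id,
            "mismatches": h.mismatches,
            "is_star": h.is_star,
        }
        for lib in libraries:
            raw = read.count_in(lib.id)
            row[f"raw_{lib.id}"] = raw
            row[f"rpm_{lib.id}"] = round(raw * 1e6 / lib.total_filtered_reads, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def composition_summary(hits: Iterable[MiRNAHit]) -> tuple[pd.Series, dict[str, float]]:
    """Length histogram and 5'-nucleotide percentages over unique hits.

    Plant mature miRNAs are expected to peak at 21 nt with a strong
    5'-U (stored as T) bias; this summary makes both visible.
    """
    seqs = sorted({h.sequence for h in hits})
    if not seqs:
        raise ValueError("composition_summary requires at least one hit")
    lengths = pd.Series([len(s) for s in seqs], name="length")
    hist = lengths.value_counts().sort_index()
    first = pd.Series([s[0] for s in seqs])
    pct = (first.value_counts() / len(seqs) * 100.0).round(1)
    return hist, {base: float(pct.get(base, 0.0)) for base in "ACGT"}


def set_overlap(groups: Mapping[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Exact Venn-region cardinalities for >= 2 named sets.

    Keys are sorted tuples of group names; the value is the number of
    elements belonging to exactly those groups.
    """
    if len(groups) < 2:
        raise ValueError("set_overlap requires at least two groups")
    names = sorted(groups)
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for subset in combinations(names, r):
            inside = set.intersection(*(groups[n] for n in subset))
            outside = set.union(
                set(), *(groups[n] for n in names if n not in subset)
            )
            out[subset] = len(inside - outside)
    return out
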