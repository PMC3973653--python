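"""Raw-read cleaning: adapter/N trimming, length window, complexity and
contaminant filters, and collapsing to unique sequences.

The filter order is fixed: trim -> length -> complexity -> contaminant ->
collapse.  Each stage can only shrink the read set, and the per-stage
totals are reported in a :class:`FilterReport` so attrition is auditable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import CollapsedRead, reverse_complement


@dataclass
class FilterReport:
    """Per-stage read totals for one library (redundant reads, not unique)."""

    input_reads: int = 0
    after_trim: int = 0
    after_length: int = 0
    after_complexity: int = 0
    after_contaminant: int = 0
    unique_sequences: int = 0

    def validate(self) -> None:
        stages = [
            self.input_reads,
            self.after_trim,
            self.after_length,
            self.after_complexity,
            self.after_contaminant,
        ]
        if any(b > a for a, b in zip(stages, stages[1:])):
            raise ValueError("filter stages must be monotonically non-increasing")
        if self.unique_sequences > self.after_contaminant:
            raise ValueError("unique_sequences exceeds surviving read total")


def trim_read(raw: str, adapter3: str, min_overlap: int = 6) -> str | None:
    """Remove the 3' adapter at its leftmost occurrence; drop reads with N.

    The adapter is located by exact prefix match against a read suffix
    with at least ``min_overlap`` nt of overlap.  Reads with no adapter
    occurrence are kept untrimmed; any read still containing an N after
    trimming is discarded (``None``).
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    insert = raw
    for i in range(len(raw) - min_overlap + 1):
        overlap = min(len(adapter3), len(raw) - i)
        if overlap >= min_overlap and raw[i : i + overlap] == adapter3[:overlap]:
            insert = raw[:i]
            break
    if "N" in insert:
        return None
    return insert


def pass_length(seq: str, l_min: int = 18, l_max: int = 28) -> bool:
    return l_min <= len(seq) <= l_max


def pass_complexity(seq: str, complexity_min_bases: int = 3) -> bool:
    """True iff the read uses at least ``complexity_min_bases`` distinct bases."""
    return len(set(seq)) >= complexity_min_bases


class ContaminantIndex:
    """Sense+antisense exact-substring membership against a contaminant set.

    A read is contaminant-derived iff it occurs verbatim inside any
    t/rRNA-type reference sequence or its reverse complement.  The
    references are concatenated with separators so membership is a pair
    of C-speed substring scans.
    """

    def __init__(self, contaminants: Sequence[tuple[str, str]]):
        if not contaminants:
            raise ValueError("contaminant set must be non-empty")
        seqs = [seq for _, seq in contaminants]
        self._sense = "#".join(seqs)
        self._antisense = "#".join(reverse_complement(s) for s in seqs)

    def __contains__(self, read: str) -> bool:
        return read in self._sense or read in self._antisense


def remove_contaminants(
    reads: Iterable[str], contaminants: Sequence[tuple[str, str]]
) -> list[str]:
    """Drop reads matching any contaminant on either strand, keep the rest."""
    index = ContaminantIndex(contaminants)
    return [r for r in reads if r not in index]


def collapse(
    reads: Iterable[tuple[str, int]], library_id: str
) -> list[CollapsedRead]:
    counter: Counter[str] = Counter()
    for seq, mult in reads:
        counter[seq] += mult
    return [
        CollapsedRead(seq, {library_id: n}) for seq, n in sorted(counter.items())
    ]


def preprocess_library(
    raw_reads: Iterable[tuple[str, int]],
    adapter3: str,
    contaminants: Sequence[tuple[str, str]],
    library_id: str,
    l_min: int = 18,
    l_max: int = 28,
    complexity_min_bases: int = 3,
    adapter_min_overlap: int = 6,
) -> tuple[list[CollapsedRead], FilterReport]:
    """Run the full trim/length/complexity/contaminant/collapse chain."""
    report = FilterReport()
    trimmed: list[tuple[str, int]] = []
    for seq, mult in raw_reads:
        report.input_reads += mult
        insert = trim_read(seq, adapter3, adapter_min_overlap)
        if insert is None:
            continue
        report.after_trim += mult
        trimmed.append((insert, mult))

    sized = [(s, m) for s, m in trimmed if pass_length(s, l_min, l_max)]
    report.after_length = sum(m for _, m in sized)

    complex_enough = [
        (s, m) for s, m in sized if pass_complexity(s, complexity_min_bases)
    ]
    report.after_complexity = sum(m for _, m in complex_enough)

    index = ContaminantIndex(contaminants)
    survivors = [(s, m) for s, m in complex_enough if s not in index]
    report.after_contaminant = sum(m for _, m in survivors)

    collapsed = collapse(survivors, library_id)
    report.unique_sequences = len(collapsed)
    report.validate()
    return collapsed, report
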