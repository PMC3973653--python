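"""Domain types and readers/writers for the formats the pipeline touches.

Sequences are stored DNA-style throughout: RNA inputs are mapped U->T on
the way in, so reads, mature miRNAs, transcripts and repeat references all
live in one {A,C,G,T} alphabet and can be compared directly.

Coordinates in every output table are 1-based inclusive on the forward
strand of the named reference.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default per-library length window, nt
L_MIN_DEFAULT = 18
L_MAX_DEFAULT = 28


def normalize_sequence(seq: str) -> str:
    """Uppercase and map U->T (RNA stored as DNA)."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CollapsedRead:
    """A unique small-RNA sequence with per-library read counts.

    The atom of every downstream stage: profiling, differential
    expression, siRNA discovery and clustering all consume these.
    """

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def total_count(self) -> int:
        return sum(self.counts.values())

    def count_in(self, library_id: str) -> int:
        return self.counts.get(library_id, 0)

    def validate(self, l_min: int = L_MIN_DEFAULT, l_max: int = L_MAX_DEFAULT) -> None:
        if not (l_min <= self.length <= l_max):
            raise ValueError(
                f"collapsed read length {self.length} outside [{l_min}, {l_max}]"
            )
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative read count")
        if not any(c > 0 for c in self.counts.values()):
            raise ValueError("collapsed read with no positive count")


@dataclass(frozen=True)
class Library:
    """One sequenced small-RNA library and its normalization denominator.

    ``group`` distinguishes the pooled tolerant/sensitive libraries from
    the two individual-cultivar libraries; ``total_filtered_reads`` is the
    post-filter read total used for reads-per-million normalization.
    """

    id: str
    tissue: str = "leaf"  # {leaf, root}
    group: str = "tolerant-pool"  # {tolerant-pool, sensitive-pool, individual-cultivar}
    timepoint: str = "0h"  # {0h, 24h}
    total_filtered_reads: int = 0

    def __post_init__(self):
        if self.total_filtered_reads < 0:
            raise ValueError("total_filtered_reads must be non-negative")


def _sniff_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fastq", ".fq")):
        return "fastq"
    return "fasta"


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_sequences(path, format: str | None = None) -> list[tuple[str, int]]:
    """Read raw sequences with multiplicities from FASTQ/FASTA/collapsed-FASTA.

    Returns ``[(sequence, multiplicity), ...]`` with sequences uppercased
    and U mapped to T.  FASTQ/FASTA records have multiplicity 1; the
    collapsed-FASTA dialect carries the count as an ``>id_count`` integer
    header suffix.  Qualities are ignored.
    """
    path = Path(path)
    fmt = format or _sniff_format(path)
    if fmt in ("fastq", "fasta"):
        with _open_text(path) as fh:
            return [
                (normalize_sequence(str(rec.seq)), 1) for rec in SeqIO.parse(fh, fmt)
            ]
    if fmt == "collapsed-fasta":
        out: list[tuple[str, int]] = []
        with _open_text(path) as fh:
            header = None
            lineno_header = 0
            chunks: list[str] = []

            def flush():
                if header is None:
                    return
                if not chunks:
                    raise ValueError(
                        f"{path}:{lineno_header}: header without sequence"
                    )
                tail = header.rsplit("_", 1)
                if len(tail) != 2 or not tail[1].isdigit():
                    raise ValueError(
                        f"{path}:{lineno_header}: collapsed-FASTA header "
                        f"'>{header}' lacks an '_count' integer suffix"
                    )
                out.append((normalize_sequence("".join(chunks)), int(tail[1])))

            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    flush()
                    header = line[1:].split()[0]
                    lineno_header = lineno
                    chunks = []
                else:
                    if header is None:
                        raise ValueError(f"{path}:{lineno}: sequence before header")
                    chunks.append(line)
            flush()
        return out
    raise ValueError(f"unknown sequence format: {fmt}")


def read_fasta(path) -> list[tuple[str, str]]:
    """Plain FASTA as ``[(id, normalized sequence), ...]``."""
    with _open_text(Path(path)) as fh:
        return [(rec.id, normalize_sequence(str(rec.seq))) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_collapsed_fasta(reads: Iterable[CollapsedRead], library_id: str, path) -> None:
    """Write one library's collapsed reads as ``>sN_count`` records.

    Rows are ordered by descending count then sequence, so output is
    deterministic and the most abundant species lead the file.
    """
    ordered = sorted(reads, key=lambda r: (-r.count_in(library_id), r.sequence))
    with open(path, "w") as fh:
        for i, read in enumerate(ordered, 1):
            n = read.count_in(library_id)
            if n > 0:
                fh.write(f">s{i}_{n}\n{read.sequence}\n")


def read_collapsed_library(path, library_id: str) -> list[CollapsedRead]:
    return [
        CollapsedRead(seq, {library_id: mult})
        for seq, mult in read_sequences(path, format="collapsed-fasta")
    ]


def write_table(df: pd.DataFrame, path, float_format: str = "%.2f") -> None:
    """Write a TSV with a header line; floats (RPM etc.) get 2 decimals."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def merge_collapsed(per_library: Mapping[str, Iterable[CollapsedRead]]) -> list[CollapsedRead]:
    """Union per-library collapsed reads into one set with joint counts."""
    joined: dict[str, CollapsedRead] = {}
    for lib_id, reads in per_library.items():
        for read in reads:
            tgt = joined.setdefault(read.sequence, CollapsedRead(read.sequence, {}))
            tgt.counts[lib_id] = tgt.counts.get(lib_id, 0) + read.count_in(lib_id)
    return sorted(joined.values(), key=lambda r: r.sequence)
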