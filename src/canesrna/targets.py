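"""Rule-based plant miRNA target prediction with an MFE-ratio criterion.

A candidate binding site is an ungapped, full-miRNA-length antiparallel
duplex between the miRNA (5'->3') and a transcript window.  Each
position is Watson-Crick (WC), G:U wobble (GU, weighted 0.5 mismatch)
or mismatch (MM, weighted 1).  A site is accepted iff all six rules
hold:

  R1  total weighted mismatches <= 4.0
  R2  no more than two adjacent non-WC positions anywhere
  R3  no adjacent non-WC positions within miRNA positions 2-12
  R4  miRNA positions 10 and 11 both WC
  R5  weighted mismatches over positions 1-12 <= 2.5
  R6  duplex MFE >= 74% of the MFE of the miRNA bound to its perfect
      complement

Energies come from an embedded nearest-neighbor stacking table
(RNA/RNA Watson-Crick free energies at 37 C; wobble-containing stacks
contribute a flat -1.3 kcal/mol); a mismatch voids its stacks and adds
a flat +1.0 kcal/mol destabilization.  R6 consumes only the ratio of
two values computed by the same function, so the flat terms cancel in
the reference point.

The cleavage site is the transcript base paired to miRNA position 10
(the 5' side of the 10-11 scissile bond), the standard slicer geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import PipelineConfig

WC = "WC"
GU = "GU"
MM = "MM"

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

# RNA/RNA nearest-neighbor stack free energies, kcal/mol at 37 C,
# written here in the DNA alphabet (U -> T).  Keys are
# (top 5'->3' dinucleotide, paired bases under it read 3'->5').
_WC_CORE = {
    ("AA", "TT"): -0.93,
    ("AT", "TA"): -1.10,
    ("TA", "AT"): -1.33,
    ("CT", "GA"): -2.08,
    ("CA", "GT"): -2.11,
    ("GT", "CA"): -2.24,
    ("GA", "CT"): -2.35,
    ("CG", "GC"): -2.36,
    ("GG", "CC"): -3.26,
    ("GC", "CG"): -3.42,
}
WC_STACKS: dict[tuple[str, str], float] = {}
for (top, bottom), dg in _WC_CORE.items():
    WC_STACKS[(top, bottom)] = dg
    WC_STACKS[(bottom[::-1], top[::-1])] = dg  # read from the other strand

GU_STACK_ENERGY = -1.3


def pair_state(mirna_base: str, target_base: str) -> str:
    if _COMP[mirna_base] == target_base:
        return WC
    if (mirna_base, target_base) in (("G", "T"), ("T", "G")):
        return GU
    return MM


_WEIGHT = {WC: 0.0, GU: 0.5, MM: 1.0}


@dataclass
class DuplexAlignment:
    """One ungapped miRNA/target-window duplex.

    ``target_window`` is the transcript sense strand 5'->3'; position i
    of the miRNA (1-based from its 5' end) pairs the window base
    ``target_window[L - i]`` (antiparallel geometry).  ``start``/``end``
    are 1-based inclusive transcript coordinates of the window.
    """

    mirna: str
    target_window: str
    start: int
    end: int
    pair_states: list[str]

    @property
    def mismatch_score_total(self) -> float:
        return sum(_WEIGHT[s] for s in self.pair_states)


def align_duplex(mirna: str, transcript: str, offset: int) -> DuplexAlignment:
    """Build the duplex for the window starting at 1-based ``offset``."""
    L = len(mirna)
    if offset < 1 or offset + L - 1 > len(transcript):
        raise IndexError("duplex window outside transcript")
    window = transcript[offset - 1 : offset - 1 + L]
    paired = window[::-1]  # paired[i] faces mirna[i]
    states = [pair_state(m, t) for m, t in zip(mirna, paired)]
    return DuplexAlignment(mirna, window, offset, offset + L - 1, states)


def duplex_mfe(duplex: DuplexAlignment, mismatch_penalty: float = 1.0) -> float:
    """Nearest-neighbor stacking sum plus flat mismatch penalties."""
    m = duplex.mirna
    paired = duplex.target_window[::-1]
    states = duplex.pair_states
    energy = 0.0
    for i in range(len(m) - 1):
        if states[i] == MM or states[i + 1] == MM:
            continue
        if states[i] == WC and states[i + 1] == WC:
            energy += WC_STACKS[(m[i : i + 2], paired[i : i + 2])]
        else:
            energy += GU_STACK_ENERGY
    energy += mismatch_penalty * sum(1 for s in states if s == MM)
    return energy


def perfect_complement_mfe(mirna: str, mismatch_penalty: float = 1.0) -> float:
    """MFE of the miRNA bound to its perfect complement (same scorer)."""
    window = "".join(_COMP[b] for b in mirna)[::-1]
    perfect = DuplexAlignment(mirna, window, 1, len(mirna), [WC] * len(mirna))
    return duplex_mfe(perfect, mismatch_penalty)


def mfe_ratio(duplex: DuplexAlignment, mismatch_penalty: float = 1.0) -> float:
    """duplex MFE / perfect-complement MFE, clamped into [0, 1]."""
    perfect = perfect_complement_mfe(duplex.mirna, mismatch_penalty)
    dg = duplex_mfe(duplex, mismatch_penalty)
    if dg >= 0.0:
        return 0.0
    return min(1.0, max(0.0, dg / perfect))


def check_rules(
    duplex: DuplexAlignment, config: PipelineConfig | None = None
) -> dict[str, bool]:
    """Evaluate R1-R6; ``accepted`` iff all six pass."""
    cfg = config or PipelineConfig()
    states = duplex.pair_states
    L = len(states)
    weights = [_WEIGHT[s] for s in states]
    non_wc = [s != WC for s in states]

    r1 = sum(weights) <= cfg.mismatch_cap_total
    run = longest = 0
    for flag in non_wc:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    r2 = longest <= cfg.max_adjacent_mismatches
    # adjacent non-WC pairs with both positions in 2..12 (1-based)
    r3 = not any(
        non_wc[i] and non_wc[i + 1] for i in range(1, min(11, L - 1))
    )
    r4 = L >= 11 and states[9] == WC and states[10] == WC
    r5 = sum(weights[:12]) <= cfg.mismatch_cap_5prime
    ratio = mfe_ratio(duplex, cfg.mismatch_penalty_kcal)
    r6 = ratio >= cfg.mfe_ratio_min
    rules = {"R1": r1, "R2": r2, "R3": r3, "R4": r4, "R5": r5, "R6": r6}
    rules["accepted"] = all(rules.values())
    return rules


@dataclass
class TargetSite:
    """An accepted miRNA binding site on a transcript."""

    mirna_id: str
    mirna_seq: str
    transcript_id: str
    start: int
    end: int
    duplex: DuplexAlignment
    mfe_duplex: float
    mfe_perfect: float
    mfe_ratio: float
    cleavage_position: int
    passed_rules: dict[str, bool]


def cleavage_position(end: int) -> int:
    """Transcript coordinate paired to miRNA position 10 for a site ending at ``end``."""
    return end - 9


def _window_weights(mirna: str, transcript: str) -> np.ndarray:
    """Weighted mismatch totals for every window, vectorized.

    Used only as a conservative prefilter (R1); surviving windows are
    re-scored through :func:`align_duplex`/:func:`check_rules`.
    """
    L = len(mirna)
    t = np.frombuffer(transcript.encode(), dtype=np.uint8)
    W = len(t) - L + 1
    if W <= 0:
        return np.empty(0)
    totals = np.zeros(W)
    for i in range(1, L + 1):  # miRNA position i pairs t[o + L - i]
        tv = t[L - i : L - i + W]
        m = mirna[i - 1]
        wc = tv == ord(_COMP[m])
        if m == "G":
            gu = tv == ord("T")
        elif m == "T":
            gu = tv == ord("G")
        else:
            gu = np.zeros(W, dtype=bool)
        totals += np.where(wc, 0.0, np.where(gu, 0.5, 1.0))
    return totals


def predict_targets(
    mirna_id: str,
    mirna: str,
    transcripts: Sequence[tuple[str, str]],
    config: PipelineConfig | None = None,
) -> list[TargetSite]:
    """Scan every window of every transcript; return rule-passing sites.

    Output is sorted by (transcript id, start) and is therefore
    invariant to the order of the input transcript records.
    """
    if not transcripts:
        raise ValueError("transcript set must be non-empty")
    cfg = config or PipelineConfig()
    sites: list[TargetSite] = []
    for tid, tseq in transcripts:
        totals = _window_weights(mirna, tseq)
        for o in np.nonzero(totals <= cfg.mismatch_cap_total)[0]:
            duplex = align_duplex(mirna, tseq, int(o) + 1)
            rules = check_rules(duplex, cfg)
            if not rules["accepted"]:
                continue
            dg = duplex_mfe(duplex, cfg.mismatch_penalty_kcal)
            dg_perfect = perfect_complement_mfe(mirna, cfg.mismatch_penalty_kcal)
            sites.append(
                TargetSite(
                    mirna_id=mirna_id,
                    mirna_seq=mirna,
                    transcript_id=tid,
                    start=duplex.start,
                    end=duplex.end,
                    duplex=duplex,
                    mfe_duplex=dg,
                    mfe_perfect=dg_perfect,
                    mfe_ratio=mfe_ratio(duplex, cfg.mismatch_penalty_kcal),
                    cleavage_position=cleavage_position(duplex.end),
                    passed_rules=rules,
                )
            )
    sites.sort(key=lambda s: (s.transcript_id, s.start, s.mirna_id))
    return sites
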