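"""Per-miRNA Fisher exact tests between unreplicated libraries, Bonferroni
control, regulation calls, and the pool-vs-individual concordance
classifier.

The test statistic is the classical conditional one: for the 2x2 table
``[[count_a, total_a - count_a], [count_b, total_b - count_b]]`` the
two-sided p-value sums the hypergeometric probabilities of every table
with the same margins whose probability does not exceed the observed
one (with the customary 1e-7 relative slack against float ties).  The
kernel returns the whole conditional family at once and is JIT-compiled,
which keeps exhaustive verification sweeps over all small tables cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

_REL_EPS = 1.0 + 1e-7

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"

CLASS_BOTH = "both"
CLASS_COMP1_ONLY = "comp1_only"
CLASS_COMP2_ONLY = "comp2_only"
CLASS_NEITHER = "neither"

_logfact_cache = np.zeros(1)


def _logfact(n: int) -> np.ndarray:
    """Cached table of log(k!) for k = 0..n."""
    global _logfact_cache
    if _logfact_cache.size <= n:
        _logfact_cache = np.concatenate(
            ([0.0], np.cumsum(np.log(np.arange(1, n + 1, dtype=np.float64))))
        )
    return _logfact_cache


@njit(cache=True)
def family_pvalues(M: int, n1: int, N: int, logfact: np.ndarray) -> tuple[int, np.ndarray]:
    """Two-sided p-values for every table in one conditional family.

    The family is hypergeometric(M, n1, N): ``k`` successes in the first
    row with row totals (N, M-N) and first-column total n1.  Returns
    (kmin, p) where ``p[i]`` is the p-value for ``k = kmin + i``.
    """
    kmin = n1 - (M - N)
    if kmin < 0:
        kmin = 0
    kmax = n1 if n1 < N else N
    s = kmax - kmin + 1
    base = logfact[n1] + logfact[M - n1] + logfact[N] + logfact[M - N] - logfact[M]
    pmf = np.empty(s)
    for i in range(s):
        k = kmin + i
        pmf[i] = math.exp(
            base
            - logfact[k]
            - logfact[N - k]
            - logfact[n1 - k]
            - logfact[M - N - n1 + k]
        )
    order = np.argsort(pmf)
    sorted_pmf = pmf[order]
    csum = np.cumsum(sorted_pmf)
    p = np.empty(s)
    for i in range(s):
        thr = pmf[i] * _REL_EPS
        lo, hi = 0, s  # last sorted index with pmf <= thr
        while lo < hi:
            mid = (lo + hi) // 2
            if sorted_pmf[mid] <= thr:
                lo = mid + 1
            else:
                hi = mid
        p[i] = csum[lo - 1] if lo > 0 else 0.0
        if p[i] > 1.0:
            p[i] = 1.0
    return kmin, p


def fisher_test(count_a: int, count_b: int, total_a: int, total_b: int) -> float:
    """Two-sided Fisher exact p-value for one sequence across two libraries."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    if not (0 <= count_a <= total_a) or not (0 <= count_b <= total_b):
        raise ValueError("counts must lie within their library totals")
    M = total_a + total_b
    n1 = count_a + count_b
    kmin, p = family_pvalues(M, n1, total_a, _logfact(M))
    return float(p[count_a - kmin])


def bonferroni(p_raw: float, m: int) -> float:
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p_raw * m)


def call_regulation(
    rpm_a: float, rpm_b: float, p_adj: float, alpha: float = 0.05
) -> tuple[str, bool]:
    """Direction of change a->b plus its Bonferroni-level significance."""
    if rpm_a < 0 or rpm_b < 0:
        raise ValueError("rpm values must be non-negative")
    if rpm_b > rpm_a:
        direction = UP
    elif rpm_b < rpm_a:
        direction = DOWN
    else:
        direction = UNCHANGED
    return direction, p_adj < alpha


@dataclass
class RegulationCall:
    sequence: str
    library_a: str
    library_b: str
    p_raw: float
    p_adj: float
    direction: str
    significant: bool


def test_library_pair(
    counts: Mapping[str, tuple[int, int]],
    total_a: int,
    total_b: int,
    library_a: str = "a",
    library_b: str = "b",
    alpha: float = 0.05,
) -> list[RegulationCall]:
    """Fisher test every sequence in one library pair, Bonferroni-corrected.

    ``counts`` maps sequence id -> (count_a, count_b); the correction
    factor m is the number of sequences tested in this pair.
    """
    m = len(counts)
    calls = []
    for seq_id in sorted(counts):
        ca, cb = counts[seq_id]
        p = fisher_test(ca, cb, total_a, total_b)
        p_adj = bonferroni(p, m)
        rpm_a = ca * 1e6 / total_a
        rpm_b = cb * 1e6 / total_b
        direction, significant = call_regulation(rpm_a, rpm_b, p_adj, alpha)
        calls.append(
            RegulationCall(seq_id, library_a, library_b, p, p_adj, direction, significant)
        )
    return calls


# --- pool-vs-individual concordance -----------------------------------------


def ratio_direction(
    count_num: int,
    count_den: int,
    total_num: int,
    total_den: int,
    pseudocount: int = 1,
) -> str:
    """Direction of the RPM ratio numerator/denominator.

    A pseudocount (default one raw read) replaces zero counts before the
    ratio is formed, so absent species compare cleanly.
    """
    cn = count_num if count_num > 0 else pseudocount
    cd = count_den if count_den > 0 else pseudocount
    rpm_n = cn * 1e6 / total_num
    rpm_d = cd * 1e6 / total_den
    if rpm_n > rpm_d:
        return UP
    if rpm_n < rpm_d:
        return DOWN
    return UNCHANGED


def concordance_class(comp1: bool, comp2: bool) -> str:
    if comp1 and comp2:
        return CLASS_BOTH
    if comp1:
        return CLASS_COMP1_ONLY
    if comp2:
        return CLASS_COMP2_ONLY
    return CLASS_NEITHER


@dataclass
class ConcordanceOutcome:
    mirna: str
    comp1: bool
    comp2: bool
    genotype_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def outcome_class(self) -> str:
        return concordance_class(self.comp1, self.comp2)


def classify_concordance(
    pool_stress_dirs: Mapping[str, str],
    individual_dirs: Mapping[str, str],
    genotype_pool_dirs: Mapping[str, Mapping[str, str]],
    genotype_individual_dirs: Mapping[str, Mapping[str, str]],
) -> list[ConcordanceOutcome]:
    """Compare the pooled-library miRNA profile with individual genotypes.

    Comparison 1 (genetic variation): the tolerant/sensitive ratio at
    24 h in the pools agrees with the tolerant/sensitive ratio in the
    individual-cultivar libraries.  Comparison 2 (water depletion): per
    genotype, the individual-vs-control ratio agrees with the matched
    pool-vs-control ratio; the per-genotype flags are OR-combined.

    All four mappings are keyed by miRNA id; the genotype mappings map
    genotype name -> {miRNA id -> direction}.
    """
    genotypes = sorted(genotype_pool_dirs)
    if sorted(genotype_individual_dirs) != genotypes:
        raise ValueError("genotype direction maps must cover the same genotypes")
    outcomes = []
    for mirna in sorted(pool_stress_dirs):
        if mirna not in individual_dirs:
            raise ValueError(f"missing individual-library direction for {mirna}")
        comp1 = pool_stress_dirs[mirna] == individual_dirs[mirna]
        flags = {}
        for g in genotypes:
            flags[g] = genotype_pool_dirs[g][mirna] == genotype_individual_dirs[g][mirna]
        outcomes.append(
            ConcordanceOutcome(mirna, comp1, any(flags.values()), flags)
        )
    return outcomes


def concordance_table(outcomes: Sequence[ConcordanceOutcome]):
    """Tabular form of per-miRNA outcomes ('+'/'-' flags plus class)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "mirna": o.mirna,
                "comp1": "+" if o.comp1 else "-",
                "comp2": "+" if o.comp2 else "-",
                **{f"comp2_{g}": "+" if f else "-" for g, f in sorted(o.genotype_flags.items())},
                "class": o.outcome_class,
            }
            for o in outcomes
        ]
    )


def class_count_table(outcomes: Sequence[ConcordanceOutcome]):
    """Aggregate class cardinalities as a two-column table."""
    import pandas as pd

    counts = summarize_flags([(o.comp1, o.comp2) for o in outcomes])
    return pd.DataFrame(
        [{"class": k, "count": v} for k, v in sorted(counts.items())]
    )


def summarize_flags(flag_pairs: Sequence[tuple[bool, bool]]) -> dict[str, int]:
    """Class counts for (comp1, comp2) flag pairs, plus positive-in->=1."""
    counts = {
        CLASS_BOTH: 0,
        CLASS_COMP1_ONLY: 0,
        CLASS_COMP2_ONLY: 0,
        CLASS_NEITHER: 0,
    }
    for c1, c2 in flag_pairs:
        counts[concordance_class(c1, c2)] += 1
    counts["positive_any"] = len(flag_pairs) - counts[CLASS_NEITHER]
    return counts
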