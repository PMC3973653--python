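import numpy as np
import pytest

from canesrna.config import PipelineConfig
from canesrna.io import reverse_complement
from canesrna.targets import (
    GU,
    GU_STACK_ENERGY,
    MM,
    WC,
    WC_STACKS,
    DuplexAlignment,
    align_duplex,
    check_rules,
    duplex_mfe,
    mfe_ratio,
    pair_state,
    perfect_complement_mfe,
    predict_targets,
)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
_GU_PARTNER = {"G": "T", "T": "G"}
_MM_BASE = {"A": "A", "C": "C", "G": "A", "T": "C"}


def build_duplex(mirna: str, states: list[str]) -> DuplexAlignment:
    """Construct a target window realizing the requested pair states."""
    paired = []
    for m, s in zip(mirna, states):
        if s == WC:
            paired.append(_COMP[m])
        elif s == GU:
            paired.append(_GU_PARTNER[m])
        else:
            paired.append(_MM_BASE[m])
    window = "".join(paired)[::-1]
    duplex = align_duplex(mirna, window, 1)
    assert duplex.pair_states == states
    return duplex


def random_state_vector(rng, length: int) -> tuple[str, list[str]]:
    """Random (miRNA, states): state drawn first, base drawn to realize it."""
    states, mirna = [], []
    for _ in range(length):
        s = (WC, GU, MM)[rng.integers(3)]
        base = "GT"[rng.integers(2)] if s == GU else "ACGT"[rng.integers(4)]
        states.append(s)
        mirna.append(base)
    return "".join(mirna), states


def brute_force_rules(states, weights=None, cfg=None):
    """Independent rule evaluator for R1-R5 (positional logic only)."""
    cfg = cfg or PipelineConfig()
    w = {WC: 0.0, GU: 0.5, MM: 1.0}
    total = sum(w[s] for s in states)
    r1 = total <= cfg.mismatch_cap_total
    r2 = all(
        not all(x != WC for x in states[i : i + 3]) for i in range(len(states) - 2)
    )
    r3 = True
    for pos in range(2, 12):  # 1-based adjacent pairs (2,3) .. (11,12)
        if pos + 1 > len(states):
            break
        if states[pos - 1] != WC and states[pos] != WC:
            r3 = False
    r4 = len(states) >= 11 and states[9] == WC and states[10] == WC
    r5 = sum(w[s] for s in states[:12]) <= cfg.mismatch_cap_5prime
    return {"R1": r1, "R2": r2, "R3": r3, "R4": r4, "R5": r5}


def stack_energy_oracle(duplex: DuplexAlignment, penalty=1.0) -> float:
    """Independent table walk over adjacent paired positions."""
    paired = duplex.target_window[::-1]
    total = 0.0
    for i in range(len(duplex.mirna) - 1):
        a, b = duplex.pair_states[i], duplex.pair_states[i + 1]
        if MM in (a, b):
            continue
        if (a, b) == (WC, WC):
            total += WC_STACKS[(duplex.mirna[i : i + 2], paired[i : i + 2])]
        else:
            total += GU_STACK_ENERGY
    return total + penalty * duplex.pair_states.count(MM)


def test_pair_states():
    assert pair_state("A", "T") == WC and pair_state("C", "G") == WC
    assert pair_state("G", "T") == GU and pair_state("T", "G") == GU
    assert pair_state("A", "C") == MM


def test_perfect_complement_all_wc_score_zero():
    mirna = "TTGGATTGAAGGGAGCTCTG"
    transcript = "AAAA" + reverse_complement(mirna) + "CCCC"
    duplex = align_duplex(mirna, transcript, 5)
    assert duplex.pair_states == [WC] * len(mirna)
    assert duplex.mismatch_score_total == 0.0
    with pytest.raises(IndexError):
        align_duplex(mirna, transcript, 15)


def test_single_wobble_weighs_half():
    mirna = "G" + "A" * 20
    states = [GU] + [WC] * 20
    assert build_duplex(mirna, states).mismatch_score_total == 0.5


def test_alignment_matches_positionwise_oracle(rng):
    for _ in range(50):
        mirna = "".join("ACGT"[i] for i in rng.integers(0, 4, 21))
        transcript = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        offset = int(rng.integers(1, 40))
        duplex = align_duplex(mirna, transcript, offset)
        window = transcript[offset - 1 : offset + 20]
        for i in range(21):  # miRNA position i+1 pairs window base L-i-1
            assert duplex.pair_states[i] == pair_state(mirna[i], window[20 - i])


def test_perfect_duplex_passes_all_rules():
    mirna = "TTGGATTGAAGGGAGCTCTG"
    duplex = build_duplex(mirna, [WC] * len(mirna))
    rules = check_rules(duplex)
    assert rules["accepted"] and all(rules[f"R{i}"] for i in range(1, 7))


def test_mismatch_at_position_ten_fails_r4():
    mirna = "TTGGATTGAAGGGAGCTCTG"
    states = [WC] * len(mirna)
    states[9] = MM
    rules = check_rules(build_duplex(mirna, states))
    assert not rules["R4"] and not rules["accepted"]


def test_nine_scattered_wobbles_fail_r1():
    """9 GU x 0.5 = 4.5 > 4.0 even with no true mismatch anywhere."""
    mirna = "G" * 28
    states = [WC] * 28
    for pos in (1, 13, 15, 17, 19, 21, 23, 25, 27):  # non-adjacent, outside 2-12
        states[pos - 1] = GU
    rules = check_rules(build_duplex(mirna, states))
    assert not rules["R1"]
    assert rules["R2"] and rules["R3"] and rules["R4"] and rules["R5"]


def test_rules_match_brute_force_evaluator(rng):
    for _ in range(500):
        mirna, states = random_state_vector(rng, 21)
        got = check_rules(build_duplex(mirna, states))
        expected = brute_force_rules(states)
        for rule, val in expected.items():
            assert got[rule] == val, (rule, states)


def test_perfect_complement_ratio_exactly_one():
    for mirna in ("TTGGATTGAAGGGAGCTCTG", "TGTTAATTACTCCTCCGGAATT"):
        duplex = build_duplex(mirna, [WC] * len(mirna))
        assert mfe_ratio(duplex) == 1.0
        assert duplex_mfe(duplex) == perfect_complement_mfe(mirna)


def test_all_mismatch_duplex_clamps_to_zero():
    mirna = "A" * 21
    duplex = build_duplex(mirna, [MM] * 21)
    assert duplex_mfe(duplex) >= 0
    assert mfe_ratio(duplex) == 0.0
    assert not check_rules(duplex)["R6"]


def test_energy_matches_table_lookup_oracle(rng):
    for _ in range(200):
        mirna, states = random_state_vector(rng, 21)
        duplex = build_duplex(mirna, states)
        assert duplex_mfe(duplex) == pytest.approx(
            stack_energy_oracle(duplex), abs=1e-12
        )


def test_planted_site_found_at_exact_coordinates():
    mirna = "TTGGATTGAAGGGAGCTCTGC"  # 21 nt
    rng = np.random.default_rng(3)
    transcript = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    transcript = transcript[:100] + reverse_complement(mirna) + transcript[121:]
    sites = predict_targets("miR159 XI", mirna, [("TC1", transcript)])
    assert [(s.start, s.end) for s in sites] == [(101, 121)]
    assert sites[0].cleavage_position == 121 - 9
    assert sites[0].mfe_ratio == 1.0


def test_poly_a_transcript_has_no_sites():
    assert predict_targets("m", "TTGGATTGAAGGGAGCTCTG", [("t", "A" * 500)]) == []


def test_output_invariant_to_transcript_order(rng):
    mirna = "TGTTAATTACTCCTCCGGAATT"
    ts = []
    for i in range(3):
        t = "".join("ACGT"[j] for j in rng.integers(0, 4, 200))
        t = t[:50] + reverse_complement(mirna) + t[50 + len(mirna):]
        ts.append((f"T{i}", t))
    fwd = predict_targets("m", mirna, ts)
    rev = predict_targets("m", mirna, ts[::-1])
    assert [(s.transcript_id, s.start) for s in fwd] == [
        (s.transcript_id, s.start) for s in rev
    ]


def test_dropping_energy_filter_only_enlarges_output(rng):
    mirna = "TGTTAATTACTCCTCCGGAATT"
    t = "".join("ACGT"[j] for j in rng.integers(0, 4, 400))
    # plant a marginal site with two mismatches in the 3' half
    window = reverse_complement(mirna)
    window = window[:3] + _MM_BASE[mirna[-4]] + window[4:]
    t = t[:200] + window + t[200 + len(window):]
    strict = predict_targets("m", mirna, [("t", t)], PipelineConfig())
    loose_cfg = PipelineConfig(mfe_ratio_min=1e-9)
    loose = predict_targets("m", mirna, [("t", t)], loose_cfg)
    assert {(s.transcript_id, s.start) for s in strict} <= {
        (s.transcript_id, s.start) for s in loose
    }


def test_planted_synthetic_sites_and_decoys(synth_small, result_small):
    """All planted rule-passing sites are found; every decoy is rejected."""
    truth = synth_small.truth
    found = {(s.transcript_id, s.start, s.end) for s in result_small.target_sites}
    for site in truth.planted_sites:
        key = (site.transcript_id, site.start, site.end)
        if site.expect_pass:
            assert key in found
        else:
            assert key not in found
    assert len(found) == sum(1 for s in truth.planted_sites if s.expect_pass)
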