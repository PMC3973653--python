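"""Synthetic small-RNA study generator with known ground truth.

Emulates the salient structure of a drought-stress small-RNA experiment
on pooled leaf libraries: 18-28 nt reads with abundance peaks at
21/22/24 nt, conserved miRNA families at library-specific abundances
(including a two-fold stress response), a 5'-U bias, t/rRNA
contaminants, repeat-derived siRNAs with per-category mixtures (and a
planted 24->21 nt LTR-gypsy size shift between control and stressed
tolerant libraries), and a 22-nt miRNA whose target transcript sheds
secondary siRNAs anchored at the cleavage site.  Every planted quantity
is recorded in a :class:`SyntheticTruth` so each pipeline stage can be
tested against exact expectations without any downloaded data.

The same seed reproduces the dataset byte-for-byte; different seeds
differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .io import Library, reverse_complement
from .profiler import match_read
from .targets import align_duplex, check_rules

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
# a base that is neither the WC partner nor a wobble partner
_MM_BASE = {"A": "A", "C": "C", "G": "A", "T": "C"}

DEFAULT_LIBRARIES = {
    # id: (tissue, group, timepoint)
    "T0h": ("leaf", "tolerant-pool", "0h"),
    "T24h": ("leaf", "tolerant-pool", "24h"),
    "S0h": ("leaf", "sensitive-pool", "0h"),
    "S24h": ("leaf", "sensitive-pool", "24h"),
}

# read composition of one library (fractions of reads_per_library)
DEFAULT_COMPOSITION = {
    "mirna": 0.24,
    "contaminant": 0.10,
    "tasirna": 0.01,
    "repeat": 0.53,
    "background": 0.09,
    "n_fail": 0.01,
    "length_fail": 0.01,
    "low_complexity": 0.01,
}

# repeat-derived siRNA mixture (fractions of the repeat slice)
DEFAULT_REPEAT_WEIGHTS = {
    "retrotransposon/LTR-gypsy": 0.40,
    "transposon": 0.06,
    "MITE": 0.05,
    "centromere/telomere/ribosomal": 0.06,
    "TC EST": 0.27,
    "unannotated repeat": 0.16,
}

# redundant-read length profile: the leaf-library triple peak 21/22/24
DEFAULT_SIZE_WEIGHTS = {18: 0.02, 19: 0.03, 20: 0.05, 21: 0.35, 22: 0.20, 23: 0.05, 24: 0.30}

# planted LTR-gypsy size shift: 24-nt-dominated in the tolerant control,
# 21-nt-dominated after 24 h of water depletion
LTR_SIZE_WEIGHTS = {
    "T0h": {20: 0.10, 21: 0.10, 22: 0.20, 24: 0.60},
    "T24h": {20: 0.10, 21: 0.60, 22: 0.10, 24: 0.20},
}

# per-family relative abundance within the miRNA slice, per library;
# miR902 is the planted two-fold down-regulated family in T24h
FAMILY_DESIGN = {
    "miR901": {"T0h": 0.15, "T24h": 0.15, "S0h": 0.15, "S24h": 0.15},  # 22-nt trigger
    "miR901*": {"T0h": 0.02, "T24h": 0.02, "S0h": 0.02, "S24h": 0.02},
    "miR902": {"T0h": 0.20, "T24h": 0.10, "S0h": 0.20, "S24h": 0.20},
    "miR903": {"T0h": 0.08, "T24h": 0.16, "S0h": 0.08, "S24h": 0.08},
    "miR904": {"T0h": 0.12, "T24h": 0.12, "S0h": 0.12, "S24h": 0.12},  # 24 nt
    "miR905": {"T0h": 0.12, "T24h": 0.12, "S0h": 0.06, "S24h": 0.06},
    "miR906": {"T0h": 0.10, "T24h": 0.10, "S0h": 0.14, "S24h": 0.14},
    "miR907": {"T0h": 0.11, "T24h": 0.11, "S0h": 0.11, "S24h": 0.13},
    "miR908": {"T0h": 0.10, "T24h": 0.12, "S0h": 0.12, "S24h": 0.10},
}
FAMILY_LENGTHS = {
    "miR901": 22, "miR901*": 22, "miR902": 21, "miR903": 21, "miR904": 24,
    "miR905": 21, "miR906": 21, "miR907": 21, "miR908": 20,
}

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class SyntheticSettings:
    reads_per_library: int = 100_000
    raw_read_length: int = 36
    adapter3: str = DEFAULT_ADAPTER
    five_prime_u_prob: float = 0.8
    background_vocab: int = 1200
    contaminant_vocab: int = 400
    seed: int = 0


@dataclass
class PlantedSite:
    mirna_id: str
    mirna_seq: str
    transcript_id: str
    start: int
    end: int
    expect_pass: bool
    violated_rules: tuple[str, ...] = ()


@dataclass
class TasiLocus:
    trigger_id: str
    trigger_seq: str
    transcript_id: str
    site_start: int
    site_end: int
    cleavage: int
    representative: str
    member_weights: dict[str, float] = field(default_factory=dict)


@dataclass
class LibraryTruth:
    filter_stages: dict[str, int] = field(default_factory=dict)
    family_counts: dict[str, int] = field(default_factory=dict)
    category_counts: dict[str, int] = field(default_factory=dict)
    tasirna_member_counts: dict[str, int] = field(default_factory=dict)
    total_filtered_reads: int = 0


@dataclass
class SyntheticTruth:
    mirna_reference: list[tuple[str, str]] = field(default_factory=list)
    families: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    contaminants: list[tuple[str, str]] = field(default_factory=list)
    transcripts: list[tuple[str, str]] = field(default_factory=list)
    repeats: list[tuple[str, str]] = field(default_factory=list)
    repeat_annotation: dict[str, str] = field(default_factory=dict)
    est_source_ids: list[str] = field(default_factory=list)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    tasirna: TasiLocus | None = None
    per_library: dict[str, LibraryTruth] = field(default_factory=dict)
    seed: int = 0


@dataclass
class SyntheticDataset:
    settings: SyntheticSettings
    truth: SyntheticTruth
    libraries: list[Library]
    raw_reads: dict[str, list[str]]  # library id -> shuffled raw reads


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _clean(seq: str, adapter6: str) -> bool:
    return adapter6 not in seq and "N" not in seq and len(set(seq)) >= 3


def _rand_clean_seq(rng, n, adapter6) -> str:
    while True:
        s = _rand_seq(rng, n)
        if _clean(s, adapter6):
            return s


def _choose_weighted(rng, weights: dict) -> object:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _min_window_distance(a: str, b: str) -> int:
    """Minimal Hamming distance of the shorter over windows of the longer."""
    if len(a) > len(b):
        a, b = b, a
    return min(
        sum(x != y for x, y in zip(a, b[o : o + len(a)]))
        for o in range(len(b) - len(a) + 1)
    )


def _site_window(mirna: str, mods: dict[int, str]) -> str:
    """Transcript sense window binding ``mirna``, with per-position overrides.

    ``mods`` maps a miRNA position (1-based from the 5' end) to the
    paired target base to plant there instead of the WC partner.
    """
    paired = [_COMP[b] for b in mirna]
    for pos, base in mods.items():
        paired[pos - 1] = base
    return "".join(paired)[::-1]


def generate_references(
    settings: SyntheticSettings | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticTruth:
    """miRNA/contaminant/transcript/repeat references plus planted sites."""
    settings = settings or SyntheticSettings()
    rng = rng if rng is not None else np.random.default_rng(settings.seed)
    adapter6 = settings.adapter3[:6]
    truth = SyntheticTruth(seed=settings.seed)

    # mature miRNA families, mutually >= 8 mismatches apart
    matures: list[str] = []
    for family in FAMILY_DESIGN:
        if family.endswith("*"):
            continue
        L = FAMILY_LENGTHS[family]
        while True:
            seq = _rand_clean_seq(rng, L, adapter6)
            if rng.random() < settings.five_prime_u_prob:
                seq = "T" + seq[1:]
            if all(_min_window_distance(seq, m) >= 8 for m in matures):
                break
        matures.append(seq)
        num = family[3:]
        refs = [(f"ssp-miR{num}a", seq)]
        if family in ("miR902", "miR905"):  # second mature variant
            mid = L // 2
            var = seq[:mid] + _MM_BASE[seq[mid]] + seq[mid + 1 :]
            refs.append((f"ssp-miR{num}b", var))
        truth.families[family] = refs
        truth.mirna_reference.extend(refs)
    star_src = dict(truth.families["miR901"])["ssp-miR901a"]
    star = reverse_complement(star_src)
    truth.families["miR901*"] = [("ssp-miR901a*", star)]
    truth.mirna_reference.append(("ssp-miR901a*", star))
    truth.mirna_reference.sort()

    # contaminant t/rRNA-type references
    truth.contaminants = [
        ("rRNA_1", _rand_clean_seq(rng, 300, adapter6)),
        ("tRNA_1", _rand_clean_seq(rng, 75, adapter6)),
        ("snoRNA_1", _rand_clean_seq(rng, 120, adapter6)),
    ]

    # transcripts with planted target sites and decoys
    trigger_id, trigger = truth.families["miR901"][0]
    mir903_id, mir903 = truth.families["miR903"][0]

    def embed(tid: str, length: int, window: str, start: int) -> str:
        assert start + len(window) - 1 <= length
        t = _rand_seq(rng, length)
        t = t[: start - 1] + window + t[start - 1 + len(window) :]
        return t

    # passing site 1: the 22-nt trigger, perfect complement
    t1 = embed("TC134001", 900, _site_window(trigger, {}), 301)
    # passing site 2: miR903 with one wobble outside positions 1-12
    wobble_pos = next(
        (p for p in range(13, len(mir903) + 1) if mir903[p - 1] in "GT"), None
    )
    mods2 = {}
    if wobble_pos is not None:
        mods2 = {wobble_pos: "T" if mir903[wobble_pos - 1] == "G" else "G"}
    t2 = embed("TC134002", 800, _site_window(mir903, mods2), 201)
    # decoys for the trigger, each violating a named duplex rule
    decoy_mods = {
        "R4": {10: _MM_BASE[trigger[9]]},
        "R2": {p: _MM_BASE[trigger[p - 1]] for p in (14, 15, 16)},
        "R1": {p: _MM_BASE[trigger[p - 1]] for p in (13, 15, 17, 19, 21)},
    }
    t3 = embed("TC134003", 700, _site_window(trigger, decoy_mods["R4"]), 101)
    t4 = embed("TC134004", 700, _site_window(trigger, decoy_mods["R2"]), 151)
    t5 = embed("TC134005", 700, _site_window(trigger, decoy_mods["R1"]), 251)
    t6 = _rand_seq(rng, 850)
    t7 = _rand_seq(rng, 650)
    t8 = _rand_seq(rng, 750)
    truth.transcripts = [
        ("TC134001", t1), ("TC134002", t2), ("TC134003", t3), ("TC134004", t4),
        ("TC134005", t5), ("TC134006", t6), ("CA229001", t7), ("CA229002", t8),
    ]
    # EST-derived siRNA reads are drawn only from transcripts without a
    # planted binding window, so windows overlapping a (decoy) site can
    # never masquerade as miRNA-family reads
    truth.est_source_ids = ["TC134006", "CA229001", "CA229002"]

    def record_site(mid, mseq, tid, tseq, start, expect_pass):
        duplex = align_duplex(mseq, tseq, start)
        rules = check_rules(duplex)
        violated = tuple(r for r in ("R1", "R2", "R3", "R4", "R5", "R6") if not rules[r])
        if expect_pass and violated:
            raise ValueError(f"planted site at {tid}:{start} fails {violated}")
        if not expect_pass and not violated:
            raise ValueError(f"planted decoy at {tid}:{start} passes all rules")
        truth.planted_sites.append(
            PlantedSite(mid, mseq, tid, start, start + len(mseq) - 1, expect_pass, violated)
        )

    record_site(trigger_id, trigger, "TC134001", t1, 301, True)
    record_site(mir903_id, mir903, "TC134002", t2, 201, True)
    record_site(trigger_id, trigger, "TC134003", t3, 101, False)
    record_site(trigger_id, trigger, "TC134004", t4, 151, False)
    record_site(trigger_id, trigger, "TC134005", t5, 251, False)

    # repeat references with class labels
    truth.repeats = [
        ("RPT_gypsy_1", _rand_seq(rng, 2500)),
        ("RPT_gypsy_2", _rand_seq(rng, 1800)),
        ("RPT_dna_1", _rand_seq(rng, 1200)),
        ("RPT_mite_1", _rand_seq(rng, 400)),
        ("RPT_rdna_1", _rand_seq(rng, 800)),
        ("RPT_unk_1", _rand_seq(rng, 900)),
    ]
    truth.repeat_annotation = {
        "RPT_gypsy_1": "retrotransposon/LTR-gypsy",
        "RPT_gypsy_2": "retrotransposon/LTR-gypsy",
        "RPT_dna_1": "transposon",
        "RPT_mite_1": "MITE",
        "RPT_rdna_1": "centromere/telomere/ribosomal",
        "RPT_unk_1": "unannotated",
    }

    # ta-siRNA locus: sense fragments of the trigger target, anchored at
    # the cleavage site (the 3' cleavage fragment RDR6 would copy)
    site_start, site_end = 301, 301 + len(trigger) - 1
    cleav = site_end - 9
    c0 = cleav - 1  # 0-based
    members = {
        t1[c0 : c0 + 21]: 0.55,
        t1[c0 : c0 + 22]: 0.20,
        t1[c0 + 1 : c0 + 22]: 0.15,
        t1[c0 - 2 : c0 + 19]: 0.10,
    }
    for seq in members:
        if not _clean(seq, adapter6):
            raise ValueError("ta-siRNA member insert not clean; choose another seed")
        if match_read(seq, truth.mirna_reference, 3) is not None:
            raise ValueError("ta-siRNA member collides with a miRNA reference")
    truth.tasirna = TasiLocus(
        trigger_id, trigger, "TC134001", site_start, site_end, cleav,
        representative=t1[c0 : c0 + 21], member_weights=members,
    )
    return truth


def _background_vocab(truth: SyntheticTruth, settings, rng) -> list[str]:
    """Distinct reads that match no reference (clean negatives)."""
    adapter6 = settings.adapter3[:6]
    blob = "#".join(
        s for _, s in truth.contaminants + truth.transcripts + truth.repeats
    )
    rc_blob = reverse_complement(blob)  # '#' separators pass through untouched
    vocab: list[str] = []
    while len(vocab) < settings.background_vocab:
        L = int(_choose_weighted(rng, DEFAULT_SIZE_WEIGHTS))
        s = _rand_clean_seq(rng, L, adapter6)
        if s in blob or s in rc_blob:
            continue
        if match_read(s, truth.mirna_reference, 3) is not None:
            continue
        vocab.append(s)
    return vocab


def _sample_window(rng, ref: str, length: int, adapter6: str) -> str:
    for _ in range(200):
        start = int(rng.integers(0, len(ref) - length + 1))
        s = ref[start : start + length]
        if rng.random() < 0.5:
            s = reverse_complement(s)
        if _clean(s, adapter6):
            return s
    raise RuntimeError("could not sample a clean window")


def generate_libraries(
    truth: SyntheticTruth,
    settings: SyntheticSettings,
    rng: np.random.Generator,
) -> tuple[list[Library], dict[str, list[str]]]:
    """Sample per-library raw reads (insert + 3' adapter) and record truth."""
    adapter = settings.adapter3
    adapter6 = adapter[:6]
    raw_len = settings.raw_read_length
    comp_names = list(DEFAULT_COMPOSITION)
    comp_probs = np.array([DEFAULT_COMPOSITION[c] for c in comp_names])

    # variant-level miRNA emission weights
    variant_rows = []  # (family, seq, per-library weight)
    for family, refs in truth.families.items():
        per_lib = FAMILY_DESIGN[family]
        split = [1.0] if len(refs) == 1 else [0.75, 0.25]
        for (ref_id, seq), frac in zip(refs, split):
            variant_rows.append((family, seq, {k: v * frac for k, v in per_lib.items()}))

    cat_refs = {
        "retrotransposon/LTR-gypsy": ["RPT_gypsy_1", "RPT_gypsy_2"],
        "transposon": ["RPT_dna_1"],
        "MITE": ["RPT_mite_1"],
        "centromere/telomere/ribosomal": ["RPT_rdna_1"],
        "TC EST": truth.est_source_ids,
        "unannotated repeat": ["RPT_unk_1"],
    }
    ref_seqs = dict(truth.repeats + truth.transcripts)
    vocab = _background_vocab(truth, settings, rng)
    tasi_members = list(truth.tasirna.member_weights)
    tasi_probs = np.array([truth.tasirna.member_weights[m] for m in tasi_members])

    libraries: list[Library] = []
    raw_reads: dict[str, list[str]] = {}
    for lib_id, (tissue, group, timepoint) in DEFAULT_LIBRARIES.items():
        lt = LibraryTruth()
        n = settings.reads_per_library
        slice_counts = dict(zip(comp_names, rng.multinomial(n, comp_probs)))
        inserts: list[str] = []

        # conserved miRNAs
        w = np.array([row[2][lib_id] for row in variant_rows])
        vcounts = rng.multinomial(slice_counts["mirna"], w / w.sum())
        for (family, seq, _), k in zip(variant_rows, vcounts):
            inserts.extend([seq] * int(k))
            lt.family_counts[family] = lt.family_counts.get(family, 0) + int(k)

        # contaminant-derived reads
        for _ in range(slice_counts["contaminant"]):
            _, ref = truth.contaminants[int(rng.integers(len(truth.contaminants)))]
            L = int(_choose_weighted(rng, DEFAULT_SIZE_WEIGHTS))
            inserts.append(_sample_window(rng, ref, L, adapter6))

        # ta-siRNA fragment tiles
        mcounts = rng.multinomial(slice_counts["tasirna"], tasi_probs / tasi_probs.sum())
        for seq, k in zip(tasi_members, mcounts):
            inserts.extend([seq] * int(k))
            lt.tasirna_member_counts[seq] = int(k)
        lt.category_counts["TC EST"] = int(slice_counts["tasirna"])

        # repeat-derived siRNAs
        cat_names = list(DEFAULT_REPEAT_WEIGHTS)
        cat_p = np.array([DEFAULT_REPEAT_WEIGHTS[c] for c in cat_names])
        ccounts = rng.multinomial(slice_counts["repeat"], cat_p / cat_p.sum())
        for cat, k in zip(cat_names, ccounts):
            size_w = DEFAULT_SIZE_WEIGHTS
            if cat == "retrotransposon/LTR-gypsy":
                size_w = LTR_SIZE_WEIGHTS.get(lib_id, DEFAULT_SIZE_WEIGHTS)
            for _ in range(int(k)):
                rid = cat_refs[cat][int(rng.integers(len(cat_refs[cat])))]
                L = int(_choose_weighted(rng, size_w))
                inserts.append(_sample_window(rng, ref_seqs[rid], L, adapter6))
            lt.category_counts[cat] = lt.category_counts.get(cat, 0) + int(k)

        # background (maps nowhere)
        picks = rng.integers(0, len(vocab), slice_counts["background"])
        inserts.extend(vocab[i] for i in picks)
        lt.category_counts["unannotated-siRNA-cluster"] = int(slice_counts["background"])

        # planted filter attrition
        n_n = slice_counts["n_fail"]
        for _ in range(n_n):
            s = _rand_clean_seq(rng, 21, adapter6)
            p = int(rng.integers(21))
            inserts.append(s[:p] + "N" + s[p + 1 :])
        n_len = slice_counts["length_fail"]
        for i in range(n_len):
            inserts.append(_rand_clean_seq(rng, 17 if i % 2 == 0 else 29, adapter6))
        n_cplx = slice_counts["low_complexity"]
        for _ in range(n_cplx):
            a, b = rng.choice(4, 2, replace=False)
            pat = ("ACGT"[a] + "ACGT"[b]) * 11
            inserts.append(pat[:21])

        lt.filter_stages = {
            "input_reads": n,
            "after_trim": n - int(n_n),
            "after_length": n - int(n_n) - int(n_len),
            "after_complexity": n - int(n_n) - int(n_len) - int(n_cplx),
            "after_contaminant": n - int(n_n) - int(n_len) - int(n_cplx)
            - int(slice_counts["contaminant"]),
        }
        lt.total_filtered_reads = lt.filter_stages["after_contaminant"]

        raws = [(insert + adapter)[:raw_len] for insert in inserts]
        order = rng.permutation(len(raws))
        raw_reads[lib_id] = [raws[i] for i in order]
        libraries.append(
            Library(lib_id, tissue, group, timepoint, lt.total_filtered_reads)
        )
        truth.per_library[lib_id] = lt
    return libraries, raw_reads


def generate_dataset(
    settings: SyntheticSettings | None = None, seed: int | None = None
) -> SyntheticDataset:
    """References + four libraries + truth, all in memory."""
    settings = settings or SyntheticSettings()
    if seed is not None:
        settings.seed = seed
    rng = np.random.default_rng(settings.seed)
    truth = generate_references(settings, rng)
    libraries, raw_reads = generate_libraries(truth, settings, rng)
    return SyntheticDataset(settings, truth, libraries, raw_reads)


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write FASTQ libraries, reference FASTAs, annotation and a run config."""
    import os

    import yaml

    from .io import write_fasta

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    truth = dataset.truth
    write_fasta(truth.mirna_reference, p("mirna_reference.fasta"))
    write_fasta(truth.contaminants, p("contaminants.fasta"))
    write_fasta(truth.transcripts, p("transcripts.fasta"))
    write_fasta(truth.repeats, p("repeats.fasta"))
    with open(p("repeat_annotation.tsv"), "w") as fh:
        fh.write("reference_id\tclass\n")
        for rid, cls in sorted(truth.repeat_annotation.items()):
            fh.write(f"{rid}\t{cls}\n")
    for lib in dataset.libraries:
        path = p(f"{lib.id}.fastq")
        with open(path, "w") as fh:
            for i, raw in enumerate(dataset.raw_reads[lib.id], 1):
                fh.write(f"@{lib.id}_{i}\n{raw}\n+\n{'I' * len(raw)}\n")
    run_cfg = {
        "adapter3": dataset.settings.adapter3,
        "references": {
            "mirna": "mirna_reference.fasta",
            "contaminants": "contaminants.fasta",
            "transcripts": "transcripts.fasta",
            "repeats": "repeats.fasta",
            "repeat_annotation": "repeat_annotation.tsv",
        },
        "libraries": [
            {
                "id": lib.id,
                "fastq": f"{lib.id}.fastq",
                "tissue": lib.tissue,
                "group": lib.group,
                "timepoint": lib.timepoint,
            }
            for lib in dataset.libraries
        ],
        "thresholds": PipelineConfig(rng_seed=dataset.settings.seed).to_dict(),
    }
    with open(p("config.yaml"), "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=False)
    return paths
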