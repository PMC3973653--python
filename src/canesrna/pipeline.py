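"""End-to-end orchestration of the analysis stages.

Stage order follows the analysis flow: filter -> miRNA profiling ->
differential expression -> target prediction -> siRNA discovery ->
siRNA clusters.  Each stage can write its TSV outputs under an output
directory, and a run manifest records config hash, stage outputs and
row counts so reruns can be compared (identical inputs give identical
manifests).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .config import PipelineConfig
from .io import (
    CollapsedRead,
    Library,
    merge_collapsed,
    read_fasta,
    read_sequences,
    write_collapsed_fasta,
    write_table,
)
from .preprocess import FilterReport, preprocess_library
from .profiler import (
    MiRNAHit,
    assign_variant_labels,
    build_expression_table,
    composition_summary,
    match_reads,
    set_overlap,
)
from .diffexpr import test_library_pair
from .targets import TargetSite, predict_targets
from .sirna import discover_sirna, filter_abundance, presence_overlap, select_triggers
from .clusters import annotate_and_tabulate, build_clusters, map_reads

STAGES = ("preprocess", "profile", "diffexp", "targets", "sirna", "clusters")


@dataclass
class PipelineInputs:
    adapter3: str
    mirna_reference: list[tuple[str, str]]
    contaminants: list[tuple[str, str]]
    transcripts: list[tuple[str, str]]
    repeats: list[tuple[str, str]]
    repeat_annotation: dict[str, str]
    library_meta: list[Library]  # totals filled by the preprocess stage
    raw_reads: dict[str, list[tuple[str, int]]]  # library id -> (seq, mult)


@dataclass
class PipelineResult:
    config: PipelineConfig
    libraries: list[Library] = field(default_factory=list)
    reports: dict[str, FilterReport] = field(default_factory=dict)
    collapsed: list[CollapsedRead] = field(default_factory=list)
    hits: dict[str, MiRNAHit] = field(default_factory=dict)
    expression: pd.DataFrame | None = None
    composition: tuple | None = None
    venn: dict | None = None
    regulation: pd.DataFrame | None = None
    target_sites: list[TargetSite] = field(default_factory=list)
    triggers: list[str] = field(default_factory=list)
    sirna_candidates: list = field(default_factory=list)
    sirna_core: list = field(default_factory=list)
    category_fractions: pd.DataFrame | None = None
    category_length_hist: pd.DataFrame | None = None
    clusters: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def load_inputs(config_path) -> tuple[PipelineInputs, PipelineConfig]:
    """Read a YAML run config and every input file it references."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = os.path.dirname(os.path.abspath(config_path))

    def resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    refs = cfg.get("references", {})
    missing = [k for k in ("mirna", "contaminants", "transcripts") if k not in refs]
    if missing:
        raise ValueError(f"config missing references: {missing}")
    for key in refs:
        if not os.path.exists(resolve(refs[key])):
            raise FileNotFoundError(f"reference file not found: {refs[key]}")

    repeat_annotation: dict[str, str] = {}
    if "repeat_annotation" in refs:
        ann = pd.read_csv(resolve(refs["repeat_annotation"]), sep="\t")
        repeat_annotation = dict(zip(ann.iloc[:, 0], ann.iloc[:, 1]))

    library_meta: list[Library] = []
    raw_reads: dict[str, list[tuple[str, int]]] = {}
    for entry in cfg.get("libraries", []):
        lib = Library(
            id=entry["id"],
            tissue=entry.get("tissue", "leaf"),
            group=entry.get("group", "tolerant-pool"),
            timepoint=entry.get("timepoint", "0h"),
            total_filtered_reads=0,
        )
        library_meta.append(lib)
        fastq = resolve(entry["fastq"])
        if not os.path.exists(fastq):
            raise FileNotFoundError(f"library file not found: {fastq}")
        raw_reads[lib.id] = read_sequences(fastq, entry.get("format"))

    inputs = PipelineInputs(
        adapter3=cfg.get("adapter3", "TGGAATTCTCGGGTGCCAAGG"),
        mirna_reference=read_fasta(resolve(refs["mirna"])),
        contaminants=read_fasta(resolve(refs["contaminants"])),
        transcripts=read_fasta(resolve(refs["transcripts"])),
        repeats=read_fasta(resolve(refs["repeats"])) if "repeats" in refs else [],
        repeat_annotation=repeat_annotation,
        library_meta=library_meta,
        raw_reads=raw_reads,
    )
    pipeline_cfg = PipelineConfig.from_dict(cfg.get("thresholds", {}))
    return inputs, pipeline_cfg


def default_pairs(libraries: Sequence[Library]) -> list[tuple[str, str]]:
    """Control-vs-stress within group and tolerant-vs-sensitive within timepoint."""
    pairs = []
    by_id = {lib.id: lib for lib in libraries}
    ids = sorted(by_id)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            la, lb = by_id[a], by_id[b]
            if la.tissue != lb.tissue:
                continue
            same_group_diff_time = la.group == lb.group and la.timepoint != lb.timepoint
            same_time_diff_group = la.timepoint == lb.timepoint and la.group != lb.group
            if same_group_diff_time:
                pairs.append((a, b) if la.timepoint < lb.timepoint else (b, a))
            elif same_time_diff_group:
                # tolerant libraries conventionally come first in the contrast
                pairs.append((a, b) if la.group.startswith("tolerant") else (b, a))
    return pairs


def run_pipeline(
    inputs: PipelineInputs,
    config: PipelineConfig | None = None,
    outdir: str | None = None,
    stages: Sequence[str] | None = None,
) -> PipelineResult:
    """Execute the requested stages (and their prerequisites) in order.

    When ``outdir`` is given, each *requested* stage writes its TSVs
    there; prerequisite stages run in memory without writing.
    """
    cfg = config or PipelineConfig()
    requested = list(stages) if stages else list(STAGES)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    # run everything up to the last requested stage; write only requested
    last = max(STAGES.index(s) for s in requested)
    to_run = STAGES[: last + 1]

    result = PipelineResult(config=cfg)
    manifest_stages = []

    def emits(stage: str) -> bool:
        return outdir is not None and stage in requested

    # --- preprocess ---------------------------------------------------------
    per_library: dict[str, list[CollapsedRead]] = {}
    for meta in inputs.library_meta:
        collapsed, report = preprocess_library(
            inputs.raw_reads[meta.id],
            inputs.adapter3,
            inputs.contaminants,
            meta.id,
            l_min=cfg.l_min,
            l_max=cfg.l_max,
            complexity_min_bases=cfg.complexity_min_bases,
            adapter_min_overlap=cfg.adapter_min_overlap,
        )
        per_library[meta.id] = collapsed
        result.reports[meta.id] = report
        result.libraries.append(
            Library(meta.id, meta.tissue, meta.group, meta.timepoint, report.after_contaminant)
        )
    result.collapsed = merge_collapsed(per_library)
    if emits("preprocess"):
        rows = [
            {"library": lib_id, **vars(rep)} for lib_id, rep in sorted(result.reports.items())
        ]
        df = pd.DataFrame(rows)
        write_table(df, os.path.join(outdir, "filter_report.tsv"))
        manifest_stages.append({"stage": "preprocess", "outputs": {"filter_report.tsv": len(df)}})
        for lib_id, reads in sorted(per_library.items()):
            write_collapsed_fasta(reads, lib_id, os.path.join(outdir, f"{lib_id}.collapsed.fasta"))
            manifest_stages[-1]["outputs"][f"{lib_id}.collapsed.fasta"] = len(reads)
    if "profile" not in to_run:
        return _finish(result, inputs, cfg, outdir, manifest_stages)

    # --- miRNA profiling ----------------------------------------------------
    reads_by_seq = {r.sequence: r for r in result.collapsed}
    result.hits = match_reads(
        reads_by_seq, inputs.mirna_reference, cfg.max_mirna_mismatches
    )
    assign_variant_labels(result.hits.values())
    result.expression = build_expression_table(
        result.hits.values(), reads_by_seq, result.libraries
    )
    if result.hits:
        result.composition = composition_summary(result.hits.values())
    tissues = {lib.tissue for lib in result.libraries}
    venn_key = "tissue" if len(tissues) > 1 else "group"
    groups: dict[str, set[str]] = {}
    for lib in result.libraries:
        key = getattr(lib, venn_key)
        present = {
            seq for seq in result.hits if reads_by_seq[seq].count_in(lib.id) > 0
        }
        groups.setdefault(key, set()).update(present)
    if len(groups) > 1:
        result.venn = set_overlap(groups)
    if emits("profile"):
        write_table(result.expression, os.path.join(outdir, "electronic_northern.tsv"))
        outputs = {"electronic_northern.tsv": len(result.expression)}
        if result.composition:
            hist, five_prime = result.composition
            comp = pd.DataFrame(
                [{"metric": "length", "key": k, "value": v} for k, v in hist.items()]
                + [{"metric": "five_prime_pct", "key": b, "value": v} for b, v in five_prime.items()]
            )
            write_table(comp, os.path.join(outdir, "composition.tsv"))
            outputs["composition.tsv"] = len(comp)
        if result.venn:
            venn_df = pd.DataFrame(
                [{"groups": "&".join(k), "count": v} for k, v in sorted(result.venn.items())]
            )
            write_table(venn_df, os.path.join(outdir, "venn.tsv"))
            outputs["venn.tsv"] = len(venn_df)
        manifest_stages.append({"stage": "profile", "outputs": outputs})
    if "diffexp" not in to_run:
        return _finish(result, inputs, cfg, outdir, manifest_stages)

    # --- differential expression -------------------------------------------
    totals = {lib.id: lib.total_filtered_reads for lib in result.libraries}
    call_rows = []
    for lib_a, lib_b in default_pairs(result.libraries):
        counts = {
            seq: (reads_by_seq[seq].count_in(lib_a), reads_by_seq[seq].count_in(lib_b))
            for seq in result.hits
        }
        for call in test_library_pair(
            counts, totals[lib_a], totals[lib_b], lib_a, lib_b, cfg.alpha
        ):
            hit = result.hits[call.sequence]
            call_rows.append(
                {
                    "family": hit.family,
                    "variant": hit.variant_label,
                    "sequence": call.sequence,
                    "library_a": call.library_a,
                    "library_b": call.library_b,
                    "p_raw": call.p_raw,
                    "p_adj": call.p_adj,
                    "direction": call.direction,
                    "significant": call.significant,
                }
            )
    result.regulation = pd.DataFrame(call_rows)
    if emits("diffexp"):
        df = result.regulation.copy()
        for col in ("p_raw", "p_adj"):
            df[col] = df[col].map("{:.3g}".format)
        write_table(df, os.path.join(outdir, "regulation_calls.tsv"), float_format="%s")
        manifest_stages.append(
            {"stage": "diffexp", "outputs": {"regulation_calls.tsv": len(df)}}
        )
    if "targets" not in to_run:
        return _finish(result, inputs, cfg, outdir, manifest_stages)

    # --- target prediction --------------------------------------------------
    labeled = sorted(
        {(f"{h.family} {h.variant_label}", h.sequence) for h in result.hits.values()}
    )
    for mirna_id, seq in labeled:
        result.target_sites.extend(
            predict_targets(mirna_id, seq, inputs.transcripts, cfg)
        )
    if emits("targets"):
        df = pd.DataFrame(
            [
                {
                    "mirna_id": s.mirna_id,
                    "transcript": s.transcript_id,
                    "start": s.start,
                    "end": s.end,
                    "mismatch_score": s.duplex.mismatch_score_total,
                    "mfe_ratio": round(s.mfe_ratio, 3),
                    "cleavage_position": s.cleavage_position,
                }
                for s in result.target_sites
            ]
        )
        write_table(df, os.path.join(outdir, "target_sites.tsv"), float_format="%.3f")
        manifest_stages.append({"stage": "targets", "outputs": {"target_sites.tsv": len(df)}})
    if "sirna" not in to_run:
        return _finish(result, inputs, cfg, outdir, manifest_stages)

    # --- siRNA discovery ----------------------------------------------------
    result.triggers = select_triggers(result.hits.values())
    trigger_sites = [s for s in result.target_sites if s.mirna_seq in result.triggers]
    pool = [r for r in result.collapsed if r.sequence not in result.hits]
    lib_ids = [lib.id for lib in result.libraries]
    result.sirna_candidates, result.sirna_core = discover_sirna(
        trigger_sites,
        dict(inputs.transcripts),
        pool,
        lib_ids,
        a_min=cfg.min_sirna_alignment,
        c_min=cfg.min_sirna_reads,
        end_tolerance=cfg.merge_end_tolerance,
    )
    if emits("sirna"):
        rows = []
        for cand in result.sirna_candidates:
            row = {
                "sequence": cand.representative,
                "transcripts": ";".join(sorted(cand.loci)),
                "coordinates": ";".join(
                    cand.display_coords(t) for t in sorted(cand.loci)
                ),
                "trigger_mirna": cand.trigger_mirna,
                "cleavage_concordant": cand.cleavage_concordant,
                "phase_register": cand.phase_register,
            }
            for lib_id in lib_ids:
                row[f"raw_{lib_id}"] = cand.counts.get(lib_id, 0)
            for lib_id, rpm in cand.rpm(totals).items():
                row[f"rpm_{lib_id}"] = rpm
            rows.append(row)
        df = pd.DataFrame(rows)
        write_table(df, os.path.join(outdir, "sirna_candidates.tsv"))
        outputs = {"sirna_candidates.tsv": len(df)}
        presence, _ = filter_abundance(result.sirna_candidates, lib_ids, cfg.min_sirna_reads)
        if presence:
            venn_df = pd.DataFrame(
                [
                    {"libraries": "&".join(k), "count": v}
                    for k, v in sorted(presence_overlap(presence).items())
                ]
            )
            write_table(venn_df, os.path.join(outdir, "venn_sirna.tsv"))
            outputs["venn_sirna.tsv"] = len(venn_df)
        manifest_stages.append({"stage": "sirna", "outputs": outputs})
    if "clusters" not in to_run:
        return _finish(result, inputs, cfg, outdir, manifest_stages)

    # --- siRNA clusters -----------------------------------------------------
    pool = [r for r in result.collapsed if r.sequence not in result.hits]
    references = list(inputs.repeats) + list(inputs.transcripts)
    placements, unmapped = map_reads(pool, references)
    result.clusters = build_clusters(placements, cfg.cluster_merge_gap)
    est_ids = {tid for tid, _ in inputs.transcripts}
    pool_counts = {r.sequence: r for r in pool}
    result.category_fractions, result.category_length_hist = annotate_and_tabulate(
        result.clusters,
        inputs.repeat_annotation,
        est_ids,
        pool_counts,
        [lib.id for lib in result.libraries],
        unmapped,
    )
    if emits("clusters"):
        cluster_df = pd.DataFrame(
            [
                {
                    "cluster_id": cl.cluster_id,
                    "reference_id": cl.reference_id,
                    "start": cl.start,
                    "end": cl.end,
                    "category": cl.category,
                    "n_placements": len(cl.placements),
                }
                for cl in result.clusters
            ]
        )
        write_table(cluster_df, os.path.join(outdir, "cluster_table.tsv"))
        write_table(
            result.category_fractions,
            os.path.join(outdir, "category_fractions.tsv"),
            float_format="%.4f",
        )
        write_table(
            result.category_length_hist,
            os.path.join(outdir, "category_length_hist.tsv"),
            float_format="%.2f",
        )
        manifest_stages.append(
            {
                "stage": "clusters",
                "outputs": {
                    "cluster_table.tsv": len(cluster_df),
                    "category_fractions.tsv": len(result.category_fractions),
                    "category_length_hist.tsv": len(result.category_length_hist),
                },
            }
        )
    return _finish(result, inputs, cfg, outdir, manifest_stages)


def _config_hash(inputs: PipelineInputs, cfg: PipelineConfig) -> str:
    payload = {
        "config": cfg.to_dict(),
        "adapter3": inputs.adapter3,
        "libraries": [lib.id for lib in inputs.library_meta],
        "n_reference": len(inputs.mirna_reference),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _finish(result, inputs, cfg, outdir, manifest_stages) -> PipelineResult:
    result.manifest = {
        "tool_version": __version__,
        "config_hash": _config_hash(inputs, cfg),
        "seed": cfg.rng_seed,
        "stages": manifest_stages,
    }
    if outdir is not None:
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(result.manifest, fh, indent=2, sort_keys=True)
    return result
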