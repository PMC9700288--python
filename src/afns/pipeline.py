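"""End-to-end orchestration of the assembly-free novel-sequence flow.

Stages, in order: select reads bearing unmapped fragments, quality-filter
and adapter-trim them, refine fragments through the multi-round
align-and-subtract loop, remove contaminants, cluster redundant
candidates and keep the longest representative of each cluster, and drop
representatives that are mostly low-complexity/simple repeat.  Every
numeric threshold lives in :class:`PipelineConfig` with the published
defaults.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from .align import KmerIndex, PRESETS, all_vs_all, index_reference
from .cluster import build_clusters, representatives
from .contam import Taxonomy, filter_contaminants
from .extract import (
    CandidateFragment,
    RoundConfig,
    extract_candidates,
    run_rounds,
)
from .io import AlignmentRecord, Interval, SeqRecord, TaxonomicCall
from .mask import repeat_filter
from .qc import run_qc

__all__ = [
    "PipelineConfig",
    "StageReport",
    "AfnsResult",
    "run_afns",
    "classify_common_specific",
    "calls_for_fragments",
]


@dataclass
class PipelineConfig:
    """Every tunable of the discovery and placement flows, in one place."""

    min_fragment_len: int = 300
    min_mean_q: float = 10.0
    n_rounds: int = 3
    conf_threshold: float = 0.05
    cov_threshold: float = 0.8
    identity_threshold: float = 0.8
    max_masked_frac: float = 0.8
    placement_min_len: int = 1000
    merge_dist: int = 100
    min_support: int = 3
    seed: int = 42
    k: int = 15
    qc_first: bool = False          # default: select unmapped-bearing reads first
    reciprocal_coverage: bool = False
    adapter_end_window: int = 150
    adapter_min_identity: float = 0.75
    adapter_min_match: int = 10

    def validate(self) -> None:
        for name in (
            "min_fragment_len", "min_mean_q", "n_rounds", "conf_threshold",
            "cov_threshold", "identity_threshold", "max_masked_frac",
            "placement_min_len", "merge_dist", "min_support",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")

    def manifest(self) -> dict:
        cfg = asdict(self)
        digest = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16]
        return {"config": cfg, "config_hash": digest}


@dataclass
class StageReport:
    stage: str
    n_in: int
    n_out: int
    detail: dict = field(default_factory=dict)


@dataclass
class AfnsResult:
    final_records: list[SeqRecord]
    stage_reports: list[StageReport]
    fragments_by_stage: dict[str, list[CandidateFragment]]
    read_alignments: dict[str, list[AlignmentRecord]]
    manifest: dict


def calls_for_fragments(
    fragments: list[CandidateFragment], read_calls: list[TaxonomicCall]
) -> list[TaxonomicCall]:
    """Re-key per-read classifications onto the fragments they produced.

    A classifier run upstream labels whole reads; each fragment inherits
    its source read's call.  Fragments from unlabelled reads get none.
    """
    by_read = {c.seq_id: c for c in read_calls}
    out = []
    for frag in fragments:
        call = by_read.get(frag.source_read_id)
        if call is not None:
            out.append(
                TaxonomicCall(
                    frag.fragment_id, call.classified, call.taxid,
                    len(frag.sequence), list(call.lca_counts),
                )
            )
    return out


def run_afns(
    reads: list[SeqRecord],
    reference: list[SeqRecord] | SeqRecord,
    config: PipelineConfig | None = None,
    adapters: list[SeqRecord] | None = None,
    read_calls: list[TaxonomicCall] | None = None,
    taxonomy: Taxonomy | None = None,
    reference_index: KmerIndex | None = None,
) -> AfnsResult:
    """Run the full discovery flow and return the final novel set.

    ``read_calls`` are per-read classifier lines (contaminant screening
    is skipped when absent), ``taxonomy`` the matching taxonomy.  The
    reference index can be passed in to share it across samples.
    """
    config = config or PipelineConfig()
    config.validate()
    reports: list[StageReport] = []
    stages: dict[str, list[CandidateFragment]] = {}

    if reference_index is None:
        reference_index = index_reference(reference, k=config.k)

    # stage 0: optional QC-first mode
    working = reads
    if config.qc_first:
        working, qc_rep = run_qc(
            working, adapters, config.min_mean_q,
            config.adapter_end_window, config.adapter_min_identity,
            config.adapter_min_match,
        )
        reports.append(StageReport("qc", qc_rep.n_input, len(working),
                                   {"fail_quality": qc_rep.n_fail_quality}))

    # stage 1: select reads with unmapped fragments > min_fragment_len
    candidates, read_alignments = extract_candidates(
        working, reference_index, min_len=config.min_fragment_len,
        preset=PRESETS["map-long"],
    )
    selected_ids = {c.source_read_id for c in candidates}
    selected = [r for r in working if r.id in selected_ids]
    reports.append(StageReport("select", len(working), len(selected),
                               {"candidate_fragments": len(candidates)}))

    # stage 2: QC on the selected reads (paper order)
    if not config.qc_first:
        selected, qc_rep = run_qc(
            selected, adapters, config.min_mean_q,
            config.adapter_end_window, config.adapter_min_identity,
            config.adapter_min_match,
        )
        reports.append(StageReport("qc", qc_rep.n_input, len(selected),
                                   {"fail_quality": qc_rep.n_fail_quality,
                                    "trimmed": qc_rep.n_trimmed}))
        kept_ids = {r.id for r in selected}
        by_read = {r.id: r for r in selected}
        refreshed = []
        for frag in candidates:
            if frag.source_read_id not in kept_ids:
                continue
            read = by_read[frag.source_read_id]
            # trimming may have shortened the read; re-clip the fragment
            end = min(frag.read_interval.end, len(read.sequence))
            if end - frag.read_interval.start <= config.min_fragment_len:
                continue
            refreshed.append(
                CandidateFragment(
                    f"{read.id}:{frag.read_interval.start}-{end}",
                    read.id,
                    Interval(frag.read_interval.start, end),
                    read.sequence[frag.read_interval.start : end],
                    frag.round_created,
                )
            )
        candidates = refreshed
    stages["initial"] = candidates

    # stage 3: multi-round align-and-subtract
    rounds = RoundConfig.default_rounds()[: config.n_rounds]
    survivors = run_rounds(
        candidates, reference_index, rounds, min_len=config.min_fragment_len
    )
    reports.append(StageReport("rounds", len(candidates), len(survivors)))
    stages["after_rounds"] = survivors

    # stage 4: contaminant removal
    if read_calls is not None and taxonomy is not None:
        frag_calls = calls_for_fragments(survivors, read_calls)
        survivors, removed = filter_contaminants(
            survivors, frag_calls, taxonomy, config.conf_threshold
        )
        reports.append(
            StageReport("decontam", len(removed) + len(survivors), len(survivors),
                        {"removed": [r[0] for r in removed]})
        )
    stages["after_decontam"] = survivors

    # stage 5: redundancy clustering, longest representative
    frag_records = [f.as_record() for f in survivors]
    ava = all_vs_all(frag_records, k=config.k) if len(frag_records) > 1 else []
    clusters = build_clusters(
        frag_records, ava, config.cov_threshold, config.reciprocal_coverage
    )
    reps = representatives(clusters, frag_records)
    reports.append(StageReport("cluster", len(frag_records), len(reps),
                               {"clusters": len(clusters)}))
    rep_ids = {r.id for r in reps}
    rep_frags = [f for f in survivors if f.fragment_id in rep_ids]
    stages["representatives"] = rep_frags

    # stage 6: repeat-fraction filter
    kept, dropped = repeat_filter(rep_frags, config.max_masked_frac)
    reports.append(StageReport("mask_filter", len(rep_frags), len(kept),
                               {"dropped": [f.fragment_id for f, _ in dropped]}))
    stages["final"] = kept

    final_records = sorted(
        (f.as_record() for f in kept), key=lambda r: (-len(r.sequence), r.id)
    )
    return AfnsResult(
        final_records=final_records,
        stage_reports=reports,
        fragments_by_stage=stages,
        read_alignments=read_alignments,
        manifest=config.manifest(),
    )


def classify_common_specific(
    novel_sets: dict[str, list[SeqRecord]],
    identity_threshold: float = 0.8,
    k: int = 15,
) -> dict[str, dict[str, str]]:
    """Label each sample's sequences common vs individual-specific.

    A sequence is common when it aligns to any other sample's sequence at
    >= identity_threshold; the relation is applied symmetrically.
    Returns {sample: {seq_id: "common" | "individual-specific"}}.
    """
    if len(novel_sets) < 2:
        raise ValueError("need at least two samples' novel sets")
    tagged: list[SeqRecord] = []
    owner: dict[str, str] = {}
    for sample, recs in sorted(novel_sets.items()):
        for rec in recs:
            tid = f"{sample}|{rec.id}"
            tagged.append(SeqRecord(tid, rec.sequence))
            owner[tid] = sample
    common: set[str] = set()
    ava = all_vs_all(tagged, k=k) if len(tagged) > 1 else []
    for rec in ava:
        if owner[rec.query_id] == owner[rec.target_id]:
            continue
        if rec.identity >= identity_threshold:
            common.add(rec.query_id)
            common.add(rec.target_id)
    labels: dict[str, dict[str, str]] = {s: {} for s in novel_sets}
    for tid in owner:
        sample, seq_id = tid.split("|", 1)
        labels[sample][seq_id] = (
            "common" if tid in common else "individual-specific"
        )
    return labels
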