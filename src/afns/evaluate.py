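"""Truth-table comparison of pipeline output against a simulated study.

Given the simulator's planted insertions and read provenance, these
helpers measure what the discovery and placement flows recovered:
fraction of planted insertions matched by a final representative,
contaminant leakage, breakpoint accuracy of placement clusters, and
agreement of sharing labels with planted categories.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import align, index_reference
from .io import SeqRecord
from .placement import PlacementCluster
from .sim import SimResult

__all__ = [
    "RecoveryReport",
    "insertion_recovery",
    "contaminant_representatives",
    "placement_recovery",
    "bep_breakpoint_offsets",
    "sharing_label_accuracy",
]


@dataclass
class RecoveryReport:
    n_recovered: int
    n_eligible: int
    missed: list[str]

    @property
    def fraction(self) -> float:
        return self.n_recovered / self.n_eligible if self.n_eligible else 1.0


def insertion_recovery(
    final_records: list[SeqRecord],
    sim: SimResult,
    sample: str,
    min_len: int = 300,
    min_identity: float = 0.9,
    k: int = 15,
) -> RecoveryReport:
    """Fraction of the sample's planted insertions longer than ``min_len``
    recovered by a final representative aligning at >= min_identity."""
    eligible = [
        ins
        for ins in sim.truth.insertions
        if sample in ins.samples and len(ins.sequence) > min_len
    ]
    if not final_records:
        return RecoveryReport(0, len(eligible), [i.insertion_id for i in eligible])
    rep_index = index_reference(final_records, k=k)
    recovered = 0
    missed = []
    for ins in eligible:
        hits = align(SeqRecord(ins.insertion_id, ins.sequence), rep_index, "map-long")
        if any(h.identity >= min_identity for h in hits):
            recovered += 1
        else:
            missed.append(ins.insertion_id)
    return RecoveryReport(recovered, len(eligible), missed)


def contaminant_representatives(
    final_records: list[SeqRecord], sim: SimResult
) -> list[str]:
    """Final representatives whose source read was a contaminant."""
    out = []
    for rec in final_records:
        read_id = rec.id.split(":")[0]
        prov = sim.truth.read_provenance.get(read_id)
        if prov is not None and prov.source == "contaminant":
            out.append(rec.id)
    return out


def _span_distance(cluster: PlacementCluster, locus: int) -> int:
    lo, hi = cluster.merged_breakpoint
    if lo <= locus <= hi:
        return 0
    return min(abs(locus - lo), abs(locus - hi))


def placement_recovery(
    clusters: list[PlacementCluster],
    sim: SimResult,
    sample: str,
    min_len: int = 1000,
    min_spanning_reads: int = 3,
    max_dist: int = 100,
) -> RecoveryReport:
    """Planted insertions > min_len spanned by enough reads that yield a
    surviving cluster within max_dist of the planted locus."""
    spanning: dict[str, int] = {}
    for prov in sim.truth.read_provenance.values():
        if prov.sample == sample and prov.spans_insertion:
            spanning[prov.spans_insertion] = spanning.get(prov.spans_insertion, 0) + 1
    eligible = [
        ins
        for ins in sim.truth.insertions
        if sample in ins.samples
        and len(ins.sequence) > min_len
        and spanning.get(ins.insertion_id, 0) >= min_spanning_reads
    ]
    recovered = 0
    missed = []
    for ins in eligible:
        if any(
            c.target_id == sim.reference.id
            and _span_distance(c, ins.ref_locus) <= max_dist
            for c in clusters
        ):
            recovered += 1
        else:
            missed.append(ins.insertion_id)
    return RecoveryReport(recovered, len(eligible), missed)


def bep_breakpoint_offsets(
    clusters: list[PlacementCluster], sim: SimResult
) -> list[int]:
    """Distance of every BEP cluster's breakpoint span to the nearest
    planted locus (0 when a locus falls inside the span)."""
    loci = [ins.ref_locus for ins in sim.truth.insertions]
    return [
        min(_span_distance(c, locus) for locus in loci)
        for c in clusters
        if c.kind == "BEP"
    ]


def sharing_label_accuracy(
    labelled_per_sample: dict[str, list[PlacementCluster]],
    sim: SimResult,
    max_dist: int = 100,
) -> RecoveryReport:
    """Agreement of sharing labels with planted insertion categories.

    For each planted insertion recovered in at least one sample, the
    nearest matching cluster's label is compared with the expectation:
    shared -> population-shared, population_specific ->
    population-specific, individual -> individual.  Only loci the caller
    recovered count.
    """
    expected = {
        "shared": "population-shared",
        "population_specific": "population-specific",
        "individual": "individual",
    }
    n_ok = 0
    n_total = 0
    missed = []
    for ins in sim.truth.insertions:
        matches = []
        for sample, clusters in labelled_per_sample.items():
            if sample not in ins.samples:
                continue
            for c in clusters:
                if (
                    c.target_id == sim.reference.id
                    and _span_distance(c, ins.ref_locus) <= max_dist
                ):
                    matches.append(c)
        if not matches:
            continue
        n_total += 1
        if any(c.label == expected[ins.category] for c in matches):
            n_ok += 1
        else:
            missed.append(ins.insertion_id)
    return RecoveryReport(n_ok, n_total, missed)
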