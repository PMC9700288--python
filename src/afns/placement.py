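"""Placement of novel sequences on the reference by split-read evidence.

Reads are aligned to the reference and alignments below 80% identity are
discarded.  A read with exactly one or exactly two *consistent* remaining
alignments (same target and strand, collinear, non-overlapping) can
anchor an unmapped fragment longer than 1,000 bp:

* BEP (both-end placement) — the fragment sits between two anchors; the
  insertion breakpoint is the reference span between them (zero-width
  when they abut).
* SEP (single-end placement) — the fragment hangs off one end of a
  single anchor; the breakpoint is the zero-width reference position the
  anchor faces.

Calls of the same kind are merged (BEP: breakpoints within 100 bp and
near-full-length mutual fragment overlap; SEP: breakpoints within
100 bp), clusters with fewer than three supporting reads are discarded,
and the longest member represents each surviving cluster.  Clusters from
different samples at the same locus classify loci as individual,
population-specific or population-shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .align import PRESETS, index_reference, align as _align
from .cluster import _UnionFind
from .extract import CandidateFragment
from .intervals import merge_intervals
from .io import AlignmentRecord, Interval, SeqRecord

__all__ = [
    "PlacementCall",
    "PlacementCluster",
    "consistent_anchor_set",
    "call_placements",
    "merge_bep",
    "merge_sep",
    "filter_clusters",
    "classify_sharing",
    "place_sample",
]


@dataclass
class PlacementCall:
    kind: str  # "SEP" | "BEP"
    sample_id: str
    read_id: str
    fragment: CandidateFragment
    target_id: str
    breakpoint: tuple[int, int]  # half-open span on target; may be zero-width
    left_anchor: Optional[AlignmentRecord] = None
    right_anchor: Optional[AlignmentRecord] = None

    def __post_init__(self) -> None:
        if self.kind not in ("SEP", "BEP"):
            raise ValueError(f"bad placement kind {self.kind}")
        n_anchors = (self.left_anchor is not None) + (self.right_anchor is not None)
        if self.kind == "BEP" and n_anchors != 2:
            raise ValueError("BEP requires both anchors")
        if self.kind == "SEP" and n_anchors != 1:
            raise ValueError("SEP requires exactly one anchor")


@dataclass
class PlacementCluster:
    cluster_id: str
    kind: str
    target_id: str
    merged_breakpoint: tuple[int, int]
    member_calls: list[PlacementCall]
    representative_call: PlacementCall = field(init=False)
    samples: set[str] = field(init=False)
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.member_calls:
            raise ValueError(f"{self.cluster_id} has no members")
        self.representative_call = min(
            self.member_calls, key=lambda c: (-len(c.fragment), c.read_id)
        )
        self.samples = {c.sample_id for c in self.member_calls}

    @property
    def support(self) -> int:
        return len(self.member_calls)


def consistent_anchor_set(
    alignments: list[AlignmentRecord], min_identity: float = 0.8
) -> Optional[list[AlignmentRecord]]:
    """Anchor alignments of one read, or None if the read is rejected.

    Keeps alignments with identity >= min_identity (inclusive); accepts
    exactly one alignment, or exactly two that are consistent: same
    target, same strand, non-overlapping on read and reference, with
    reference order matching read order on "+" and reversed on "-".
    """
    if not alignments:
        return None
    qids = {a.query_id for a in alignments}
    if len(qids) > 1:
        raise ValueError(f"alignments from multiple reads: {sorted(qids)}")
    good = [a for a in alignments if a.identity >= min_identity]
    if len(good) == 1:
        return good
    if len(good) != 2:
        return None
    a, b = sorted(good, key=lambda r: r.q_start)
    if a.target_id != b.target_id or a.strand != b.strand:
        return None
    if b.q_start < a.q_end:  # overlap on the read
        return None
    if a.strand == "+":
        ok = b.t_start >= a.t_end
    else:
        ok = a.t_start >= b.t_end
    return [a, b] if ok else None


def call_placements(
    read: SeqRecord,
    anchors: list[AlignmentRecord],
    sample_id: str,
    min_fragment_len: int = 1000,
) -> tuple[list[PlacementCall], int]:
    """SEP/BEP calls from a read's accepted anchors.

    Unmapped read intervals strictly longer than ``min_fragment_len``
    adjacent to the anchors become calls; a middle fragment next to a
    single anchor cannot be placed and is only counted.  Returns
    (calls, n_unplaceable).
    """
    rlen = len(read.sequence)
    calls: list[PlacementCall] = []
    unplaceable = 0

    def frag(iv: Interval) -> CandidateFragment:
        return CandidateFragment(
            fragment_id=f"{read.id}:{iv.start}-{iv.end}",
            source_read_id=read.id,
            read_interval=iv,
            sequence=read.sequence[iv.start : iv.end],
        )

    anchors = sorted(anchors, key=lambda a: a.q_start)
    merged = merge_intervals([a.query_interval for a in anchors])
    gaps = []
    cursor = 0
    for iv in merged:
        if iv.start > cursor:
            gaps.append(Interval(cursor, iv.start))
        cursor = iv.end
    if cursor < rlen:
        gaps.append(Interval(cursor, rlen))

    for gap in gaps:
        if len(gap) <= min_fragment_len:
            continue
        left = max(
            (a for a in anchors if a.q_end <= gap.start),
            key=lambda a: a.q_end,
            default=None,
        )
        right = min(
            (a for a in anchors if a.q_start >= gap.end),
            key=lambda a: a.q_start,
            default=None,
        )
        if left is not None and right is not None:
            # between the two anchors: breakpoint spans the inter-anchor gap
            if left.strand == "+":
                lo, hi = left.t_end, right.t_start
            else:
                lo, hi = right.t_end, left.t_start
            if hi < lo:  # reference micro-homology: collapse to the midpoint
                lo = hi = (lo + hi) // 2
            calls.append(
                PlacementCall(
                    kind="BEP",
                    sample_id=sample_id,
                    read_id=read.id,
                    fragment=frag(gap),
                    target_id=left.target_id,
                    breakpoint=(lo, hi),
                    left_anchor=left,
                    right_anchor=right,
                )
            )
        elif left is not None and gap.end == rlen:
            # read tail past the anchor: SEP at the anchor's facing boundary
            pos = left.t_end if left.strand == "+" else left.t_start
            calls.append(
                PlacementCall(
                    kind="SEP",
                    sample_id=sample_id,
                    read_id=read.id,
                    fragment=frag(gap),
                    target_id=left.target_id,
                    breakpoint=(pos, pos),
                    left_anchor=left,
                )
            )
        elif right is not None and gap.start == 0:
            pos = right.t_start if right.strand == "+" else right.t_end
            calls.append(
                PlacementCall(
                    kind="SEP",
                    sample_id=sample_id,
                    read_id=read.id,
                    fragment=frag(gap),
                    target_id=right.target_id,
                    breakpoint=(pos, pos),
                    right_anchor=right,
                )
            )
        else:
            unplaceable += 1
    return calls, unplaceable


def _breakpoint_dist(a: PlacementCall, b: PlacementCall) -> int:
    if a.target_id != b.target_id:
        return 1 << 60
    lo = max(a.breakpoint[0], b.breakpoint[0])
    hi = min(a.breakpoint[1], b.breakpoint[1])
    return max(0, lo - hi)


def _fragments_overlap_near_full(
    a: PlacementCall, b: PlacementCall, max_dist: int, k: int = 15
) -> bool:
    """Do the two fragments mutually overlap to within max_dist of the
    shorter one's length?"""
    fa, fb = a.fragment.as_record(), b.fragment.as_record()
    if fa.sequence == fb.sequence:
        return True
    short, long_ = (fa, fb) if len(fa) <= len(fb) else (fb, fa)
    if len(short) < k:
        return False
    idx = index_reference(long_, k=k)
    recs = _align(short, idx, PRESETS["ava"])
    if not recs:
        return False
    overlap = sum(
        len(iv)
        for iv in merge_intervals([r.query_interval for r in recs])
    )
    return abs(overlap - len(short)) < max_dist


def _components_to_clusters(
    calls: list[PlacementCall], edges: list[tuple[int, int]], kind: str
) -> list[PlacementCluster]:
    uf = _UnionFind(range(len(calls)))
    for i, j in edges:
        uf.union(i, j)
    groups: dict[int, list[PlacementCall]] = {}
    for i, call in enumerate(calls):
        groups.setdefault(uf.find(i), []).append(call)

    def span(members: list[PlacementCall]) -> tuple[int, int]:
        return (
            min(c.breakpoint[0] for c in members),
            max(c.breakpoint[1] for c in members),
        )

    ordered = sorted(
        groups.values(),
        key=lambda ms: (ms[0].target_id, span(ms)[0], span(ms)[1]),
    )
    return [
        PlacementCluster(
            cluster_id=f"{kind.lower()}{n + 1}",
            kind=kind,
            target_id=ms[0].target_id,
            merged_breakpoint=span(ms),
            member_calls=sorted(ms, key=lambda c: (c.read_id, c.fragment.fragment_id)),
        )
        for n, ms in enumerate(ordered)
    ]


def merge_bep(calls: list[PlacementCall], max_dist: int = 100) -> list[PlacementCluster]:
    """Merge BEP calls: breakpoints within max_dist AND near-full-length
    mutual fragment overlap (|overlap - shorter length| < max_dist)."""
    for c in calls:
        if c.kind != "BEP":
            raise ValueError(f"merge_bep given a {c.kind} call ({c.read_id})")
    edges = []
    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            if _breakpoint_dist(calls[i], calls[j]) > max_dist:
                continue
            if _fragments_overlap_near_full(calls[i], calls[j], max_dist):
                edges.append((i, j))
    return _components_to_clusters(calls, edges, "BEP")


def merge_sep(calls: list[PlacementCall], max_dist: int = 100) -> list[PlacementCluster]:
    """Single-linkage merge of SEP breakpoints within max_dist (inclusive)."""
    for c in calls:
        if c.kind != "SEP":
            raise ValueError(f"merge_sep given a {c.kind} call ({c.read_id})")
    edges = []
    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            if _breakpoint_dist(calls[i], calls[j]) <= max_dist:
                edges.append((i, j))
    return _components_to_clusters(calls, edges, "SEP")


def filter_clusters(
    clusters: list[PlacementCluster], min_support: int = 3
) -> list[PlacementCluster]:
    """Keep clusters supported by at least min_support calls."""
    return [c for c in clusters if c.support >= min_support]


def _representatives_match(
    a: PlacementCluster, b: PlacementCluster, min_identity: float, k: int = 15
) -> bool:
    fa = a.representative_call.fragment.as_record()
    fb = b.representative_call.fragment.as_record()
    if fa.sequence == fb.sequence:
        return True
    idx = index_reference(SeqRecord("b", fb.sequence), k=k)
    recs = _align(SeqRecord("a", fa.sequence), idx, PRESETS["ava"])
    return any(r.identity >= min_identity for r in recs)


def classify_sharing(
    clusters_per_sample: dict[str, list[PlacementCluster]],
    population_map: dict[str, str],
    max_dist: int = 100,
    min_identity: float = 0.8,
) -> list[PlacementCluster]:
    """Label loci as individual / population-specific / population-shared.

    Clusters from different samples are matched when their breakpoints lie
    within max_dist and their representative fragments align at
    >= min_identity.  A locus seen in one sample is individual; in >= 2
    samples of one population, population-specific; across populations,
    population-shared.
    """
    if len(clusters_per_sample) < 2:
        raise ValueError("sharing classification needs at least two samples")
    for sample in clusters_per_sample:
        if sample not in population_map:
            raise ValueError(f"sample {sample} missing from population map")
    flat: list[tuple[str, PlacementCluster]] = [
        (sample, cl)
        for sample, cls in sorted(clusters_per_sample.items())
        for cl in cls
    ]
    uf = _UnionFind(range(len(flat)))
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            (sa, ca), (sb, cb) = flat[i], flat[j]
            if sa == sb or ca.kind != cb.kind or ca.target_id != cb.target_id:
                continue
            lo = max(ca.merged_breakpoint[0], cb.merged_breakpoint[0])
            hi = min(ca.merged_breakpoint[1], cb.merged_breakpoint[1])
            if max(0, lo - hi) > max_dist:
                continue
            if _representatives_match(ca, cb, min_identity):
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(flat)):
        groups.setdefault(uf.find(i), []).append(i)
    for members in groups.values():
        samples = {flat[i][0] for i in members}
        pops = {population_map[s] for s in samples}
        if len(samples) == 1:
            label = "individual"
        elif len(pops) == 1:
            label = "population-specific"
        else:
            label = "population-shared"
        for i in members:
            flat[i][1].label = label
    return [cl for _, cl in flat]


def place_sample(
    reads: list[SeqRecord],
    alignments_by_read: dict[str, list[AlignmentRecord]],
    sample_id: str,
    min_identity: float = 0.8,
    min_fragment_len: int = 1000,
    max_dist: int = 100,
    min_support: int = 3,
) -> list[PlacementCluster]:
    """Full placement flow for one sample from precomputed alignments."""
    bep: list[PlacementCall] = []
    sep: list[PlacementCall] = []
    for read in reads:
        anchors = consistent_anchor_set(
            alignments_by_read.get(read.id, []), min_identity=min_identity
        )
        if anchors is None:
            continue
        calls, _ = call_placements(read, anchors, sample_id, min_fragment_len)
        for c in calls:
            (bep if c.kind == "BEP" else sep).append(c)
    clusters = merge_bep(bep, max_dist) + merge_sep(sep, max_dist)
    return filter_clusters(clusters, min_support)
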