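"""Redundancy clustering of candidate fragments by alignment coverage.

Two fragments are linked when their mutual alignment covers more than 80%
of the shorter one (merged over alignment blocks); clusters are the
connected components of that graph and each cluster is represented by its
longest member.  Coverage of the shorter sequence — rather than
reciprocal coverage — is the default because a longest-member
representative implies clusters of unequal lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import merge_intervals, total_length
from .io import AlignmentRecord, Interval, SeqRecord

__all__ = ["Cluster", "pair_coverage", "build_clusters", "representatives"]


@dataclass
class Cluster:
    cluster_id: str
    member_ids: frozenset[str]
    representative_id: str

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError(f"{self.cluster_id}: representative not a member")


def pair_coverage(
    alignments: list[AlignmentRecord],
    id_a: str,
    len_a: int,
    id_b: str,
    len_b: int,
    reciprocal: bool = False,
) -> float:
    """Merged aligned fraction of the shorter of two sequences.

    Alignment blocks between a and b (either orientation) are projected
    onto each sequence and merged before measuring.  With
    ``reciprocal=True`` the minimum of the two fractions is returned
    instead.
    """
    iv_a: list[Interval] = []
    iv_b: list[Interval] = []
    for rec in alignments:
        if rec.query_id == id_a and rec.target_id == id_b:
            iv_a.append(rec.query_interval)
            iv_b.append(rec.target_interval)
        elif rec.query_id == id_b and rec.target_id == id_a:
            iv_b.append(rec.query_interval)
            iv_a.append(rec.target_interval)
        else:
            raise ValueError(
                f"alignment {rec.query_id} vs {rec.target_id} is not between "
                f"{id_a} and {id_b}"
            )
    if not iv_a:
        return 0.0
    frac_a = total_length(merge_intervals(iv_a)) / len_a
    frac_b = total_length(merge_intervals(iv_b)) / len_b
    if reciprocal:
        return min(frac_a, frac_b)
    return frac_a if len_a <= len_b else frac_b


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_clusters(
    fragments: list[SeqRecord],
    pairwise_alignments: list[AlignmentRecord],
    cov_threshold: float = 0.8,
    reciprocal: bool = False,
) -> list[Cluster]:
    """Single-linkage clusters under the strict >threshold coverage rule.

    Deterministic: clusters are ordered by representative length
    descending then id; singletons are their own cluster.
    """
    lengths = {f.id: len(f.sequence) for f in fragments}
    pair_alns: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for rec in pairwise_alignments:
        if rec.query_id not in lengths or rec.target_id not in lengths:
            unknown = rec.query_id if rec.query_id not in lengths else rec.target_id
            raise ValueError(f"alignment names unknown fragment {unknown}")
        if rec.query_id == rec.target_id:
            continue
        key = tuple(sorted((rec.query_id, rec.target_id)))
        pair_alns.setdefault(key, []).append(rec)

    uf = _UnionFind(lengths)
    for (a, b), alns in pair_alns.items():
        cov = pair_coverage(alns, a, lengths[a], b, lengths[b], reciprocal=reciprocal)
        if cov > cov_threshold:
            uf.union(a, b)

    groups: dict[str, set[str]] = {}
    for fid in lengths:
        groups.setdefault(uf.find(fid), set()).add(fid)

    def rep(members: set[str]) -> str:
        # longest member; ties broken by lexicographically smallest id
        return min(members, key=lambda m: (-lengths[m], m))

    clusters = sorted(
        groups.values(), key=lambda ms: (-lengths[rep(ms)], rep(ms))
    )
    return [
        Cluster(f"cluster{n + 1}", frozenset(ms), rep(ms))
        for n, ms in enumerate(clusters)
    ]


def representatives(
    clusters: list[Cluster], fragments: list[SeqRecord]
) -> list[SeqRecord]:
    """The longest member of each cluster, in cluster order."""
    by_id = {f.id: f for f in fragments}
    out = []
    for cl in clusters:
        if not cl.member_ids:
            raise ValueError(f"{cl.cluster_id} is empty")
        out.append(by_id[cl.representative_id])
    return out
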