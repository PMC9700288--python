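"""Coverage-based redundancy clustering against brute-force closure."""

import numpy as np
import pytest

from afns.cluster import build_clusters, pair_coverage, representatives
from afns.io import AlignmentRecord, SeqRecord


def _aln(qid, qlen, q0, q1, tid, tlen, t0, t1):
    bl = max(q1 - q0, t1 - t0)
    return AlignmentRecord(qid, qlen, q0, q1, "+", tid, tlen, t0, t1, bl, bl)


class TestPairCoverage:
    def test_full_coverage_of_shorter(self):
        alns = [_aln("a", 1000, 0, 400, "b", 400, 0, 400)]
        assert pair_coverage(alns, "a", 1000, "b", 400) == 1.0

    def test_blocks_merged_before_measuring(self):
        alns = [
            _aln("a", 1000, 0, 300, "b", 1000, 0, 300),
            _aln("a", 1000, 250, 600, "b", 1000, 250, 600),
        ]
        assert pair_coverage(alns, "a", 1000, "b", 1000) == pytest.approx(0.6)

    def test_no_alignments(self):
        assert pair_coverage([], "a", 1000, "b", 400) == 0.0

    def test_wrong_pair_rejected(self):
        alns = [_aln("a", 1000, 0, 400, "c", 400, 0, 400)]
        with pytest.raises(ValueError):
            pair_coverage(alns, "a", 1000, "b", 400)


def brute_force_components(n_nodes, edges):
    """Transitive closure by repeated relaxation."""
    comp = list(range(n_nodes))
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            lo = min(comp[a], comp[b])
            if comp[a] != lo or comp[b] != lo:
                comp[a] = comp[b] = lo
                changed = True
    groups = {}
    for i, c in enumerate(comp):
        groups.setdefault(c, set()).add(i)
    return sorted(map(frozenset, groups.values()), key=min)


class TestBuildClusters:
    def test_transitive_chain(self):
        frags = [SeqRecord(x, "A" * 500) for x in "abc"]
        alns = [
            _aln("a", 500, 0, 450, "b", 500, 0, 450),
            _aln("b", 500, 0, 450, "c", 500, 0, 450),
        ]
        clusters = build_clusters(frags, alns)
        assert len(clusters) == 1 and clusters[0].member_ids == {"a", "b", "c"}

    def test_no_alignments_gives_singletons(self):
        frags = [SeqRecord(f"f{i}", "A" * (100 + i)) for i in range(4)]
        clusters = build_clusters(frags, [])
        assert len(clusters) == 4
        assert all(len(c.member_ids) == 1 for c in clusters)

    def test_coverage_exactly_threshold_is_no_edge(self):
        frags = [SeqRecord("a", "A" * 1000), SeqRecord("b", "A" * 1000)]
        alns = [_aln("a", 1000, 0, 800, "b", 1000, 0, 800)]  # coverage == 0.8
        clusters = build_clusters(frags, alns, cov_threshold=0.8)
        assert len(clusters) == 2

    def test_unknown_fragment_in_alignment(self):
        frags = [SeqRecord("a", "A" * 500)]
        alns = [_aln("a", 500, 0, 450, "zz", 500, 0, 450)]
        with pytest.raises(ValueError, match="zz"):
            build_clusters(frags, alns)

    def test_matches_brute_force_closure_on_random_instances(self, rng):
        for _ in range(500):
            n = int(rng.integers(2, 40))
            frags = [SeqRecord(f"f{i:03d}", "A" * int(rng.integers(301, 2000)))
                     for i in range(n)]
            lengths = {f.id: len(f.sequence) for f in frags}
            edges = []
            alns = []
            for _ in range(int(rng.integers(0, n))):
                i, j = rng.choice(n, 2, replace=False)
                a, b = frags[i].id, frags[j].id
                # either near-full coverage of the shorter (edge) or weak hit
                shorter = min(lengths[a], lengths[b])
                if rng.random() < 0.6:
                    span = int(shorter * 0.9)
                    edges.append((i, j))
                else:
                    span = int(shorter * 0.5)
                alns.append(_aln(a, lengths[a], 0, span, b, lengths[b], 0, span))
            expected = brute_force_components(n, edges)
            got = build_clusters(frags, alns)
            got_sets = sorted(
                (frozenset(int(m[1:]) for m in c.member_ids) for c in got), key=min
            )
            assert got_sets == expected

    def test_order_independence(self, rng):
        frags = [SeqRecord(f"f{i}", "A" * int(rng.integers(301, 900))) for i in range(12)]
        lengths = {f.id: len(f.sequence) for f in frags}
        alns = []
        for i in range(0, 12, 3):
            a, b = frags[i].id, frags[i + 1].id
            span = int(min(lengths[a], lengths[b]) * 0.95)
            alns.append(_aln(a, lengths[a], 0, span, b, lengths[b], 0, span))
        c1 = build_clusters(frags, alns)
        c2 = build_clusters(list(reversed(frags)), list(reversed(alns)))
        assert [(c.member_ids, c.representative_id) for c in c1] == \
               [(c.member_ids, c.representative_id) for c in c2]

    def test_membership_partitions_input(self, rng):
        frags = [SeqRecord(f"f{i}", "A" * int(rng.integers(301, 900))) for i in range(30)]
        clusters = build_clusters(frags, [])
        assert sum(len(c.member_ids) for c in clusters) == len(frags)


class TestRepresentatives:
    def test_longest_wins_tie_breaks_lexicographic(self):
        frags = [SeqRecord("x", "A" * 400), SeqRecord("b", "A" * 900),
                 SeqRecord("a", "A" * 900)]
        alns = [
            _aln("a", 900, 0, 890, "b", 900, 0, 890),
            _aln("a", 900, 0, 390, "x", 400, 0, 390),
        ]
        clusters = build_clusters(frags, alns)
        assert len(clusters) == 1 and clusters[0].representative_id == "a"
        reps = representatives(clusters, frags)
        assert reps[0].id == "a" and len(reps[0].sequence) == 900

    def test_singleton_is_itself(self):
        frags = [SeqRecord("solo", "A" * 500)]
        clusters = build_clusters(frags, [])
        assert representatives(clusters, frags)[0].id == "solo"

    def test_representative_is_maximal_on_random_clusters(self, rng):
        frags = [SeqRecord(f"f{i}", "A" * int(rng.integers(301, 3000)))
                 for i in range(50)]
        lengths = {f.id: len(f.sequence) for f in frags}
        alns = []
        for i in range(0, 50, 5):
            for j in range(i + 1, i + 5):
                a, b = frags[i].id, frags[j].id
                span = int(min(lengths[a], lengths[b]) * 0.95)
                alns.append(_aln(a, lengths[a], 0, span, b, lengths[b], 0, span))
        clusters = build_clusters(frags, alns)
        for c in clusters:
            assert lengths[c.representative_id] == max(lengths[m] for m in c.member_ids)
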