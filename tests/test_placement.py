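"""Split-read SEP/BEP calling, merging and cross-sample sharing."""

import numpy as np
import pytest

from afns.extract import CandidateFragment
from afns.io import AlignmentRecord, Interval, SeqRecord
from afns.placement import (
    PlacementCall,
    call_placements,
    classify_sharing,
    consistent_anchor_set,
    filter_clusters,
    merge_bep,
    merge_sep,
)


def _aln(q0, q1, t0, t1, ident=0.95, strand="+", qid="r1", tid="chr1",
         qlen=12000, tlen=50000):
    bl = max(q1 - q0, t1 - t0)
    return AlignmentRecord(qid, qlen, q0, q1, strand, tid, tlen, t0, t1,
                           max(1, int(bl * ident)), bl)


class TestConsistentAnchors:
    def test_identity_boundary_inclusive(self):
        assert consistent_anchor_set([_aln(0, 5000, 10000, 15000, ident=0.8)]) is not None
        assert consistent_anchor_set([_aln(0, 5000, 10000, 15000, ident=0.79)]) is None

    def test_two_collinear_anchors_accepted(self):
        a = _aln(0, 5000, 10000, 15000)
        b = _aln(7000, 12000, 15000, 20000)
        got = consistent_anchor_set([a, b])
        assert got == [a, b]

    def test_different_chromosomes_rejected(self):
        a = _aln(0, 5000, 10000, 15000)
        b = _aln(7000, 12000, 15000, 20000, tid="chr2")
        assert consistent_anchor_set([a, b]) is None

    def test_wrong_reference_order_rejected(self):
        a = _aln(0, 5000, 20000, 25000)
        b = _aln(7000, 12000, 10000, 15000)  # goes backwards on "+"
        assert consistent_anchor_set([a, b]) is None

    def test_minus_strand_order_reversed(self):
        a = _aln(0, 5000, 20000, 25000, strand="-")
        b = _aln(7000, 12000, 10000, 15000, strand="-")
        assert consistent_anchor_set([a, b]) is not None

    def test_three_alignments_rejected(self):
        alns = [_aln(0, 2000, 10000, 12000), _aln(3000, 5000, 13000, 15000),
                _aln(6000, 8000, 16000, 18000)]
        assert consistent_anchor_set(alns) is None


def _read(n=12000, rid="r1"):
    rng = np.random.default_rng(0)
    return SeqRecord(rid, "".join(rng.choice(list("ACGT"), n)))


class TestCallPlacements:
    def test_bep_between_abutting_anchors(self):
        read = _read(12000)
        anchors = [_aln(0, 5000, 10000, 15000), _aln(7000, 12000, 15000, 20000)]
        calls, _ = call_placements(read, anchors, "s1")
        assert len(calls) == 1
        c = calls[0]
        assert c.kind == "BEP" and len(c.fragment) == 2000
        assert c.breakpoint == (15000, 15000)

    def test_sep_leading_fragment(self):
        read = _read(6000)
        anchors = [_aln(1500, 6000, 20000, 24500, qlen=6000)]
        calls, _ = call_placements(read, anchors, "s1")
        assert len(calls) == 1
        c = calls[0]
        assert c.kind == "SEP" and len(c.fragment) == 1500
        assert c.breakpoint == (20000, 20000)

    def test_gap_exactly_1000_not_called(self):
        read = _read(11000)
        anchors = [_aln(0, 5000, 10000, 15000, qlen=11000),
                   _aln(6000, 11000, 15000, 20000, qlen=11000)]
        calls, _ = call_placements(read, anchors, "s1")
        assert calls == []

    def test_minus_strand_breakpoint(self):
        read = _read(12000)
        anchors = [_aln(0, 5000, 15000, 20000, strand="-"),
                   _aln(7000, 12000, 10000, 15000, strand="-")]
        calls, _ = call_placements(read, anchors, "s1")
        assert len(calls) == 1 and calls[0].breakpoint == (15000, 15000)


def _sep(pos, rid, frag_len=1500, tid="chr1", sample="s1"):
    frag = CandidateFragment(f"{rid}:0-{frag_len}", rid, Interval(0, frag_len),
                             "A" * frag_len)
    return PlacementCall("SEP", sample, rid, frag, tid, (pos, pos),
                         left_anchor=_aln(frag_len, frag_len + 2000, pos,
                                          pos + 2000, qid=rid))


def brute_force_single_linkage(positions, max_dist):
    n = len(positions)
    comp = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if abs(positions[i] - positions[j]) <= max_dist and comp[i] != comp[j]:
                    lo = min(comp[i], comp[j])
                    comp[i] = comp[j] = lo
                    changed = True
    groups = {}
    for i, c in enumerate(comp):
        groups.setdefault(c, set()).add(i)
    return sorted(map(frozenset, groups.values()), key=min)


class TestMergeSep:
    def test_chain_and_gap(self):
        calls = [_sep(1000, "a"), _sep(1080, "b"), _sep(1300, "c")]
        clusters = merge_sep(calls, max_dist=100)
        sizes = sorted(c.support for c in clusters)
        assert sizes == [1, 2]

    def test_distance_exactly_100_merges(self):
        clusters = merge_sep([_sep(1000, "a"), _sep(1100, "b")], max_dist=100)
        assert len(clusters) == 1 and clusters[0].support == 2

    def test_singleton(self):
        clusters = merge_sep([_sep(5000, "a")])
        assert len(clusters) == 1 and clusters[0].support == 1

    def test_non_sep_rejected(self):
        frag = CandidateFragment("f", "r", Interval(0, 1500), "A" * 1500)
        bep = PlacementCall("BEP", "s1", "r", frag, "chr1", (5, 5),
                            left_anchor=_aln(1500, 3000, 0, 1500),
                            right_anchor=_aln(4000, 6000, 1500, 3500))
        with pytest.raises(ValueError):
            merge_sep([bep])

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(500):
            n = int(rng.integers(1, 25))
            positions = sorted(int(p) for p in rng.integers(0, 3000, n))
            calls = [_sep(p, f"r{i:02d}") for i, p in enumerate(positions)]
            clusters = merge_sep(calls, max_dist=100)
            got = sorted(
                (frozenset(int(c.read_id[1:]) for c in cl.member_calls)
                 for cl in clusters),
                key=min,
            )
            assert got == brute_force_single_linkage(positions, 100)
            # breakpoint span covers members; support conserved
            assert sum(cl.support for cl in clusters) == n
            for cl in clusters:
                lo, hi = cl.merged_breakpoint
                for c in cl.member_calls:
                    assert lo <= c.breakpoint[0] <= c.breakpoint[1] <= hi


class TestMergeBep:
    def _bep(self, pos, rid, seq, sample="s1"):
        frag = CandidateFragment(f"{rid}:5000-{5000 + len(seq)}", rid,
                                 Interval(5000, 5000 + len(seq)), seq)
        return PlacementCall(
            "BEP", sample, rid, frag, "chr1", (pos, pos),
            left_anchor=_aln(0, 5000, pos - 5000, pos, qid=rid),
            right_anchor=_aln(5000 + len(seq), 10000 + len(seq), pos,
                              pos + 5000, qid=rid, qlen=20000),
        )

    def test_same_insertion_merges(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 2000))
        a, b = self._bep(10000, "a", seq), self._bep(10050, "b", seq)
        clusters = merge_bep([a, b])
        assert len(clusters) == 1 and clusters[0].support == 2

    def test_nearby_but_dissimilar_fragments_not_merged(self, rng):
        a = self._bep(10000, "a", "".join(rng.choice(list("ACGT"), 2000)))
        b = self._bep(10050, "b", "".join(rng.choice(list("ACGT"), 2000)))
        clusters = merge_bep([a, b])
        assert len(clusters) == 2

    def test_identical_call_twice(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1500))
        clusters = merge_bep([self._bep(9000, "a", seq), self._bep(9000, "b", seq)])
        assert len(clusters) == 1 and clusters[0].support == 2

    def test_distant_identical_fragments_not_merged(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1500))
        clusters = merge_bep([self._bep(9000, "a", seq), self._bep(20000, "b", seq)])
        assert len(clusters) == 2


class TestFilterClusters:
    def test_support_threshold(self, rng):
        groups = []
        for n, base in zip((1, 2, 3, 7), (1000, 5000, 9000, 13000)):
            groups += [_sep(base, f"g{base}_{i}") for i in range(n)]
        clusters = merge_sep(groups, max_dist=100)
        kept = filter_clusters(clusters, min_support=3)
        assert sorted(c.support for c in kept) == [3, 7]

    def test_empty_input(self):
        assert filter_clusters([]) == []

    def test_representative_is_longest(self, rng):
        calls = [_sep(1000, "a", frag_len=1200), _sep(1010, "b", frag_len=2500),
                 _sep(1020, "c", frag_len=1800)]
        kept = filter_clusters(merge_sep(calls), min_support=3)
        assert len(kept) == 1
        assert len(kept[0].representative_call.fragment) == 2500


class TestClassifySharing:
    def _clusters(self, rng, seq, pos, sample):
        call = _sep(pos, f"{sample}_r", sample=sample)
        call.fragment.sequence = seq
        call.fragment.read_interval = Interval(0, len(seq))
        return merge_sep([call])

    def test_two_samples_one_population_is_population_specific(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1500))
        per_sample = {
            "s1": self._clusters(rng, seq, 1000, "s1"),
            "s2": self._clusters(rng, seq, 1050, "s2"),
        }
        out = classify_sharing(per_sample, {"s1": "popA", "s2": "popA"})
        assert all(c.label == "population-specific" for c in out)

    def test_two_populations_is_population_shared(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 1500))
        per_sample = {
            "s1": self._clusters(rng, seq, 1000, "s1"),
            "s2": self._clusters(rng, seq, 1050, "s2"),
        }
        out = classify_sharing(per_sample, {"s1": "popA", "s2": "popB"})
        assert all(c.label == "population-shared" for c in out)

    def test_unmatched_cluster_is_individual(self, rng):
        per_sample = {
            "s1": self._clusters(rng, "".join(rng.choice(list("ACGT"), 1500)),
                                 1000, "s1"),
            "s2": self._clusters(rng, "".join(rng.choice(list("ACGT"), 1500)),
                                 9000, "s2"),
        }
        out = classify_sharing(per_sample, {"s1": "popA", "s2": "popB"})
        assert all(c.label == "individual" for c in out)

    def test_missing_population_raises(self, rng):
        per_sample = {
            "s1": self._clusters(rng, "ACGT" * 400, 1000, "s1"),
            "s2": self._clusters(rng, "ACGT" * 400, 2000, "s2"),
        }
        with pytest.raises(ValueError, match="s2"):
            classify_sharing(per_sample, {"s1": "popA"})
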