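"""Interval arithmetic and the align-and-subtract loop, against a
per-base boolean-array oracle."""

import numpy as np
import pytest

from afns.align import index_reference
from afns.extract import (
    CandidateFragment,
    aligned_query_intervals,
    run_rounds,
    subtract_mapped,
    unmapped_fragments,
)
from afns.intervals import complement_intervals, merge_intervals, total_length
from afns.io import AlignmentRecord, Interval, SeqRecord


def _aln(q0, q1, qlen=5000, qid="r1"):
    return AlignmentRecord(qid, qlen, q0, q1, "+", "t", 10000, 0, q1 - q0,
                           q1 - q0, q1 - q0)


def oracle_union(intervals, length):
    """Mark bases in a boolean array; read back maximal runs."""
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        mask[iv.start : iv.end] = True
    return _runs(mask)


def oracle_complement(intervals, length):
    mask = np.ones(length, dtype=bool)
    for iv in intervals:
        mask[iv.start : iv.end] = False
    return _runs(mask)


def _runs(mask):
    out = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            out.append(Interval(start, i))
            start = None
    if start is not None:
        out.append(Interval(start, len(mask)))
    return out


class TestAlignedQueryIntervals:
    def test_overlap_merge(self):
        got = aligned_query_intervals([_aln(0, 400), _aln(350, 600)])
        assert [(iv.start, iv.end) for iv in got] == [(0, 600)]

    def test_empty(self):
        assert aligned_query_intervals([]) == []

    def test_mixed_overlap(self):
        got = aligned_query_intervals([_aln(0, 100), _aln(200, 300), _aln(250, 400)])
        assert [(iv.start, iv.end) for iv in got] == [(0, 100), (200, 400)]

    def test_mixed_query_ids_rejected(self):
        with pytest.raises(ValueError):
            aligned_query_intervals([_aln(0, 100), _aln(0, 100, qid="r2")])

    def test_matches_per_base_oracle_on_random_cases(self, rng):
        for _ in range(1000):
            length = int(rng.integers(10, 5000))
            n = int(rng.integers(0, 11))
            ivs = []
            for _ in range(n):
                a = int(rng.integers(0, length - 1))
                b = int(rng.integers(a + 1, length + 1))
                ivs.append(Interval(a, b))
            assert merge_intervals(ivs) == oracle_union(ivs, length)
            merged = merge_intervals(ivs)
            assert complement_intervals(merged, length) == oracle_complement(ivs, length)


class TestUnmappedFragments:
    def _read(self, n=1000):
        return SeqRecord("r1", "A" * n)

    def test_short_gap_excluded(self):
        got = unmapped_fragments(self._read(), [Interval(0, 400), Interval(600, 1000)])
        assert got == []  # 200 bp gap is not longer than 300

    def test_fully_unmapped_read(self):
        got = unmapped_fragments(self._read(), [])
        assert len(got) == 1 and (got[0].read_interval.start, got[0].read_interval.end) == (0, 1000)

    def test_tail_fragment_kept(self):
        got = unmapped_fragments(self._read(), [Interval(0, 300)])
        assert len(got) == 1 and len(got[0]) == 700

    def test_boundary_exactly_min_len_dropped(self):
        # 300-long gap is not "longer than 300"
        got = unmapped_fragments(self._read(), [Interval(0, 700)])
        assert got == []

    def test_interval_beyond_read_rejected(self):
        with pytest.raises(ValueError):
            unmapped_fragments(self._read(100), [Interval(0, 200)])

    def test_fragment_sequence_matches_interval(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 3000))
        read = SeqRecord("r1", seq)
        frags = unmapped_fragments(read, [Interval(500, 900), Interval(1400, 2000)])
        for f in frags:
            assert f.sequence == seq[f.read_interval.start : f.read_interval.end]


class TestSubtractMapped:
    def _frag(self, n=900, offset=100):
        return CandidateFragment("f1", "r1", Interval(offset, offset + n), "G" * n)

    def test_split_with_threshold(self):
        # children [0,300) (== 300, dropped) and [500,900) (400, kept)
        frag = self._frag(900)
        out = subtract_mapped(frag, [_aln(300, 500, qlen=900, qid="f1")])
        assert len(out) == 1
        child = out[0]
        assert len(child) == 400
        # coordinates re-mapped onto the original read
        assert (child.read_interval.start, child.read_interval.end) == (600, 1000)
        assert child.round_created == frag.round_created + 1

    def test_no_alignment_identity_case(self):
        frag = self._frag(900)
        out = subtract_mapped(frag, [])
        assert len(out) == 1 and out[0].sequence == frag.sequence

    def test_fully_aligned_removed(self):
        frag = self._frag(400)
        out = subtract_mapped(frag, [_aln(0, 400, qlen=400, qid="f1")])
        assert out == []

    def test_monotone_and_matches_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(301, 5000))
            frag = CandidateFragment("f", "r", Interval(0, n),
                                     "".join(rng.choice(list("ACGT"), n)))
            alns = []
            for _ in range(int(rng.integers(0, 6))):
                a = int(rng.integers(0, n - 1))
                b = int(rng.integers(a + 1, n + 1))
                alns.append(_aln(a, b, qlen=n, qid="f"))
            out = subtract_mapped(frag, alns)
            expected = [
                iv for iv in oracle_complement(
                    [a.query_interval for a in alns], n)
                if len(iv) > 300
            ]
            assert [(c.read_interval.start, c.read_interval.end) for c in out] == \
                   [(iv.start, iv.end) for iv in expected]
            assert sum(len(c) for c in out) <= n


class TestRunRounds:
    def test_reference_fragment_eliminated_and_novel_survives(self, rng):
        ref_seq = "".join(rng.choice(list("ACGT"), 20000))
        idx = index_reference(SeqRecord("ref", ref_seq), k=15)
        ref_frag = CandidateFragment("a", "ra", Interval(0, 800), ref_seq[4000:4800])
        novel_seq = "".join(rng.choice(list("ACGT"), 800))
        novel_frag = CandidateFragment("b", "rb", Interval(0, 800), novel_seq)
        out = run_rounds([ref_frag, novel_frag], idx)
        assert [f.source_read_id for f in out] == ["rb"]
        assert out[0].sequence == novel_seq

    def test_chimera_split(self, rng):
        ref_seq = "".join(rng.choice(list("ACGT"), 20000))
        idx = index_reference(SeqRecord("ref", ref_seq), k=15)
        novel = "".join(rng.choice(list("ACGT"), 1000))
        chimera = CandidateFragment(
            "c", "rc", Interval(0, 2000), novel + ref_seq[8000:9000])
        out = run_rounds([chimera], idx)
        assert len(out) == 1
        # surviving child is the novel part, up to aligner end tolerance
        assert abs(len(out[0]) - 1000) < 50
        assert out[0].sequence in chimera.sequence

    def test_total_surviving_length_non_increasing(self, rng):
        ref_seq = "".join(rng.choice(list("ACGT"), 20000))
        idx = index_reference(SeqRecord("ref", ref_seq), k=15)
        frags = []
        for i in range(5):
            novel = "".join(rng.choice(list("ACGT"), 600))
            start = 2000 * i
            frags.append(CandidateFragment(
                f"f{i}", f"r{i}", Interval(0, 600 + 800),
                novel + ref_seq[start : start + 800]))
        before = sum(len(f) for f in frags)
        from afns.extract import RoundConfig
        current = frags
        for rc in RoundConfig.default_rounds():
            nxt = run_rounds(current, idx, rounds=[rc])
            assert sum(len(f) for f in nxt) <= sum(len(f) for f in current)
            current = nxt
        assert sum(len(f) for f in current) <= before
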