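"""Unmapped-fragment extraction and the multi-round align-and-subtract loop.

A read's aligned query intervals are merged and complemented; complement
pieces strictly longer than ``min_fragment_len`` (300 bp by default) become
candidate fragments.  Candidates are then re-aligned to the reference for
a configurable number of rounds (three by default, with a more sensitive
preset in round two); every aligned portion is subtracted and only
survivors longer than the cutoff persist, with coordinates always mapped
back onto the original read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import KmerIndex, PRESETS, AlignPreset, align
from .intervals import complement_intervals, merge_intervals
from .io import AlignmentRecord, Interval, SeqRecord

__all__ = [
    "CandidateFragment",
    "RoundConfig",
    "DEFAULT_ROUNDS",
    "aligned_query_intervals",
    "unmapped_fragments",
    "subtract_mapped",
    "run_rounds",
    "extract_candidates",
]


@dataclass
class CandidateFragment:
    """An unmapped sub-interval of a read, carried through the filters."""

    fragment_id: str
    source_read_id: str
    read_interval: Interval
    sequence: str
    round_created: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.read_interval):
            raise ValueError(
                f"{self.fragment_id}: sequence length {len(self.sequence)} != "
                f"interval length {len(self.read_interval)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def as_record(self) -> SeqRecord:
        return SeqRecord(self.fragment_id, self.sequence)


@dataclass
class RoundConfig:
    round_index: int
    preset: AlignPreset

    @classmethod
    def default_rounds(cls) -> list["RoundConfig"]:
        # rounds 1 and 3 use the long-read preset, round 2 the sensitive one
        return [
            cls(1, PRESETS["map-long"]),
            cls(2, PRESETS["sensitive"]),
            cls(3, PRESETS["map-long"]),
        ]


DEFAULT_ROUNDS = RoundConfig.default_rounds


def aligned_query_intervals(alignments: list[AlignmentRecord]) -> list[Interval]:
    """Merged union of [q_start, q_end) over one read's alignments.

    Query coordinates in PAF are always on the forward strand, so the
    union is strand-independent.
    """
    if not alignments:
        return []
    qids = {a.query_id for a in alignments}
    if len(qids) > 1:
        raise ValueError(f"alignments from multiple queries: {sorted(qids)}")
    return merge_intervals([a.query_interval for a in alignments])


def unmapped_fragments(
    read: SeqRecord, merged_aligned: list[Interval], min_len: int = 300
) -> list[CandidateFragment]:
    """Complement intervals strictly longer than min_len, as fragments.

    An entirely unmapped read yields one full-length fragment.
    """
    gaps = complement_intervals(merged_aligned, len(read.sequence))
    out = []
    for n, gap in enumerate(gaps):
        if len(gap) <= min_len:
            continue
        out.append(
            CandidateFragment(
                fragment_id=f"{read.id}:{gap.start}-{gap.end}",
                source_read_id=read.id,
                read_interval=gap,
                sequence=read.sequence[gap.start : gap.end],
                round_created=0,
            )
        )
    return out


def subtract_mapped(
    fragment: CandidateFragment,
    alignments: list[AlignmentRecord],
    min_len: int = 300,
) -> list[CandidateFragment]:
    """Remove every aligned query interval from a fragment.

    Surviving complement pieces strictly longer than min_len become child
    fragments with coordinates re-mapped onto the original read and the
    creation round incremented.  Aligned portions are removed regardless
    of their own length.
    """
    merged = merge_intervals([a.query_interval for a in alignments])
    for iv in merged:
        if iv.end > len(fragment.sequence):
            raise ValueError(
                f"{fragment.fragment_id}: alignment interval [{iv.start},{iv.end}) "
                f"exceeds fragment length {len(fragment.sequence)}"
            )
    if not merged:
        return [
            CandidateFragment(
                fragment.fragment_id,
                fragment.source_read_id,
                fragment.read_interval,
                fragment.sequence,
                fragment.round_created + 1,
            )
        ]
    out = []
    base = fragment.read_interval.start
    for gap in complement_intervals(merged, len(fragment.sequence)):
        if len(gap) <= min_len:
            continue
        read_iv = Interval(base + gap.start, base + gap.end)
        out.append(
            CandidateFragment(
                fragment_id=f"{fragment.source_read_id}:{read_iv.start}-{read_iv.end}",
                source_read_id=fragment.source_read_id,
                read_interval=read_iv,
                sequence=fragment.sequence[gap.start : gap.end],
                round_created=fragment.round_created + 1,
            )
        )
    return out


def run_rounds(
    fragments: list[CandidateFragment],
    reference_index: KmerIndex,
    rounds: list[RoundConfig] | None = None,
    min_len: int = 300,
    external_paf: dict[int, list[AlignmentRecord]] | None = None,
) -> list[CandidateFragment]:
    """Apply align -> subtract sequentially for each round.

    ``external_paf`` optionally maps a round index to pre-computed
    alignments (query ids must be fragment ids), bypassing the built-in
    aligner for that round.
    """
    if rounds is None:
        rounds = RoundConfig.default_rounds()
    current = fragments
    for rc in rounds:
        ext = None
        if external_paf and rc.round_index in external_paf:
            ext = {}
            for a in external_paf[rc.round_index]:
                ext.setdefault(a.query_id, []).append(a)
        nxt: list[CandidateFragment] = []
        for frag in current:
            if ext is not None:
                alns = ext.get(frag.fragment_id, [])
            else:
                alns = align(frag.as_record(), reference_index, rc.preset)
            nxt.extend(subtract_mapped(frag, alns, min_len=min_len))
        current = nxt
    return current


def extract_candidates(
    reads: list[SeqRecord],
    reference_index: KmerIndex,
    min_len: int = 300,
    preset: AlignPreset | str = "map-long",
) -> tuple[list[CandidateFragment], dict[str, list[AlignmentRecord]]]:
    """First-pass selection: align reads, return their unmapped fragments.

    Also returns the per-read alignments so downstream steps (placement)
    can reuse them.
    """
    candidates = []
    alignments: dict[str, list[AlignmentRecord]] = {}
    for read in reads:
        alns = align(read, reference_index, preset)
        alignments[read.id] = alns
        merged = aligned_query_intervals(alns)
        candidates.extend(unmapped_fragments(read, merged, min_len=min_len))
    return candidates, alignments
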