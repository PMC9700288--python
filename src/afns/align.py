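"""Self-contained seed-and-extend pairwise aligner emitting PAF records.

Exact canonical k-mer seeds are chained per (target, strand) by a
patience-style longest-increasing-subsequence pass inside diagonal bands;
gaps between consecutive seeds are closed with a small edit-distance
alignment, ends are extended ungapped, and match counts come from the
actual alignment columns.  Deterministic by construction: no minimizer
sampling, ties broken by leftmost query start.

Presets:

====================  ====  ===============  ============  ==========
name                   k    min_chain_span   max_seed_gap  band_width
====================  ====  ===============  ============  ==========
map-long              15    100              500           500
sensitive             15    31               200           200
ava                   15    100              500           500
====================  ====  ===============  ============  ==========

The sensitive preset mirrors classic exact-match genome aligners run with
a minimum match length of 15 and minimum cluster span of 31.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import edlib

from .io import AlignmentRecord, SeqRecord, revcomp

__all__ = ["AlignPreset", "PRESETS", "KmerIndex", "index_reference", "align", "all_vs_all"]


@dataclass(frozen=True)
class AlignPreset:
    name: str
    k: int = 15
    min_chain_span: int = 100
    max_seed_gap: int = 500
    band_width: int = 500
    min_seeds: int = 3


PRESETS = {
    "map-long": AlignPreset("map-long"),
    "sensitive": AlignPreset("sensitive", min_chain_span=31, max_seed_gap=200,
                             band_width=200, min_seeds=2),
    "ava": AlignPreset("ava"),
}


class KmerIndex:
    """Canonical k-mer index over a set of target sequences."""

    def __init__(self, k: int):
        if k % 2 == 0 or not (11 <= k <= 21):
            raise ValueError(f"k must be odd and in [11, 21], got {k}")
        self.k = k
        self.positions: dict[str, list[tuple[str, int, str]]] = {}
        self.targets: dict[str, str] = {}

    def add(self, record: SeqRecord) -> None:
        if record.id in self.targets:
            raise ValueError(f"duplicate target id {record.id}")
        self.targets[record.id] = record.sequence
        k, seq = self.k, record.sequence
        pos = self.positions
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            rc = revcomp(kmer)
            canon, strand = (kmer, "+") if kmer <= rc else (rc, "-")
            pos.setdefault(canon, []).append((record.id, i, strand))

    def __len__(self) -> int:
        return len(self.positions)


def index_reference(records: list[SeqRecord] | SeqRecord, k: int = 15) -> KmerIndex:
    """Index one or more target sequences by canonical k-mer."""
    if isinstance(records, SeqRecord):
        records = [records]
    idx = KmerIndex(k)
    for rec in records:
        idx.add(rec)
    return idx


def _chain_seeds(seeds: list[tuple[int, int]], preset: AlignPreset) -> list[list[tuple[int, int]]]:
    """Split seeds into diagonal bands and chain each by LIS on target pos.

    ``seeds`` are (qpos, tpos) in a common orientation frame.  Returns
    chains as lists of collinear seeds, split at gaps > max_seed_gap.
    """
    if not seeds:
        return []
    by_diag = sorted(seeds, key=lambda s: (s[1] - s[0], s[0]))
    bands: list[list[tuple[int, int]]] = []
    cur = [by_diag[0]]
    for s in by_diag[1:]:
        if (s[1] - s[0]) - (cur[-1][1] - cur[-1][0]) > preset.band_width:
            bands.append(cur)
            cur = [s]
        else:
            cur.append(s)
    bands.append(cur)

    chains = []
    for band in bands:
        band.sort(key=lambda s: (s[0], s[1]))
        # patience LIS on tpos (strictly increasing), leftmost-query tie-break
        tails: list[int] = []  # tails[i] = smallest tpos ending an LIS of len i+1
        tails_idx: list[int] = []
        parent = [-1] * len(band)
        for i, (q, t) in enumerate(band):
            j = bisect.bisect_left(tails, t)
            if j == len(tails):
                tails.append(t)
                tails_idx.append(i)
            elif t < tails[j]:
                tails[j] = t
                tails_idx[j] = i
            else:
                continue
            parent[i] = tails_idx[j - 1] if j > 0 else -1
        if not tails_idx:
            continue
        chain = []
        i = tails_idx[-1]
        while i != -1:
            chain.append(band[i])
            i = parent[i]
        chain.reverse()
        # drop seeds that went backwards in query (LIS was on t only)
        filtered = []
        for q, t in chain:
            if not filtered or (q > filtered[-1][0] and t > filtered[-1][1]):
                filtered.append((q, t))
        # split at large gaps
        piece = [filtered[0]]
        for q, t in filtered[1:]:
            if q - piece[-1][0] > preset.max_seed_gap or t - piece[-1][1] > preset.max_seed_gap:
                chains.append(piece)
                piece = [(q, t)]
            else:
                piece.append((q, t))
        chains.append(piece)
    return chains


def _gap_align(qseq: str, tseq: str) -> tuple[int, int]:
    """(matches, columns) of a global alignment of two gap substrings."""
    if not qseq and not tseq:
        return 0, 0
    if not qseq or not tseq:
        return 0, max(len(qseq), len(tseq))
    if qseq == tseq:
        return len(qseq), len(qseq)
    if len(qseq) == len(tseq) and len(qseq) <= 3:
        return sum(a == b for a, b in zip(qseq, tseq)), len(qseq)
    res = edlib.align(qseq, tseq, mode="NW", task="path")
    matches = 0
    cols = 0
    num = ""
    for c in res["cigar"]:
        if c.isdigit():
            num += c
        else:
            n = int(num)
            num = ""
            cols += n
            if c == "=":
                matches += n
    return matches, cols


def _chain_to_record(
    chain: list[tuple[int, int]],
    qseq: str,
    query_id: str,
    query_len: int,
    target_id: str,
    tseq: str,
    strand: str,
    k: int,
) -> AlignmentRecord | None:
    """Stitch a seed chain into an alignment record.

    ``qseq`` is the query in the chain's orientation frame (reverse
    complemented for '-' chains); coordinates are mapped back at the end.
    """
    matches = 0
    cols = 0
    cq, ct = chain[0]
    q0, t0 = cq, ct
    cq += k
    ct += k
    matches += k
    cols += k
    for q, t in chain[1:]:
        if q + k <= cq or t + k <= ct:
            continue
        # trim the new anchor's start so it begins past the aligned prefix
        qa = max(q, cq)
        ta = t + (qa - q)
        if ta < ct:
            continue
        gm, gc = _gap_align(qseq[cq:qa], tseq[ct:ta])
        matches += gm
        cols += gc
        anchor_len = q + k - qa
        matches += anchor_len
        cols += anchor_len
        cq, ct = q + k, t + k
    # ungapped end extension
    while q0 > 0 and t0 > 0 and qseq[q0 - 1] == tseq[t0 - 1]:
        q0 -= 1
        t0 -= 1
        matches += 1
        cols += 1
    while cq < len(qseq) and ct < len(tseq) and qseq[cq] == tseq[ct]:
        matches += 1
        cols += 1
        cq += 1
        ct += 1
    if matches <= 0:
        return None
    if strand == "+":
        q_start, q_end = q0, cq
    else:
        q_start, q_end = query_len - cq, query_len - q0
    return AlignmentRecord(
        query_id=query_id,
        query_len=query_len,
        q_start=q_start,
        q_end=q_end,
        strand=strand,
        target_id=target_id,
        target_len=len(tseq),
        t_start=t0,
        t_end=ct,
        n_matches=matches,
        block_len=cols,
    )


def align(
    query: SeqRecord, index: KmerIndex, preset: AlignPreset | str = "map-long",
    exclude_self: bool = False,
) -> list[AlignmentRecord]:
    """Align one query against the index; returns PAF-semantics records.

    No hits is an empty list, never an error.  Records are sorted by
    query start position.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    k = index.k
    qseq = query.sequence
    qlen = len(qseq)
    if qlen < k:
        return []
    # gather seeds per (target, relative strand), in the orientation frame
    seeds: dict[tuple[str, str], list[tuple[int, int]]] = {}
    pos = index.positions
    for i in range(qlen - k + 1):
        kmer = qseq[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        canon, qstrand = (kmer, "+") if kmer <= rc else (rc, "-")
        for tid, tpos, tstrand in pos.get(canon, ()):
            if exclude_self and tid == query.id:
                continue
            rel = "+" if qstrand == tstrand else "-"
            qpos = i if rel == "+" else qlen - k - i
            seeds.setdefault((tid, rel), []).append((qpos, tpos))

    records = []
    for (tid, rel), ss in sorted(seeds.items()):
        tseq = index.targets[tid]
        oriented_q = qseq if rel == "+" else revcomp(qseq)
        for chain in _chain_seeds(ss, preset):
            if len(chain) < preset.min_seeds:
                continue
            span = chain[-1][0] + k - chain[0][0]
            if span < preset.min_chain_span:
                continue
            rec = _chain_to_record(chain, oriented_q, query.id, qlen, tid, tseq, rel, k)
            if rec is not None:
                records.append(rec)
    records.sort(key=lambda r: (r.q_start, r.q_end, r.target_id, r.t_start))
    return records


def all_vs_all(
    fragments: list[SeqRecord], preset: AlignPreset | str = "ava", k: int = 15
) -> list[AlignmentRecord]:
    """All-vs-all overlaps; self-hits excluded, each pair reported once.

    Each unordered pair appears with the lexicographically smaller id as
    query, making the output symmetric under input order.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    idx = index_reference(sorted(fragments, key=lambda r: r.id), k=k)
    records = []
    for frag in sorted(fragments, key=lambda r: r.id):
        for rec in align(frag, idx, preset, exclude_self=True):
            if rec.query_id < rec.target_id:
                records.append(rec)
    return records
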