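"""Read quality control: mean-quality filtering and adapter trimming.

The per-read quality is the Phred-scaled mean of per-base error
probabilities, Q_read = -10*log10(mean_i 10^(-Q_i/10)) — the convention of
nanopore QC tools, not the arithmetic mean of Phred scores (which would
overestimate quality).  Reads with mean quality below 10 are dropped by
default.  Adapters are searched semi-globally within a 150-base window at
each read end and trimmed at the adapter's inner boundary, repeatedly,
until no confident hit remains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib

from .io import SeqRecord, revcomp

__all__ = ["QCReport", "mean_quality", "filter_by_quality", "trim_adapters", "run_qc"]


@dataclass
class QCReport:
    n_input: int = 0
    n_fail_quality: int = 0
    n_trimmed: int = 0
    n_empty_after_trim: int = 0
    n_pass: int = 0
    mean_q: dict = field(default_factory=dict)  # read_id -> mean quality


def mean_quality(qualities: list[int]) -> float:
    """Phred-scaled mean error probability of a quality string.

    mean_quality([10,10,20]) = -10*log10((0.1+0.1+0.01)/3) ~ 11.55: the
    probability-space mean sits below the arithmetic Phred mean because a
    single bad base dominates the error budget.
    """
    if not qualities:
        raise ValueError("mean_quality of empty quality list")
    p = sum(10.0 ** (-q / 10.0) for q in qualities) / len(qualities)
    return -10.0 * math.log10(p)


def filter_by_quality(
    records: list[SeqRecord], min_q: float = 10.0
) -> tuple[list[SeqRecord], QCReport]:
    """Keep reads whose mean quality is >= min_q (strictly-below dropped)."""
    report = QCReport()
    kept = []
    for rec in records:
        if rec.qualities is None:
            raise ValueError(f"read {rec.id} has no qualities; cannot quality-filter")
        report.n_input += 1
        mq = mean_quality(rec.qualities)
        report.mean_q[rec.id] = mq
        if mq < min_q:
            report.n_fail_quality += 1
        else:
            kept.append(rec)
            report.n_pass += 1
    return kept, report


def _best_adapter_hit(
    window: str, adapters: list[SeqRecord], min_identity: float, min_match: int
):
    """Best infix alignment of any adapter (either strand) inside window.

    Returns (start, end, identity) in window coordinates, or None.
    """
    best = None
    for ad in adapters:
        for aseq in (ad.sequence, revcomp(ad.sequence)):
            if len(aseq) < min_match or len(aseq) > len(window):
                continue
            res = edlib.align(aseq, window, mode="HW", task="locations")
            if res["editDistance"] < 0:
                continue
            ident = 1.0 - res["editDistance"] / len(aseq)
            if ident < min_identity:
                continue
            loc = res["locations"][0]
            cand = (loc[0], loc[1] + 1, ident)
            if best is None or cand[2] > best[2]:
                best = cand
    return best


def trim_adapters(
    record: SeqRecord,
    adapters: list[SeqRecord],
    end_window: int = 150,
    min_identity: float = 0.75,
    min_match: int = 10,
) -> SeqRecord | None:
    """Trim end-anchored adapters; returns None if nothing would remain.

    Each adapter (both strands) is aligned semi-globally against the first
    and last ``end_window`` bases.  A hit with identity >= min_identity over
    an adapter of >= min_match bases truncates the read at the hit's inner
    boundary; the search repeats until no hit.  Output is always a
    contiguous substring of the input; qualities follow in lockstep.
    """
    rec = record
    changed = True
    while changed and len(rec.sequence) > 0:
        changed = False
        w = min(end_window, len(rec.sequence))
        # leading end
        hit = _best_adapter_hit(rec.sequence[:w], adapters, min_identity, min_match)
        if hit is not None:
            rec = rec.slice(hit[1], len(rec.sequence)) if hit[1] < len(rec.sequence) else None
            if rec is None:
                return None
            changed = True
            continue
        # trailing end
        off = len(rec.sequence) - w
        hit = _best_adapter_hit(rec.sequence[off:], adapters, min_identity, min_match)
        if hit is not None:
            if off + hit[0] == 0:
                return None
            rec = rec.slice(0, off + hit[0])
            changed = True
    return rec if len(rec.sequence) > 0 else None


def run_qc(
    records: list[SeqRecord],
    adapters: list[SeqRecord] | None = None,
    min_q: float = 10.0,
    end_window: int = 150,
    min_identity: float = 0.75,
    min_match: int = 10,
) -> tuple[list[SeqRecord], QCReport]:
    """Quality-filter then adapter-trim; reads emptied by trimming are dropped."""
    kept, report = filter_by_quality(records, min_q=min_q)
    if not adapters:
        return kept, report
    out = []
    for rec in kept:
        trimmed = trim_adapters(rec, adapters, end_window, min_identity, min_match)
        if trimmed is None:
            report.n_empty_after_trim += 1
            report.n_pass -= 1
            continue
        if len(trimmed) != len(rec):
            report.n_trimmed += 1
        out.append(trimmed)
    return out, report
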