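"""Low-complexity and simple-tandem-repeat masking.

Long reads are error-prone in low-complexity regions, so fragments that
are mostly repeat are unreliable: a fragment is dropped when at least 80%
of its bases fall in the union of

* DUST-style low-complexity intervals — windows whose triplet composition
  score ``10 * sum_t c_t (c_t - 1) / 2 / (L - 3)`` exceeds a threshold
  (perfect homopolymers score far above any random sequence), and
* short tandem repeats with unit length 1-6 — intervals in which the
  sequence matches itself shifted by the unit length, up to a bounded
  mismatch fraction.

N bases are never masked by themselves but break DUST windows and count
as mismatches in tandem detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .extract import CandidateFragment
from .intervals import merge_intervals, total_length
from .io import Interval

__all__ = ["MaskAnnotation", "dust_mask", "tandem_mask", "annotate", "repeat_filter"]


@dataclass
class MaskAnnotation:
    seq_id: str
    # (interval, class) with class in {"low_complexity", "simple_repeat"}
    segments: list[tuple[Interval, str]]
    masked_fraction: float


def _nfree_chunks(sequence: str):
    """Yield (offset, substring) for maximal N-free stretches."""
    start = None
    for i, c in enumerate(sequence):
        if c == "N":
            if start is not None:
                yield start, sequence[start:i]
                start = None
        elif start is None:
            start = i
    if start is not None:
        yield start, sequence[start:]


def _dust_chunk(seq: str, window: int, score_threshold: float) -> list[Interval]:
    """Masked intervals of one N-free chunk, by rolling triplet counts.

    Every window of length min(window, len) is scored; windows whose score
    strictly exceeds the threshold are masked and merged.
    """
    n = len(seq)
    if n < 4:
        return []
    w = min(window, n)
    counts: dict[str, int] = {}
    pair_sum = 0  # sum over triplets of c*(c-1)/2
    triplets = [seq[i : i + 3] for i in range(n - 2)]
    for t in triplets[: w - 2]:
        c = counts.get(t, 0)
        pair_sum += c
        counts[t] = c + 1
    masked: list[Interval] = []
    denom = w - 3
    for start in range(n - w + 1):
        if start > 0:
            out_t = triplets[start - 1]
            counts[out_t] -= 1
            pair_sum -= counts[out_t]
            in_t = triplets[start + w - 3]
            c = counts.get(in_t, 0)
            pair_sum += c
            counts[in_t] = c + 1
        if 10.0 * pair_sum / denom > score_threshold:
            masked.append(Interval(start, start + w))
    return merge_intervals(masked)


def dust_mask(
    sequence: str, window: int = 64, score_threshold: float = 20.0
) -> list[Interval]:
    """Merged low-complexity intervals of a sequence (DUST triplet score)."""
    out: list[Interval] = []
    for offset, chunk in _nfree_chunks(sequence):
        for iv in _dust_chunk(chunk, window, score_threshold):
            out.append(Interval(offset + iv.start, offset + iv.end))
    return merge_intervals(out)


def tandem_mask(
    sequence: str,
    max_unit: int = 6,
    min_span: int = 20,
    max_mismatch_frac: float = 0.1,
) -> list[Interval]:
    """Merged tandem-repeat intervals for unit lengths 1..max_unit.

    An interval [s, e) is a tandem run of unit u when it spans at least
    max(min_span, 2u) bases and the positions disagreeing with the copy u
    bases earlier number at most max_mismatch_frac * (e - s).  The mask is
    the union of all such intervals, computed exactly by a prefix-maximum
    sweep (for each end, the widest valid start is found in O(log n)).
    """
    n = len(sequence)
    frac = Fraction(str(max_mismatch_frac))
    fn, fd = frac.numerator, frac.denominator
    out: list[Interval] = []
    for u in range(1, max_unit + 1):
        span_req = max(min_span, 2 * u)
        if n < span_req:
            continue
        # prefix[j] = number of mismatch positions < j (positions u..n-1)
        prefix = [0] * (n + 1)
        for j in range(n):
            bad = j >= u and (
                sequence[j] != sequence[j - u]
                or sequence[j] == "N"
            )
            prefix[j + 1] = prefix[j] + (1 if bad else 0)
        # validity of [s,e): fd*(prefix[e]-prefix[s+u]) <= fn*(e-s)
        #   <=>  fd*prefix[e] - fn*e  <=  fd*prefix[s+u] - fn*s
        max_s = n - u
        b_prefix_max = [0] * (max_s + 1)
        best = None
        for s in range(max_s + 1):
            b = fd * prefix[s + u] - fn * s
            best = b if best is None or b > best else best
            b_prefix_max[s] = best
        for e in range(span_req, n + 1):
            s_hi = min(e - span_req, max_s)
            if s_hi < 0:
                continue
            a = fd * prefix[e] - fn * e
            # smallest s with B[s] >= a, i.e. first index where the
            # running max reaches a
            lo, hi = 0, s_hi + 1
            if b_prefix_max[s_hi] < a:
                continue
            while lo < hi:
                mid = (lo + hi) // 2
                if b_prefix_max[mid] >= a:
                    hi = mid
                else:
                    lo = mid + 1
            out.append(Interval(lo, e))
    return merge_intervals(out)


def annotate(
    seq_id: str,
    sequence: str,
    window: int = 64,
    score_threshold: float = 20.0,
    max_unit: int = 6,
    min_span: int = 20,
    max_mismatch_frac: float = 0.1,
) -> MaskAnnotation:
    """Mask a sequence with both detectors and compute the masked fraction."""
    segments = [(iv, "low_complexity") for iv in dust_mask(sequence, window, score_threshold)]
    segments += [
        (iv, "simple_repeat")
        for iv in tandem_mask(sequence, max_unit, min_span, max_mismatch_frac)
    ]
    union = merge_intervals([iv for iv, _ in segments])
    frac = total_length(union) / len(sequence) if sequence else 0.0
    return MaskAnnotation(seq_id, segments, frac)


def repeat_filter(
    fragments: list[CandidateFragment],
    max_masked_frac: float = 0.8,
    **mask_kwargs,
) -> tuple[list[CandidateFragment], list[tuple[CandidateFragment, MaskAnnotation]]]:
    """Drop fragments whose masked fraction is >= max_masked_frac.

    The boundary is inclusive (a fragment exactly 80% masked is removed).
    Returns (kept, dropped-with-annotation).
    """
    kept = []
    dropped = []
    for frag in fragments:
        ann = annotate(frag.fragment_id, frag.sequence, **mask_kwargs)
        if ann.masked_fraction >= max_masked_frac:
            dropped.append((frag, ann))
        else:
            kept.append(frag)
    return kept, dropped
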