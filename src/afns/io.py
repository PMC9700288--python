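"""Readers and writers for the formats the pipeline touches.

FASTQ (Phred+33), FASTA, PAF (minimap2 dialect), BED5 and Kraken2-style
per-sequence classification output.  All coordinates are 0-based half-open
internally, which is the native convention of PAF and BED.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "AlignmentRecord",
    "TaxonomicCall",
    "Interval",
    "ParseError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "parse_paf",
    "format_paf",
    "read_paf",
    "write_paf",
    "parse_kraken2_line",
    "read_kraken2",
    "write_bed",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file violates its format."""


@dataclass
class Interval:
    """A 0-based half-open interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def __iter__(self):
        return iter((self.start, self.end))


@dataclass
class SeqRecord:
    """A read or sequence, with optional per-base Phred qualities."""

    id: str
    sequence: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int, new_id: Optional[str] = None) -> "SeqRecord":
        """Sub-record over [start, end); qualities sliced in lockstep."""
        quals = None if self.qualities is None else self.qualities[start:end]
        return SeqRecord(new_id or self.id, self.sequence[start:end], quals)


@dataclass
class AlignmentRecord:
    """One pairwise alignment with PAF column-1..11 semantics.

    Query coordinates are always on the forward strand of the query;
    ``strand`` records the orientation of the target match.
    """

    query_id: str
    query_len: int
    q_start: int
    q_end: int
    strand: str
    target_id: str
    target_len: int
    t_start: int
    t_end: int
    n_matches: int
    block_len: int
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.q_start < self.q_end <= self.query_len):
            raise ValueError(
                f"bad query interval [{self.q_start},{self.q_end}) "
                f"on {self.query_id} (len {self.query_len})"
            )
        if not (0 <= self.t_start < self.t_end <= self.target_len):
            raise ValueError(
                f"bad target interval [{self.t_start},{self.t_end}) "
                f"on {self.target_id} (len {self.target_len})"
            )
        if not (0 < self.n_matches <= self.block_len):
            raise ValueError(
                f"bad match count {self.n_matches}/{self.block_len}"
            )

    @property
    def identity(self) -> float:
        """Matches over alignment block length, in (0, 1]."""
        return self.n_matches / self.block_len

    @property
    def query_interval(self) -> Interval:
        return Interval(self.q_start, self.q_end)

    @property
    def target_interval(self) -> Interval:
        return Interval(self.t_start, self.t_end)


@dataclass
class TaxonomicCall:
    """A Kraken2-style classification of one sequence."""

    seq_id: str
    classified: bool
    taxid: int
    length: int
    # ordered (taxid, kmer_count); ambiguous entries keep the marker "A"
    lca_counts: list[tuple[object, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.classified and self.taxid != 0:
            raise ValueError(f"{self.seq_id}: unclassified call with taxid {self.taxid}")
        for tax, count in self.lca_counts:
            if count < 1:
                raise ValueError(f"{self.seq_id}: k-mer count {count} < 1 for {tax}")


# ---------------------------------------------------------------------------
# FASTQ


def _decode_quals(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]


def _encode_quals(quals: Iterable[int]) -> str:
    return "".join(chr(min(q, 93) + 33) for q in quals)


def read_fastq(path: str | os.PathLike) -> Iterator[SeqRecord]:
    """Yield records from a 4-line FASTQ file in file order.

    Raises :class:`ParseError` naming the offending line on malformed
    records (missing ``+`` separator, truncation, length mismatch).
    """
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ParseError(f"{path}:{lineno}: expected '@' header, got {header[:20]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus or not qual and qual != "":
                raise ParseError(f"{path}:{lineno}: truncated record")
            lineno += 3
            if not plus.startswith("+"):
                raise ParseError(f"{path}:{lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}:{lineno}: sequence length {len(seq)} != quality length {len(qual)}"
                )
            if not seq:
                raise ParseError(f"{path}:{lineno - 2}: empty sequence")
            rid = header[1:].split()[0]
            yield SeqRecord(rid, normalize_sequence(seq)[0], _decode_quals(qual))


def write_fastq(records: Iterable[SeqRecord], path: str | os.PathLike) -> int:
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            if rec.qualities is None:
                raise ValueError(f"record {rec.id}: FASTQ output requires qualities")
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{_encode_quals(rec.qualities)}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA


def normalize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase, U->T, any other non-ACGTN -> N.

    Returns the normalized string and the number of bases replaced by N.
    """
    seq = seq.upper().replace("U", "T")
    bad = sum(1 for c in seq if c not in "ACGTN")
    if bad:
        seq = "".join(c if c in "ACGTN" else "N" for c in seq)
    return seq, bad


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read (multi-line) FASTA; sequences are normalized to ACGTN."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq, _ = normalize_sequence(str(rec.seq))
        out.append(SeqRecord(rec.id, seq))
    return out


def write_fasta(
    records: Iterable[SeqRecord], path: str | os.PathLike, line_width: int = 60
) -> int:
    """Write FASTA wrapped at ``line_width``; returns record count."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i : i + line_width] + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# PAF


def parse_paf(line: str) -> AlignmentRecord:
    """Parse one PAF line (columns 1-12; extra tags ignored)."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ParseError(f"PAF line has {len(fields)} fields, expected >= 12")
    try:
        return AlignmentRecord(
            query_id=fields[0],
            query_len=int(fields[1]),
            q_start=int(fields[2]),
            q_end=int(fields[3]),
            strand=fields[4],
            target_id=fields[5],
            target_len=int(fields[6]),
            t_start=int(fields[7]),
            t_end=int(fields[8]),
            n_matches=int(fields[9]),
            block_len=int(fields[10]),
            mapq=int(fields[11]),
        )
    except ValueError as exc:
        raise ParseError(f"bad PAF line: {exc}") from None


def format_paf(rec: AlignmentRecord) -> str:
    return "\t".join(
        str(x)
        for x in (
            rec.query_id,
            rec.query_len,
            rec.q_start,
            rec.q_end,
            rec.strand,
            rec.target_id,
            rec.target_len,
            rec.t_start,
            rec.t_end,
            rec.n_matches,
            rec.block_len,
            rec.mapq,
        )
    ) + f"\tid:f:{rec.identity:.4f}"


def read_paf(path: str | os.PathLike) -> list[AlignmentRecord]:
    with open(path) as fh:
        return [parse_paf(line) for line in fh if line.strip()]


def write_paf(records: Iterable[AlignmentRecord], path: str | os.PathLike) -> int:
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(format_paf(rec) + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Kraken2 per-sequence output


def parse_kraken2_line(line: str) -> TaxonomicCall:
    """Parse one 5-column Kraken2 classification line.

    Columns: C/U flag, sequence id, taxid, sequence length, and the
    space-separated ``taxid:count`` LCA mapping string.  Ambiguous-base
    entries (``A:count``) are preserved with the marker ``"A"``.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 5:
        raise ParseError(f"Kraken2 line has {len(fields)} fields, expected 5")
    flag, seq_id, taxid_s, length_s, lca_s = fields[:5]
    if flag not in ("C", "U"):
        raise ParseError(f"unknown classification flag {flag!r}")
    lca_counts: list[tuple[object, int]] = []
    for token in lca_s.split():
        if token == "|:|":  # paired-read separator; not meaningful here
            continue
        try:
            tax_s, count_s = token.split(":")
            count = int(count_s)
            tax: object = "A" if tax_s == "A" else int(tax_s)
        except ValueError:
            raise ParseError(f"malformed taxid:count token {token!r}") from None
        lca_counts.append((tax, count))
    return TaxonomicCall(
        seq_id=seq_id,
        classified=(flag == "C"),
        taxid=int(taxid_s),
        length=int(length_s),
        lca_counts=lca_counts,
    )


def read_kraken2(path: str | os.PathLike) -> list[TaxonomicCall]:
    with open(path) as fh:
        return [parse_kraken2_line(line) for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# BED


def write_bed(rows: Iterable[tuple], path: str | os.PathLike) -> int:
    """Write BED5 rows (target_id, start, end, name, score/support)."""
    n = 0
    with open(path, "w") as fh:
        for row in rows:
            target_id, start, end, name, score = row
            fh.write(f"{target_id}\t{start}\t{end}\t{name}\t{score}\n")
            n += 1
    return n
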