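"""Synthetic data generator: the ground-truth surface for the pipeline.

Emulates a small sequencing study: a random reference genome, per-sample
donor genomes carrying planted novel insertions (shared across all
samples, population-specific, or individual), ONT-like long reads with
substitution/indel errors and per-base qualities tied to the realized
error rate, and contaminant reads from a separate bacterial-like genome
accompanied by Kraken2-format classification lines and a miniature
taxonomy.  Everything is deterministic given the config seed.

Defaults model the study conditions exercised throughout the tests: a
100 kb reference, 20 insertions of 500-3,000 bp, two samples from two
populations sharing half the insertions, 30x depth, 8% total read error
(5% substitutions, 1.5% insertions, 1.5% deletions) and a 5% contaminant
spike-in.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .contam import Taxonomy
from .io import SeqRecord, TaxonomicCall, write_bed, write_fasta, write_fastq

__all__ = [
    "SimConfig",
    "PlantedInsertion",
    "ReadProvenance",
    "TruthSet",
    "SimResult",
    "make_reference",
    "plant_insertions",
    "simulate_reads",
    "simulate_dataset",
    "default_taxonomy",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))

# miniature NCBI-style taxonomy: root, screened clades, a bacterial
# lineage for the contaminant, and a human lineage for the host
_TAX_PARENT = {
    2: 1,        # bacteria
    543: 2,
    561: 543,
    562: 561,    # E. coli
    2157: 1,     # archaea
    4751: 1,     # fungi
    10239: 1,    # viruses
    9604: 1,
    9605: 9604,
    9606: 9605,  # human
}
_ROOTS_OF_INTEREST = {"archaea": 2157, "bacteria": 2, "fungi": 4751, "viral": 10239}
CONTAMINANT_TAXID = 562


@dataclass
class SimConfig:
    seed: int = 42
    ref_len: int = 100_000
    n_insertions: int = 20
    insertion_len_range: tuple[int, int] = (500, 3000)
    depth: float = 30.0
    read_len_mu: float = 8.4      # lognormal of read length, mean ~4.8 kb
    read_len_sigma: float = 0.4
    min_read_len: int = 1000
    sub_rate: float = 0.05
    ins_rate: float = 0.015
    del_rate: float = 0.015
    contam_frac: float = 0.05
    bad_read_frac: float = 0.0    # reads emitted at ~2x error (Q ~ 8)
    samples: tuple[tuple[str, str], ...] = (("s1", "popA"), ("s2", "popB"))
    shared_fraction: float = 0.5
    population_specific_fraction: float = 0.0
    simple_repeat_frac: float = 0.05
    contam_genome_len: int = 30_000
    insertion_min_gap: int = 5000

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0 <= r <= 0.2:
                raise ValueError(f"error rate {r} outside [0, 0.2]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass
class PlantedInsertion:
    insertion_id: str
    sequence: str
    category: str  # shared | population_specific | individual
    ref_locus: int  # reference coordinate of the insertion point
    samples: tuple[str, ...]  # samples carrying it


@dataclass
class ReadProvenance:
    read_id: str
    sample: str
    source: str  # host | contaminant
    donor_start: int
    donor_end: int
    spans_insertion: Optional[str] = None  # fully covered with anchor flank
    overlaps_insertion: Optional[str] = None


@dataclass
class TruthSet:
    insertions: list[PlantedInsertion]
    read_provenance: dict[str, ReadProvenance] = field(default_factory=dict)


@dataclass
class SimResult:
    config: SimConfig
    reference: SeqRecord
    contaminant_genome: SeqRecord
    donors: dict[str, SeqRecord]
    # per sample: donor-coordinate intervals (insertion_id, start, end)
    donor_insertions: dict[str, list[tuple[str, int, int]]]
    reads: dict[str, list[SeqRecord]]
    kraken_calls: dict[str, list[TaxonomicCall]]
    truth: TruthSet
    taxonomy: Taxonomy


def default_taxonomy() -> Taxonomy:
    return Taxonomy(parent=dict(_TAX_PARENT), roots_of_interest=dict(_ROOTS_OF_INTEREST))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, length))


def make_reference(
    length: int = 100_000, seed: int = 42, simple_repeat_frac: float = 0.05,
    name: str = "chr1",
) -> SeqRecord:
    """Random ACGT reference with planted short tandem stretches.

    Tandem stretches (unit 1-6, ~300 bp each) total about
    ``simple_repeat_frac`` of the length; deterministic per seed.
    """
    if length < 10_000:
        raise ValueError("reference length must be >= 10 kb")
    rng = np.random.default_rng([seed, 0])
    seq = list(_random_seq(rng, length))
    if simple_repeat_frac > 0:
        n_stretch = max(1, int(length * simple_repeat_frac / 300))
        for _ in range(n_stretch):
            unit_len = int(rng.integers(1, 7))
            unit = _random_seq(rng, unit_len)
            span = int(rng.integers(200, 400))
            start = int(rng.integers(0, length - span))
            stretch = (unit * (span // unit_len + 1))[:span]
            seq[start : start + span] = list(stretch)
    return SeqRecord(name, "".join(seq))


def plant_insertions(
    reference: SeqRecord, config: SimConfig
) -> tuple[dict[str, SeqRecord], dict[str, list[tuple[str, int, int]]], TruthSet]:
    """Build per-sample donors with novel insertions spliced in.

    Insertion sequences are random (novel by construction); loci are
    non-overlapping points >= ``insertion_min_gap`` apart, away from the
    reference ends.  Categories follow the configured fractions:
    shared -> all samples, population-specific -> every sample of one
    population, individual -> one sample (round-robin).
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_insertions
    margin = 2000
    span_needed = (n - 1) * config.insertion_min_gap
    if span_needed > len(reference.sequence) - 2 * margin:
        raise ValueError(
            f"{n} insertions at >= {config.insertion_min_gap} bp spacing do not "
            f"fit a {len(reference.sequence)} bp reference"
        )
    slack = (len(reference.sequence) - 2 * margin - span_needed) // max(1, n)
    loci = []
    for i in range(n):
        jitter = int(rng.integers(0, max(1, slack)))
        loci.append(margin + i * config.insertion_min_gap + jitter)
    lo, hi = config.insertion_len_range
    n_shared = round(n * config.shared_fraction)
    n_popspec = round(n * config.population_specific_fraction)
    sample_ids = [s for s, _ in config.samples]
    populations = sorted({p for _, p in config.samples})
    insertions: list[PlantedInsertion] = []
    for i, locus in enumerate(loci):
        seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        if i < n_shared:
            category, carriers = "shared", tuple(sample_ids)
        elif i < n_shared + n_popspec:
            pop = populations[(i - n_shared) % len(populations)]
            carriers = tuple(s for s, p in config.samples if p == pop)
            category = "population_specific"
        else:
            category = "individual"
            carriers = (sample_ids[(i - n_shared - n_popspec) % len(sample_ids)],)
        insertions.append(
            PlantedInsertion(f"ins{i + 1}", seq, category, locus, carriers)
        )

    donors: dict[str, SeqRecord] = {}
    donor_insertions: dict[str, list[tuple[str, int, int]]] = {}
    for sample in sample_ids:
        mine = [ins for ins in insertions if sample in ins.samples]
        mine.sort(key=lambda x: x.ref_locus)
        pieces = []
        intervals = []
        cursor = 0
        offset = 0
        for ins in mine:
            pieces.append(reference.sequence[cursor : ins.ref_locus])
            start = ins.ref_locus + offset
            pieces.append(ins.sequence)
            intervals.append((ins.insertion_id, start, start + len(ins.sequence)))
            offset += len(ins.sequence)
            cursor = ins.ref_locus
        pieces.append(reference.sequence[cursor:])
        donors[sample] = SeqRecord(f"{sample}_donor", "".join(pieces))
        donor_insertions[sample] = intervals
    return donors, donor_insertions, TruthSet(insertions=insertions)


def _apply_errors(
    rng: np.random.Generator, template: str, sub: float, ins: float, dele: float
) -> tuple[str, int]:
    """Apply per-base errors; returns (read sequence, error count)."""
    if sub == ins == dele == 0:
        return template, 0
    n = len(template)
    r = rng.random(n)
    subs_at = r < sub
    del_at = (r >= sub) & (r < sub + dele)
    ins_at = (r >= sub + dele) & (r < sub + dele + ins)
    sub_bases = rng.integers(1, 4, size=n)  # offset from original base
    ins_bases = rng.choice(_BASES, size=n)
    out = []
    errors = 0
    base_index = {b: i for i, b in enumerate("ACGT")}
    for i, c in enumerate(template):
        if del_at[i]:
            errors += 1
            continue
        if subs_at[i] and c in base_index:
            c = "ACGT"[(base_index[c] + sub_bases[i]) % 4]
            errors += 1
        out.append(c)
        if ins_at[i]:
            out.append(ins_bases[i])
            errors += 1
    return "".join(out), errors


def _qualities(
    rng: np.random.Generator, length: int, errors: int
) -> list[int]:
    """Per-base Phred tied to the read's realized error rate, with jitter."""
    if errors == 0:
        q = 40.0
    else:
        q = -10.0 * math.log10(errors / max(1, length))
    jitter = rng.integers(-1, 2, size=length)
    return [int(max(2, min(40, round(q + j)))) for j in jitter]


def simulate_reads(
    donor: SeqRecord,
    config: SimConfig,
    rng: np.random.Generator,
    id_prefix: str = "r",
) -> list[tuple[SeqRecord, int, int]]:
    """ONT-like reads to ~``depth``x coverage of the donor.

    Returns (record, donor_start, donor_end) triples; start positions are
    uniform, lengths lognormal truncated to [min_read_len, donor length].
    """
    dlen = len(donor.sequence)
    target_bases = config.depth * dlen
    out = []
    total = 0
    i = 0
    while total < target_bases:
        length = int(rng.lognormal(config.read_len_mu, config.read_len_sigma))
        length = max(config.min_read_len, min(length, dlen))
        start = int(rng.integers(0, dlen - length + 1))
        template = donor.sequence[start : start + length]
        sub, insr, dele = config.sub_rate, config.ins_rate, config.del_rate
        if config.bad_read_frac > 0 and rng.random() < config.bad_read_frac:
            sub, insr, dele = min(0.2, sub * 2.4), min(0.2, insr * 2.4), min(0.2, dele * 2.4)
        seq, errors = _apply_errors(rng, template, sub, insr, dele)
        quals = _qualities(rng, len(seq), errors)
        i += 1
        out.append((SeqRecord(f"{id_prefix}{i}", seq, quals), start, start + length))
        total += length
    return out


def _kraken_call_for(read: SeqRecord, taxid: int, rng: np.random.Generator) -> TaxonomicCall:
    """A plausible Kraken2-style call for a contaminant read."""
    n_kmers = max(2, len(read.sequence) - 34)
    in_clade = max(1, int(n_kmers * (0.85 + 0.1 * rng.random())))
    rest = n_kmers - in_clade
    lca: list[tuple[object, int]] = [(taxid, in_clade)]
    if rest > 0:
        lca.append((0, rest))
    return TaxonomicCall(read.id, True, taxid, len(read.sequence), lca)


def simulate_dataset(config: SimConfig) -> SimResult:
    """Generate the full study: reference, donors, reads, truth, taxonomy."""
    reference = make_reference(
        config.ref_len, config.seed, config.simple_repeat_frac
    )
    contam_rng = np.random.default_rng([config.seed, 2])
    contam_genome = SeqRecord("contamG", _random_seq(contam_rng, config.contam_genome_len))
    donors, donor_insertions, truth = plant_insertions(reference, config)

    reads: dict[str, list[SeqRecord]] = {}
    kraken: dict[str, list[TaxonomicCall]] = {}
    flank = 200  # anchor flank required to count a read as spanning
    for si, (sample, _pop) in enumerate(config.samples):
        rng = np.random.default_rng([config.seed, 3, si])
        host = simulate_reads(donors[sample], config, rng, id_prefix=f"{sample}_r")
        sample_reads = []
        for rec, start, end in host:
            spans = None
            overlaps = None
            for ins_id, istart, iend in donor_insertions[sample]:
                if start < iend and istart < end:
                    overlaps = ins_id
                    if start <= istart - flank and end >= iend + flank:
                        spans = ins_id
                    break
            truth.read_provenance[rec.id] = ReadProvenance(
                rec.id, sample, "host", start, end, spans, overlaps
            )
            sample_reads.append(rec)
        calls = []
        if config.contam_frac > 0:
            n_contam = max(1, round(len(host) * config.contam_frac))
            contam_cfg = SimConfig(
                seed=config.seed,
                ref_len=config.ref_len,
                depth=1,
                read_len_mu=config.read_len_mu,
                read_len_sigma=config.read_len_sigma,
                min_read_len=config.min_read_len,
                sub_rate=config.sub_rate,
                ins_rate=config.ins_rate,
                del_rate=config.del_rate,
                contam_frac=0.0,
            )
            crng = np.random.default_rng([config.seed, 4, si])
            pool = simulate_reads(
                contam_genome, contam_cfg, crng, id_prefix=f"{sample}_c"
            )
            for rec, start, end in pool[:n_contam]:
                truth.read_provenance[rec.id] = ReadProvenance(
                    rec.id, sample, "contaminant", start, end
                )
                sample_reads.append(rec)
                calls.append(_kraken_call_for(rec, CONTAMINANT_TAXID, crng))
        reads[sample] = sample_reads
        kraken[sample] = calls

    return SimResult(
        config=config,
        reference=reference,
        contaminant_genome=contam_genome,
        donors=donors,
        donor_insertions=donor_insertions,
        reads=reads,
        kraken_calls=kraken,
        truth=truth,
        taxonomy=default_taxonomy(),
    )


def write_dataset(result: SimResult, outdir: str | os.PathLike) -> None:
    """Write the dataset as plain-text files (FASTA/FASTQ/TSV/BED)."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    write_fasta([result.reference], os.path.join(outdir, "ref.fa"))
    write_fasta([result.contaminant_genome], os.path.join(outdir, "contam.fa"))
    for sample, recs in sorted(result.reads.items()):
        write_fastq(recs, os.path.join(outdir, f"{sample}.fastq"))
    with open(os.path.join(outdir, "truth_insertions.tsv"), "w") as fh:
        fh.write("insertion_id\tcategory\tref_locus\tlength\tsamples\tsequence\n")
        for ins in result.truth.insertions:
            fh.write(
                f"{ins.insertion_id}\t{ins.category}\t{ins.ref_locus}\t"
                f"{len(ins.sequence)}\t{','.join(ins.samples)}\t{ins.sequence}\n"
            )
    write_bed(
        (
            (result.reference.id, ins.ref_locus, ins.ref_locus + 1,
             f"{ins.insertion_id}|{ins.category}", len(ins.sequence))
            for ins in result.truth.insertions
        ),
        os.path.join(outdir, "truth.bed"),
    )
    with open(os.path.join(outdir, "provenance.tsv"), "w") as fh:
        fh.write("read_id\tsample\tsource\tdonor_start\tdonor_end\tspans\toverlaps\n")
        for prov in result.truth.read_provenance.values():
            fh.write(
                f"{prov.read_id}\t{prov.sample}\t{prov.source}\t{prov.donor_start}\t"
                f"{prov.donor_end}\t{prov.spans_insertion or '.'}\t"
                f"{prov.overlaps_insertion or '.'}\n"
            )
    with open(os.path.join(outdir, "kraken_truth.txt"), "w") as fh:
        for sample, calls in sorted(result.kraken_calls.items()):
            for call in calls:
                lca = " ".join(f"{t}:{c}" for t, c in call.lca_counts)
                fh.write(f"C\t{call.seq_id}\t{call.taxid}\t{call.length}\t{lca}\n")
    with open(os.path.join(outdir, "nodes.dmp"), "w") as fh:
        for child, parent in sorted(_TAX_PARENT.items()):
            fh.write(f"{child}\t|\t{parent}\t|\tno rank\t|\n")
    with open(os.path.join(outdir, "populations.tsv"), "w") as fh:
        for sample, pop in result.config.samples:
            fh.write(f"{sample}\t{pop}\n")
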