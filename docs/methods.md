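# Methods

## The discovery model

A *novel sequence* is a stretch of sample DNA longer than 300 bp with no
alignment to the reference genome.  The pipeline treats each long read as
a miniature assembly: aligned read intervals (merged across all
alignments of the read) are subtracted, and the complement intervals are
the candidates.  Because a single chimeric or noisy alignment pass can
leave reference sequence behind, subtraction is repeated for three
rounds; rounds one and three use the long-read preset of the built-in
aligner, round two a more sensitive preset (minimum chain span 31 with
15-mer seeds) that catches shorter residual reference matches.  Each
round removes *every* reported aligned interval — no identity floor is
applied inside the loop, since the aligner presets already bound spurious
hits — and keeps only complement pieces strictly longer than the 300 bp
cutoff, with coordinates always mapped back to the original read.

Thresholds are deliberately literal: "longer than 300 bp" is strict
(a 300 bp piece is dropped), clustering coverage "> 80%" is strict,
anchor identity "≥ 80%" is inclusive, classification confidence "> 0.05"
is strict, and the repeat filter's 80% is inclusive (an exactly-80%-masked
fragment is removed; the boundary is not stated by the protocol we follow,
so the conservative reading was chosen and is configurable).

## Quality control

Per-read quality is the Phred-scaled mean error probability
`-10·log10(mean_i 10^(-Q_i/10))`, the convention of nanopore QC tools;
the arithmetic mean of Phred scores would overestimate quality because a
few bad bases dominate the error budget.  Reads below Q10 are dropped.
Adapter trimming searches each adapter (both strands) semi-globally
inside a 150 bp window at either read end and truncates at the hit's
inner boundary, repeating until no hit with identity ≥ 0.75 over an
adapter of ≥ 10 bp remains; middle-adapter splitting is out of scope.
The default stage order selects unmapped-fragment-bearing reads first
and quality-filters second; `PipelineConfig.qc_first` flips the order.

## The built-in aligner

`mini_align` is a deterministic seed-and-extend aligner producing PAF.
All canonical (strand-minimal) 15-mers of the targets are indexed — no
minimizer subsampling, so output is independent of hash choices.  Query
seeds are grouped per (target, strand), banded by diagonal
(`band_width`), chained by a patience-style longest-increasing-
subsequence pass with ties broken at the leftmost query start, and split
at gaps over `max_seed_gap`.  Gaps between consecutive chain anchors are
closed with an edit-distance alignment (edlib) whose extended CIGAR
yields exact match counts; ends are extended ungapped.  Reported identity
is matches / alignment columns.  On pairs within 10% divergence this
identity tracks a full dynamic-programming alignment to ±0.02 (checked
against Biopython's PairwiseAligner, an independent implementation).
Chains shorter than `min_chain_span` on the query, or with fewer than
`min_seeds` seeds, are discarded: map-long/ava use span 100 and 3 seeds,
the sensitive preset span 31 and 2 seeds.

## Contaminant screening

Classification confidence is recomputed from the per-sequence LCA k-mer
string rather than trusted from upstream: C/Q where C sums counts whose
taxid lies in the clade of the call and Q sums all counts except
ambiguous ("A") entries; unclassified (taxid 0) k-mers count in Q only.
This makes the strict `> 0.05` rule enforceable on classifier output
produced with any upstream confidence setting.  A fragment is removed
when its call falls under archaea, bacteria, fungi or viruses (clade
roots in the taxonomy) or carries a plasmid/UniVec library label —
libraries are matched by a seq-id→library table because they are not
taxa.  Unclassified fragments and fragments without a call are kept.
Fragments inherit the call of their source read when classification was
done per read.

## Redundancy clustering

Two fragments link when their mutual alignment blocks, merged, cover
more than 80% of the *shorter* fragment; clusters are connected
components (single linkage) and the longest member represents each
(ties: lexicographically smallest id).  Shorter-sequence coverage was
chosen over reciprocal coverage because a longest-member representative
presupposes clusters of unequal length; reciprocal mode is available via
`reciprocal_coverage`.  Cluster ids are assigned after sorting by
representative length, making output independent of input order.

## Repeat masking

Two detectors stand in for a full repeat annotator, covering exactly the
two classes the final filter uses:

* **DUST-style low complexity** — every 64 bp window (shorter at
  sequences under 64 bp) is scored `10 · Σ_t c_t(c_t−1)/2 / (L−3)` over
  its triplet counts; windows scoring > 20 are masked and merged.
  Implemented with rolling counts; the tests compare against a from-
  scratch window rescan.  N bases break windows and are never masked
  alone.
* **Simple tandem repeats** — for each unit length u ≤ 6, an interval
  [s, e) is a run when it spans ≥ max(20, 2u) bases and positions
  disagreeing with the copy u bases earlier number ≤ 10% of the span
  (exact rational arithmetic at the boundary).  The mask is the union of
  *all* such intervals, computed by a prefix-maximum sweep that finds the
  widest valid start for every end in O(n log n) per unit — "greedy
  extension" alone is underdetermined, while union-of-valid-intervals is
  order-free and verifiable by exhaustive scan.

A fragment is dropped when the union of both masks covers ≥ 80% of it.

## Placement calling

Alignments below 80% identity are discarded; a read is usable when
exactly one alignment remains, or exactly two *consistent* ones — same
target and strand, non-overlapping on read and reference, reference
order matching read order (reversed on the minus strand).  Unmapped read
intervals strictly longer than 1,000 bp adjacent to the anchors become
calls: between two anchors a BEP whose breakpoint is the inter-anchor
reference span (zero-width when the anchors abut; anchors overlapping on
the reference — micro-homology — collapse to their midpoint), past a
single anchor at a read end an SEP with a zero-width breakpoint at the
anchor's facing boundary.  A middle fragment beside a single anchor is
counted but not called.

SEP calls merge by single-linkage when breakpoints on the same target
are within 100 bp (inclusive).  The BEP merge rule is stated ambiguously
in the protocol this follows ("length difference between their overlap
and length"); it is implemented as breakpoint proximity ≤ 100 bp *and*
near-full-length mutual fragment overlap, |overlap − min(len_a, len_b)|
< 100 bp, the only reading that uses both quantities.  BEP and SEP
clusters are never merged with each other.  Clusters with fewer than
three supporting reads are removed; the longest fragment represents a
cluster.  Across samples, clusters of the same kind match when
breakpoints are within 100 bp and representatives align at ≥ 80%
identity; a locus in one sample is *individual*, in ≥ 2 samples of one
population *population-specific*, across populations
*population-shared*.

## The simulator

`simulate_dataset` emulates a small multi-sample long-read study.  The
reference is i.i.d. uniform ACGT with ~5% planted short tandem
stretches.  Insertions are random novel sequence of 500–3,000 bp placed
≥ 5 kb apart away from the reference ends; categories follow configured
fractions (shared → all samples, population-specific → one population's
samples, individual → one sample, round-robin).  Reads start uniformly,
lengths are lognormal (μ=8.4, σ=0.4; mean ≈ 4.8 kb) truncated to ≥ 1 kb;
substitutions/insertions/deletions default to 5%/1.5%/1.5% (8% total,
ONT-like).  Per-base qualities are tied to each read's realized error
rate (Q = −10·log10(realized) ± 1 jitter), so the Q10 filter is
meaningfully exercisable: default reads sit near Q11 and pass, while the
`bad_read_frac` mode emits ~2.4× error (≈ Q8) reads that must be
dropped.  Contaminant reads (5% of the host count per sample) come from
a separate random genome and ship with Kraken2-format calls (taxid 562
under the bacteria clade, ~90% clade k-mers) plus a 10-node taxonomy.
Everything derives from numpy generators seeded from the config seed:
same config, byte-identical outputs.

What the simulator does **not** model: homopolymer-biased ONT error
profiles, quality variation along a read, diploidy/haplotypes,
structural variation other than clean insertions, divergent (rather than
random) novel sequence, and real contaminant genomes.  Passing tests
therefore show the *logic* of the pipeline is sound under its stated
assumptions, not that the thresholds are optimal for real ONT data.

Insertions are random high-entropy sequence so the repeat filter never
removes true positives in the default study; decoy runs (poly-A spikes)
exercise the 80% rule separately in the tests.

## Problem sizes and numerical choices

The default study used throughout the tests and the acceptance script is
a 100 kb single-chromosome reference, 20 insertions, two samples at 30×
(~1,600 reads, ~8 Mb), chosen so a full two-sample discovery + placement
run completes in minutes on one CPU while leaving every threshold at its
published value.  Interval arithmetic, clustering, SEP merging, DUST and
tandem masking are validated against brute-force oracles on randomized
instances; the aligner against dynamic programming; the end-to-end flows
against the simulator's truth tables, including the error-free limit
(100% recovery at identity 1.0) and the no-novelty limit (reads drawn
from the reference produce an empty final set).

Known limitations: the aligner's ungapped end extension slightly
under-covers read ends relative to an affine-gap aligner; placement
anchor acceptance (≤ 2 alignments) discards reads spanning two nearby
insertions; very long unmapped tails produce SEP fragments that include
sequence beyond the insertion itself, so SEP representatives overestimate
insertion length — all consistent with the read-level, polish-free design
(no error correction is applied by intent).
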