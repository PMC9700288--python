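"""Contaminant removal from Kraken2-style per-sequence classifications.

A fragment is treated as a contaminant when its taxonomic call falls
inside one of the screened clades (archaea, bacteria, fungi, viruses) or
carries a vector/plasmid library label, *and* the classification
confidence exceeds 0.05 (strict).  Confidence is recomputed from the LCA
k-mer string — clade k-mers over all counted k-mers, ambiguous entries
excluded from the denominator, unclassified (taxid 0) k-mers included in
the denominator only — so the rule can be enforced on output produced
with any upstream ``--confidence`` setting.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

from .extract import CandidateFragment
from .io import TaxonomicCall

__all__ = ["Taxonomy", "confidence", "is_contaminant", "filter_contaminants"]

ROOT_TAXID = 1


@dataclass
class Taxonomy:
    """Parent map plus the clade roots and library labels screened out."""

    parent: dict[int, int]
    roots_of_interest: dict[str, int] = field(default_factory=dict)
    # seq_id -> library name, for sequence libraries that are not taxa
    label_sets: dict[str, str] = field(default_factory=dict)
    screened_labels: frozenset[str] = frozenset({"plasmid", "UniVec"})

    def __post_init__(self) -> None:
        for child in self.parent:
            if not self._reaches_root(child):
                raise ValueError(f"taxid {child}: parent chain does not reach root")

    def _reaches_root(self, taxid: int, limit: int = 10_000) -> bool:
        seen = 0
        while taxid != ROOT_TAXID:
            if taxid not in self.parent or seen > limit:
                return False
            taxid = self.parent[taxid]
            seen += 1
        return True

    def knows(self, taxid: int) -> bool:
        return taxid == ROOT_TAXID or taxid in self.parent

    def lineage(self, taxid: int) -> list[int]:
        """Taxid and all its ancestors up to the root."""
        out = [taxid]
        while taxid != ROOT_TAXID:
            taxid = self.parent[taxid]
            out.append(taxid)
        return out

    def in_clade(self, taxid: int, clade_root: int) -> bool:
        return clade_root in self.lineage(taxid)

    def in_screened_clade(self, taxid: int) -> bool:
        lineage = set(self.lineage(taxid))
        return any(root in lineage for root in self.roots_of_interest.values())

    @classmethod
    def from_nodes(
        cls,
        nodes_path: str | os.PathLike,
        roots_of_interest: dict[str, int],
        labels_path: str | os.PathLike | None = None,
    ) -> "Taxonomy":
        """Load from an NCBI-style nodes table (child, parent, rank)."""
        parent: dict[int, int] = {}
        with open(nodes_path) as fh:
            for line in fh:
                fields = [f.strip() for f in line.replace("|", "\t").split("\t") if f.strip()]
                if len(fields) < 2:
                    continue
                child, par = int(fields[0]), int(fields[1])
                if child != ROOT_TAXID:
                    parent[child] = par
        labels: dict[str, str] = {}
        if labels_path is not None:
            with open(labels_path) as fh:
                for row in csv.reader(fh, delimiter="\t"):
                    if len(row) >= 2:
                        labels[row[0]] = row[1]
        return cls(parent=parent, roots_of_interest=roots_of_interest, label_sets=labels)


def confidence(call: TaxonomicCall, taxonomy: Taxonomy) -> float:
    """Fraction of counted k-mers assigned within the called clade.

    C/Q with C = counts whose taxid lies in the clade rooted at the call's
    taxid and Q = all counts except ambiguous ("A") entries.  Unclassified
    (taxid 0) k-mers contribute to Q only.
    """
    if not call.classified:
        raise ValueError(f"{call.seq_id}: confidence of an unclassified call")
    clade_total = 0
    denom = 0
    for tax, count in call.lca_counts:
        if tax == "A":
            continue
        denom += count
        if tax == 0:
            continue
        if not taxonomy.knows(tax):
            raise ValueError(f"{call.seq_id}: unknown taxid {tax} in LCA string")
        if taxonomy.in_clade(tax, call.taxid):
            clade_total += count
    if denom == 0:
        return 0.0
    return clade_total / denom


def is_contaminant(
    call: TaxonomicCall, taxonomy: Taxonomy, conf_threshold: float = 0.05
) -> bool:
    """True iff the call lands in a screened clade/library with confidence
    strictly above the threshold."""
    if not call.classified:
        return False
    label = taxonomy.label_sets.get(call.seq_id)
    in_library = label is not None and label in taxonomy.screened_labels
    if not in_library and not (
        taxonomy.knows(call.taxid) and taxonomy.in_screened_clade(call.taxid)
    ):
        return False
    return confidence(call, taxonomy) > conf_threshold


def filter_contaminants(
    fragments: list[CandidateFragment],
    calls: list[TaxonomicCall],
    taxonomy: Taxonomy,
    conf_threshold: float = 0.05,
) -> tuple[list[CandidateFragment], list[tuple[str, int, float]]]:
    """Partition fragments into kept and removed-as-contaminant.

    Fragments without a call are kept (they cannot exceed any confidence
    threshold).  The removal report lists (fragment_id, taxid, confidence).
    """
    by_id: dict[str, TaxonomicCall] = {}
    for call in calls:
        if call.seq_id in by_id:
            raise ValueError(f"duplicate classification for {call.seq_id}")
        by_id[call.seq_id] = call
    kept = []
    removed = []
    for frag in fragments:
        call = by_id.get(frag.fragment_id)
        if call is not None and is_contaminant(call, taxonomy, conf_threshold):
            removed.append((frag.fragment_id, call.taxid, confidence(call, taxonomy)))
        else:
            kept.append(frag)
    return kept, removed
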