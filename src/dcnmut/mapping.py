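"""Peptide-to-genomic coordinate conversion and mutation-to-domain assignment.

Domain hits live in peptide coordinates while somatic mutation calls carry
genomic positions, so every domain occurrence is first converted to a genomic
footprint through its gene model.  Residue r of a protein occupies CDS
nucleotides 3(r-1)+1 .. 3r, where CDS nucleotide order follows translation
order: ascending genomic position on the '+' strand, descending on '-'.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .types import DomainHit, GeneModel, MutationRecord

logger = logging.getLogger(__name__)

GenomicInterval = Tuple[str, int, int]  # (chrom, start, end) 1-based inclusive


class MappingError(ValueError):
    """Raised when a domain cannot be placed on its gene model."""


def peptide_to_genomic(hit: DomainHit, model: GeneModel) -> List[GenomicInterval]:
    """Genomic intervals covering the CDS nucleotides of one domain occurrence.

    Returns one interval per overlapped CDS block, in ascending genomic
    order.  The summed interval length always equals
    3 * (pep_end - pep_start + 1).
    """
    if model.protein_id != hit.protein_id:
        raise MappingError(
            f"gene model {model.gene_id} is for protein {model.protein_id}, "
            f"hit is in {hit.protein_id}"
        )
    cds_len = model.cds_length
    nt_start = 3 * (hit.pep_start - 1) + 1
    nt_end = 3 * hit.pep_end
    if nt_end > cds_len:
        raise MappingError(
            f"domain {hit.domain_acc} residues {hit.pep_start}-{hit.pep_end} extend past the "
            f"CDS of {hit.protein_id} ({cds_len // 3} aa)"
        )

    intervals: List[Tuple[int, int]] = []
    offset = 0  # CDS nucleotides consumed by previous blocks (translation order)
    for start, end in model.blocks_in_translation_order():
        block_len = end - start + 1
        lo = max(nt_start, offset + 1)
        hi = min(nt_end, offset + block_len)
        if lo <= hi:
            if model.strand == "+":
                g_lo = start + (lo - offset - 1)
                g_hi = start + (hi - offset - 1)
            else:
                g_hi = end - (lo - offset - 1)
                g_lo = end - (hi - offset - 1)
            intervals.append((g_lo, g_hi))
        offset += block_len
        if offset >= nt_end:
            break
    intervals.sort()
    return [(model.chrom, lo, hi) for lo, hi in intervals]


def genomic_to_residue(position: int, model: GeneModel) -> int:
    """Residue index (1-based) covering one genomic position, or 0 if outside the CDS."""
    offset = 0
    for start, end in model.blocks_in_translation_order():
        if start <= position <= end:
            if model.strand == "+":
                nt = offset + (position - start) + 1
            else:
                nt = offset + (end - position) + 1
            return (nt - 1) // 3 + 1
        offset += end - start + 1
    return 0


@dataclass
class DomainFootprint:
    """All genomic intervals occupied by one domain family across the proteome."""

    domain_acc: str
    occurrences: List[Tuple[str, List[GenomicInterval]]] = field(default_factory=list)

    @property
    def cumulative_length(self) -> int:
        """Total genomic bp summed over every occurrence (the normalizer L_d)."""
        return sum(e - s + 1 for _, ivs in self.occurrences for _, s, e in ivs)


def build_footprints(
    hits: Sequence[DomainHit], models: Mapping[str, GeneModel]
) -> Dict[str, DomainFootprint]:
    """Convert every hit to genomic intervals, grouped by domain accession.

    ``models`` is keyed by protein_id; a hit whose protein has no gene model
    raises :class:`MappingError`.
    """
    footprints: Dict[str, DomainFootprint] = {}
    for hit in hits:
        model = models.get(hit.protein_id)
        if model is None:
            raise MappingError(f"no gene model for protein {hit.protein_id}")
        ivs = peptide_to_genomic(hit, model)
        fp = footprints.setdefault(hit.domain_acc, DomainFootprint(domain_acc=hit.domain_acc))
        fp.occurrences.append((hit.protein_id, ivs))
    return footprints


#: variant classifications removed before mutation counting
FILTERED_CLASSES = frozenset({"silent", "rna"})


def filter_mutations(records: Sequence[MutationRecord]) -> List[MutationRecord]:
    """Drop Silent and RNA records (case-insensitive); keep everything else."""
    kept = [r for r in records if r.variant_classification.lower() not in FILTERED_CLASSES]
    logger.info("filtered %d/%d silent/RNA mutations", len(records) - len(kept), len(records))
    return kept


@dataclass
class DomainMutationCounts:
    """Per-domain mutation assignments plus the mapped-total bookkeeping.

    A mutation inside the footprints of two different domains increments both
    domains' counts but contributes once to ``mapped``; a mutation inside two
    occurrences of the same domain increments that domain once.
    """

    counts: Dict[str, int]
    total: int
    mapped: int

    @property
    def mapped_percentage(self) -> float:
        return 100.0 * self.mapped / self.total if self.total else 0.0


def map_mutations(
    records: Sequence[MutationRecord], footprints: Mapping[str, DomainFootprint]
) -> DomainMutationCounts:
    """Assign mutations to domains by genomic position membership.

    Interval membership is inclusive on both ends.  Lookup uses per-chromosome
    interval trees; results are contractually identical to a linear scan over
    all intervals.
    """
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for fp in footprints.values():
        for _, ivs in fp.occurrences:
            for chrom, start, end in ivs:
                trees[chrom].addi(start, end + 1, fp.domain_acc)

    counts: Dict[str, int] = {acc: 0 for acc in footprints}
    mapped = 0
    for rec in records:
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        doms: Set[str] = {iv.data for iv in tree.at(rec.position)}
        if doms:
            mapped += 1
            for d in doms:
                counts[d] += 1
    return DomainMutationCounts(counts=counts, total=len(records), mapped=mapped)
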