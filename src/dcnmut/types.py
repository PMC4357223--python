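"""Core record types shared across the pipeline.

Coordinate conventions
----------------------
All coordinates are 1-based and inclusive on both ends, matching the MAF and
PfamScan dialects the pipeline reads.  Peptide coordinates count amino acids
from the protein N-terminus; genomic coordinates count base pairs along the
chromosome.  BED export (0-based, half-open) is handled at the single
conversion point in :mod:`dcnmut.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple


class ValidationError(ValueError):
    """Raised when a record violates one of its structural invariants."""


@dataclass(frozen=True)
class DomainHit:
    """One Pfam domain occurrence in one protein.

    ``pep_start``/``pep_end`` are the alignment bounds in amino-acid
    coordinates (1-based, inclusive).
    """

    protein_id: str
    domain_acc: str
    domain_name: str
    pep_start: int
    pep_end: int
    e_value: float

    def __post_init__(self) -> None:
        if not (1 <= self.pep_start <= self.pep_end):
            raise ValidationError(
                f"domain hit {self.domain_acc} in {self.protein_id}: "
                f"need 1 <= pep_start <= pep_end, got [{self.pep_start}, {self.pep_end}]"
            )
        if self.e_value < 0:
            raise ValidationError(
                f"domain hit {self.domain_acc} in {self.protein_id}: "
                f"negative e-value {self.e_value}"
            )

    @property
    def length_aa(self) -> int:
        return self.pep_end - self.pep_start + 1


@dataclass(frozen=True)
class GeneModel:
    """Placement of one protein-coding gene on the genome.

    ``cds_blocks`` are genomic intervals (1-based, inclusive), stored in
    ascending genomic order regardless of strand.  Translation order follows
    ascending genomic position on '+' and descending on '-'.
    """

    gene_id: str
    protein_id: str
    chrom: str
    strand: str
    cds_blocks: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_blocks:
            raise ValidationError(f"gene {self.gene_id}: no CDS blocks")
        object.__setattr__(self, "cds_blocks", tuple(tuple(b) for b in self.cds_blocks))
        prev_end = 0
        for start, end in self.cds_blocks:
            if start < 1 or end < start:
                raise ValidationError(f"gene {self.gene_id}: bad CDS block [{start}, {end}]")
            if start <= prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: CDS blocks overlap or are unsorted at [{start}, {end}]"
                )
            prev_end = end
        if self.cds_length % 3 != 0:
            raise ValidationError(
                f"gene {self.gene_id}: total CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_blocks)

    @property
    def protein_length_aa(self) -> int:
        return self.cds_length // 3

    def blocks_in_translation_order(self) -> Tuple[Tuple[int, int], ...]:
        if self.strand == "+":
            return self.cds_blocks
        return tuple(reversed(self.cds_blocks))


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call (minimal MAF column subset)."""

    chrom: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_classification: str
    sample_id: str
    cancer_type: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"mutation at {self.chrom}:{self.position}: position must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"mutation at {self.chrom}:{self.position}: ref and alt alleles are identical"
            )


@dataclass(frozen=True)
class ConservationLabel:
    """Evolutionary-conservation call for one domain family."""

    domain_acc: str
    conserved: bool


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the synthetic generator.

    ``rel_rate`` maps each domain accession appearing in the generated
    annotation table to the relative mutation rate actually used (1.0 means
    the baseline per-bp rate).  ``hot_domains`` are the planted elevated-rate
    domains; ``conserved`` holds the conservation labels once drawn.
    """

    rel_rate: dict = field(default_factory=dict)
    hot_domains: set = field(default_factory=set)
    conserved: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "rel_rate": dict(sorted(self.rel_rate.items())),
            "hot_domains": sorted(self.hot_domains),
            "conserved": dict(sorted(self.conserved.items())),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            rel_rate=dict(d.get("rel_rate", {})),
            hot_domains=set(d.get("hot_domains", [])),
            conserved=dict(d.get("conserved", {})),
        )
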