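"""Readers and writers for every on-disk format the pipeline touches.

Dialects:

* PfamScan tabular output (whitespace-separated, ``#`` comments) for domain
  hits; the alignment start/end columns define the domain interval.
* TCGA MAF (tab-separated, minimal column subset) for somatic mutations.
* Gene-model TSV: ``gene_id  protein_id  chrom  strand  cds_blocks`` with
  blocks encoded ``start-end,start-end`` in ascending genomic order.
* Conservation TSV: ``domain_acc  conserved``.
* BED (0-based half-open) for footprint export — the only place the internal
  1-based inclusive convention is converted.
* Two-column TSV edge lists with an optional support column.

Readers reject invariant violations rather than repairing them silently.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Sequence

import networkx as nx
import pandas as pd

from .types import ConservationLabel, DomainHit, GeneModel, MutationRecord, ValidationError

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when a file cannot be parsed under its declared dialect."""


# --------------------------------------------------------------------------
# PfamScan
# --------------------------------------------------------------------------

#: column order of pfam_scan.pl tabular output
_PFAMSCAN_COLUMNS = (
    "seq_id aln_start aln_end env_start env_end hmm_acc hmm_name type "
    "hmm_start hmm_end hmm_length bit_score e_value"
).split()


def read_pfamscan(path) -> List[DomainHit]:
    """Parse PfamScan tabular output into :class:`DomainHit` records.

    Alignment coordinates (columns 2-3), not envelope coordinates, define
    the peptide interval.  Lines starting with ``#`` and blank lines are
    skipped.  Malformed rows raise :class:`ParseError` with the line number.
    """
    hits: List[DomainHit] = []
    n_data = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n_data += 1
            fields = line.split()
            if len(fields) < 13:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 13 whitespace-separated PfamScan "
                    f"columns ({', '.join(_PFAMSCAN_COLUMNS)}), got {len(fields)}"
                )
            try:
                pep_start = int(fields[1])
                pep_end = int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer alignment coordinate: {exc}") from None
            try:
                e_value = float(fields[12])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric e-value {fields[12]!r}") from None
            try:
                hits.append(
                    DomainHit(
                        protein_id=fields[0],
                        domain_acc=fields[5],
                        domain_name=fields[6],
                        pep_start=pep_start,
                        pep_end=pep_end,
                        e_value=e_value,
                    )
                )
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    if n_data == 0:
        logger.warning("%s: no data rows (comment-only or empty file)", path)
    return hits


def write_pfamscan(hits: Iterable[DomainHit], path) -> None:
    """Write hits in the PfamScan tabular dialect that :func:`read_pfamscan` reads."""
    with open(path, "w") as fh:
        fh.write("# " + " ".join(_PFAMSCAN_COLUMNS) + "\n")
        for h in hits:
            # envelope == alignment, hmm coords 1..len: adequate for this dialect
            n = h.length_aa
            fh.write(
                f"{h.protein_id} {h.pep_start} {h.pep_end} {h.pep_start} {h.pep_end} "
                f"{h.domain_acc} {h.domain_name} Domain 1 {n} {n} 0.0 {h.e_value:g}\n"
            )


# --------------------------------------------------------------------------
# MAF
# --------------------------------------------------------------------------

_MAF_REQUIRED = {
    "chromosome": "chrom",
    "start_position": "position",
    "reference_allele": "ref_allele",
    "tumor_seq_allele2": "alt_allele",
    "variant_classification": "variant_classification",
    "tumor_sample_barcode": "sample_id",
}


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix; comparisons are string-exact thereafter."""
    return name[3:] if name.lower().startswith("chr") else name


def read_maf(path, cancer_type: str = "") -> List[MutationRecord]:
    """Read the minimal MAF column subset into :class:`MutationRecord` list.

    Column matching is case-insensitive (``Start_position`` and
    ``Start_Position`` both accepted).  Chromosome names are normalized by
    stripping a leading ``chr``.  ``cancer_type`` is a caller-supplied label,
    not a MAF column.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    colmap: Dict[str, str] = {}
    lowered = {c.lower(): c for c in df.columns}
    missing = [lc for lc in _MAF_REQUIRED if lc not in lowered]
    if missing:
        raise ParseError(
            f"{path}: mandatory MAF columns absent (case-insensitive match): {', '.join(missing)}"
        )
    for lc, attr in _MAF_REQUIRED.items():
        colmap[attr] = lowered[lc]
    records: List[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rowd = dict(zip(df.columns, row))
        pos_raw = rowd[colmap["position"]]
        try:
            position = int(pos_raw)
        except (TypeError, ValueError):
            raise ParseError(f"{path}: line {i}: non-integer Start_position {pos_raw!r}") from None
        try:
            records.append(
                MutationRecord(
                    chrom=normalize_chrom(str(rowd[colmap["chrom"]])),
                    position=position,
                    ref_allele=str(rowd[colmap["ref_allele"]]),
                    alt_allele=str(rowd[colmap["alt_allele"]]),
                    variant_classification=str(rowd[colmap["variant_classification"]]),
                    sample_id=str(rowd[colmap["sample_id"]]),
                    cancer_type=cancer_type,
                )
            )
        except ValidationError as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from None
    return records


def write_maf(records: Iterable[MutationRecord], path) -> None:
    rows = [
        {
            "Chromosome": r.chrom,
            "Start_position": r.position,
            "Reference_Allele": r.ref_allele,
            "Tumor_Seq_Allele2": r.alt_allele,
            "Variant_Classification": r.variant_classification,
            "Tumor_Sample_Barcode": r.sample_id,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "Chromosome",
            "Start_position",
            "Reference_Allele",
            "Tumor_Seq_Allele2",
            "Variant_Classification",
            "Tumor_Sample_Barcode",
        ],
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Gene models
# --------------------------------------------------------------------------


def read_gene_models(path) -> List[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "protein_id", "chrom", "strand", "cds_blocks"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: gene-model columns missing: {sorted(missing)}")
    models: List[GeneModel] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        blocks = []
        for token in str(row.cds_blocks).split(","):
            try:
                s, e = token.split("-")
                blocks.append((int(s), int(e)))
            except ValueError:
                raise ParseError(f"{path}: line {i}: bad CDS block token {token!r}") from None
        try:
            models.append(
                GeneModel(
                    gene_id=str(row.gene_id),
                    protein_id=str(row.protein_id),
                    chrom=normalize_chrom(str(row.chrom)),
                    strand=str(row.strand),
                    cds_blocks=tuple(blocks),
                )
            )
        except ValidationError as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from None
    return models


def write_gene_models(models: Iterable[GeneModel], path) -> None:
    rows = [
        {
            "gene_id": m.gene_id,
            "protein_id": m.protein_id,
            "chrom": m.chrom,
            "strand": m.strand,
            "cds_blocks": ",".join(f"{s}-{e}" for s, e in m.cds_blocks),
        }
        for m in models
    ]
    pd.DataFrame(rows, columns=["gene_id", "protein_id", "chrom", "strand", "cds_blocks"]).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------------
# Conservation labels
# --------------------------------------------------------------------------


def read_conservation(path) -> List[ConservationLabel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"domain_acc", "conserved"}.issubset(df.columns):
        raise ParseError(f"{path}: need columns domain_acc, conserved")
    if df["domain_acc"].duplicated().any():
        dup = df.loc[df["domain_acc"].duplicated(), "domain_acc"].iloc[0]
        raise ParseError(f"{path}: duplicate conservation row for domain {dup}")
    out = []
    for row in df.itertuples(index=False):
        val = str(row.conserved).strip().lower()
        if val not in {"0", "1", "true", "false"}:
            raise ParseError(f"{path}: conserved must be 0/1/true/false, got {row.conserved!r}")
        out.append(ConservationLabel(domain_acc=str(row.domain_acc), conserved=val in {"1", "true"}))
    return out


def write_conservation(labels: Iterable[ConservationLabel], path) -> None:
    rows = [{"domain_acc": l.domain_acc, "conserved": int(l.conserved)} for l in labels]
    pd.DataFrame(rows, columns=["domain_acc", "conserved"]).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# BED / edge list / generic tables
# --------------------------------------------------------------------------


def write_bed(footprints, path) -> None:
    """Export domain footprints as BED.

    Internal intervals are 1-based inclusive; BED is 0-based half-open, so the
    start is decremented by one and the end kept.  One row per genomic interval,
    named ``domain_acc|protein_id``.
    """
    lines = []
    for fp in footprints.values() if isinstance(footprints, dict) else footprints:
        for protein_id, intervals in fp.occurrences:
            for chrom, start, end in intervals:
                lines.append((chrom, start - 1, end, f"{fp.domain_acc}|{protein_id}"))
    lines.sort()
    with open(path, "w") as fh:
        for chrom, start, end, name in lines:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_edge_list(graph: nx.Graph, path) -> None:
    """Write a sorted TSV edge list with the per-edge protein support count."""
    with open(path, "w") as fh:
        fh.write("domain_a\tdomain_b\tsupport\n")
        for u, v, data in sorted(
            (tuple(sorted((u, v))) + (d,) for u, v, d in graph.edges(data=True)),
            key=lambda t: (t[0], t[1]),
        ):
            fh.write(f"{u}\t{v}\t{data.get('support', 1)}\n")


def read_edge_list(path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"domain_a": str, "domain_b": str})
    if not {"domain_a", "domain_b"}.issubset(df.columns):
        raise ParseError(f"{path}: need columns domain_a, domain_b")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        support = int(getattr(row, "support", 1))
        if support < 1:
            raise ParseError(f"{path}: edge support must be >= 1, got {support}")
        g.add_edge(row.domain_a, row.domain_b, support=support)
    return g


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table as TSV with header, stable float formatting."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
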