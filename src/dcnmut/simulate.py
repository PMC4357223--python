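"""Synthetic proteomes, gene models, mutations, and conservation labels.

The generator emulates the statistical structure the downstream analysis
assumes: multi-domain proteins whose domain-usage frequencies are heavy
tailed (a bounded Zipf law), so the co-occurrence network is scale-free-like
with a deep nested core; gene models with 1-5 CDS blocks on both strands; a
somatic mutation process with a per-bp baseline rate, a stated fraction of
Silent/RNA records, and a planted multiplicative depletion of mutation rate
with domain coreness:

    rate(domain d) = baseline_rate * exp(-core_depletion_beta * coreness(d))

Optionally a small set of "hot" driver-like domains is planted at an
elevated rate (``hot_factor`` times baseline, overriding the depletion).
Hot domains are drawn from outside the innermost nested cores, mirroring the
modeled biology in which deep-core domains are conserved and mutation
depleted.  All outputs are deterministic functions of the config seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from . import kcore, mapping, network
from .types import ConservationLabel, DomainHit, GeneModel, MutationRecord, SyntheticTruth

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a desk-scale analogue of a proteome-wide analysis:
    ~1,300 domain families in use over 4,000 proteins, ~3 Mbp of coding
    sequence, a scale-free-like network with a deep nested core, and a
    baseline of 0.03 mutations/bp giving ~5e4 mutations before filtering
    (the coreness depletion lowers the realized total below rate x length).
    """

    n_domains: int = 1500
    n_proteins: int = 4000
    domain_usage_exponent: float = 1.0
    domains_per_protein: Tuple[int, int] = (1, 4)
    cds_blocks_per_gene: Tuple[int, int] = (1, 5)
    domain_length_aa: Tuple[int, int] = (30, 120)
    baseline_rate: float = 0.03
    core_depletion_beta: float = 0.15
    silent_fraction: float = 0.25
    rna_fraction: float = 0.05
    conservation_base_prob: float = 0.2
    conservation_core_slope: float = 0.08
    seed: int = 0
    # hit-quality noise: fraction of hits given e-values in (0.01, 1]
    evalue_noise_fraction: float = 0.05
    # planted elevated-rate domains
    n_hot_domains: int = 25
    hot_factor: float = 10.0
    hot_min_footprint_bp: int = 300
    hot_core_exclusion: int = 3  # hot domains excluded from the top cores
    n_chromosomes: int = 23
    n_samples: int = 50

    def __post_init__(self) -> None:
        for name in ("n_domains", "n_proteins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("domains_per_protein", "cds_blocks_per_gene", "domain_length_aa"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name}: need 1 <= lo <= hi, got ({lo}, {hi})")
        if not (1 <= self.cds_blocks_per_gene[1] <= 5):
            raise ValueError("cds_blocks_per_gene must lie within [1, 5]")
        for name in ("silent_fraction", "rna_fraction", "conservation_base_prob",
                     "evalue_noise_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.silent_fraction + self.rna_fraction >= 1.0:
            raise ValueError("silent_fraction + rna_fraction must be < 1")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.core_depletion_beta < 0:
            raise ValueError("core_depletion_beta must be nonnegative")


def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def generate_proteome(config: SimConfig) -> Tuple[List[DomainHit], List[GeneModel]]:
    """Draw domain hits and matching gene models.

    Each protein receives 1..max domain hits at non-overlapping peptide
    intervals, with domain identity drawn from the bounded Zipf popularity
    law.  Each domain family has one fixed length.  The gene model's total
    CDS length is exactly 3x the protein length in aa, split over 1-5
    non-overlapping blocks with intronic gaps, on a uniformly random strand.
    Hit e-values are <= 0.01 except an ``evalue_noise_fraction`` injected in
    (0.01, 1] to exercise the network's inclusion filter.
    """
    rng = np.random.default_rng([config.seed, 0])
    accs = [f"PF{i:05d}" for i in range(1, config.n_domains + 1)]
    probs = _zipf_probs(config.n_domains, config.domain_usage_exponent)
    dom_len = rng.integers(config.domain_length_aa[0], config.domain_length_aa[1] + 1,
                           size=config.n_domains)

    hits: List[DomainHit] = []
    models: List[GeneModel] = []
    chrom_cursor: Dict[str, int] = {}
    dmin, dmax = config.domains_per_protein
    bmin, bmax = config.cds_blocks_per_gene

    for pi in range(config.n_proteins):
        protein_id = f"SYNP{pi + 1:06d}"
        n_dom = int(rng.integers(dmin, dmax + 1))
        dom_idx = rng.choice(config.n_domains, size=n_dom, p=probs)
        cursor = int(rng.integers(5, 31))  # N-terminal flank
        protein_hits = []
        for di in dom_idx:
            length = int(dom_len[di])
            start = cursor + 1
            end = cursor + length
            protein_hits.append((accs[di], start, end))
            cursor = end + int(rng.integers(0, 31))  # inter-domain linker
        aa_len = cursor + int(rng.integers(5, 31))  # C-terminal flank

        for acc, start, end in protein_hits:
            if rng.random() < config.evalue_noise_fraction:
                e_value = float(rng.uniform(0.0101, 1.0))
            else:
                e_value = float(10.0 ** (-rng.uniform(3.0, 30.0)))
            hits.append(DomainHit(protein_id, acc, acc.replace("PF", "Dom"), start, end, e_value))

        cds_len = 3 * aa_len
        n_blocks = int(rng.integers(bmin, min(bmax, cds_len) + 1))
        if n_blocks > 1:
            cuts = np.sort(rng.choice(np.arange(1, cds_len), size=n_blocks - 1, replace=False))
            lengths = np.diff(np.concatenate(([0], cuts, [cds_len])))
        else:
            lengths = np.array([cds_len])
        chrom = str(1 + pi % config.n_chromosomes)
        pos = chrom_cursor.get(chrom, 0) + int(rng.integers(1000, 10001))
        blocks = []
        for bl in lengths:
            blocks.append((pos + 1, pos + int(bl)))
            pos += int(bl) + int(rng.integers(50, 2001))  # intron
        chrom_cursor[chrom] = blocks[-1][1]
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel(f"SYNG{pi + 1:06d}", protein_id, chrom, strand, tuple(blocks)))
    return hits, models


def _select_hot_domains(
    footprints: Mapping[str, mapping.DomainFootprint],
    coreness: Mapping[str, int],
    config: SimConfig,
    rng: np.random.Generator,
) -> Set[str]:
    if config.n_hot_domains == 0:
        return set()
    k_max = max(coreness.values(), default=0)
    k_cap = max(0, k_max - config.hot_core_exclusion)
    eligible = sorted(
        acc for acc, fp in footprints.items()
        if fp.cumulative_length >= config.hot_min_footprint_bp
        and coreness.get(acc, 0) <= k_cap
    )
    if len(eligible) < config.n_hot_domains:
        logger.warning("only %d domains eligible as hot (wanted %d)", len(eligible),
                       config.n_hot_domains)
    take = min(config.n_hot_domains, len(eligible))
    return set(rng.choice(np.array(eligible, dtype=object), size=take, replace=False))


def generate_mutations(
    hits: Sequence[DomainHit],
    models: Sequence[GeneModel],
    coreness: Mapping[str, int],
    config: SimConfig,
    hot_domains: Optional[Set[str]] = None,
    cancer_type: str = "SYN",
) -> Tuple[List[MutationRecord], SyntheticTruth]:
    """Sample somatic mutations over the coding genome.

    Domain footprints (from hits passing the e <= 0.01 quality filter) mutate
    at ``baseline_rate * exp(-beta * coreness)``, hot domains at
    ``hot_factor * baseline_rate``, and all remaining coding sequence —
    including footprints of spurious high-e-value hits — at the baseline.
    Counts per region are Poisson; positions are uniform within the region.
    A ``silent_fraction`` of records is labeled Silent and an ``rna_fraction``
    RNA, independently of position, so filtering thins the set uniformly.
    """
    rng = np.random.default_rng([config.seed, 1])
    model_by_protein = {m.protein_id: m for m in models}
    good_hits = network.filter_hits(list(hits), network.DEFAULT_EVALUE_MAX)
    footprints = mapping.build_footprints(good_hits, model_by_protein)
    if hot_domains is None:
        hot_domains = _select_hot_domains(footprints, coreness, config, rng)
    unknown_hot = hot_domains - set(footprints)
    if unknown_hot:
        raise ValueError(f"hot domains absent from the annotation table: {sorted(unknown_hot)}")

    def domain_rel_rate(acc: str) -> float:
        if acc in hot_domains:
            return config.hot_factor
        return math.exp(-config.core_depletion_beta * coreness.get(acc, 0))

    # regions: (chrom, start, end, relative rate)
    regions: List[Tuple[str, int, int, float]] = []
    hits_by_protein: Dict[str, List[DomainHit]] = {}
    for h in good_hits:
        hits_by_protein.setdefault(h.protein_id, []).append(h)
    total_cds = 0
    for m in models:
        total_cds += m.cds_length
        covered: List[Tuple[int, int, float]] = []
        for h in hits_by_protein.get(m.protein_id, []):
            rel = domain_rel_rate(h.domain_acc)
            for chrom, s, e in mapping.peptide_to_genomic(h, m):
                covered.append((s, e, rel))
        covered.sort()
        for s, e, rel in covered:
            regions.append((m.chrom, s, e, rel))
        # complement of domain intervals within the CDS blocks, at baseline
        cov_iter = iter(covered)
        cov = next(cov_iter, None)
        for bs, be in m.cds_blocks:
            cursor = bs
            while cov is not None and cov[1] < cursor:
                cov = next(cov_iter, None)
            while cov is not None and cov[0] <= be:
                if cov[0] > cursor:
                    regions.append((m.chrom, cursor, cov[0] - 1, 1.0))
                cursor = max(cursor, cov[1] + 1)
                if cov[1] <= be:
                    cov = next(cov_iter, None)
                else:
                    break
            if cursor <= be:
                regions.append((m.chrom, cursor, be, 1.0))
    if total_cds == 0:
        raise ValueError("generate_mutations: empty coding footprint")

    classes = np.array(["Silent", "RNA", "Missense_Mutation", "Nonsense_Mutation"])
    class_p = np.array([
        config.silent_fraction,
        config.rna_fraction,
        0.9 * (1.0 - config.silent_fraction - config.rna_fraction),
        0.1 * (1.0 - config.silent_fraction - config.rna_fraction),
    ])
    samples = [f"TCGA-SYN-{i:03d}" for i in range(1, config.n_samples + 1)]

    records: List[MutationRecord] = []
    for chrom, s, e, rel in regions:
        length = e - s + 1
        count = int(rng.poisson(config.baseline_rate * rel * length))
        if count == 0:
            continue
        positions = s + rng.integers(0, length, size=count)
        kinds = rng.choice(classes, size=count, p=class_p)
        refs = rng.integers(0, 4, size=count)
        alts = (refs + rng.integers(1, 4, size=count)) % 4
        sample_idx = rng.integers(0, len(samples), size=count)
        for j in range(count):
            records.append(
                MutationRecord(
                    chrom=chrom,
                    position=int(positions[j]),
                    ref_allele=str(_BASES[refs[j]]),
                    alt_allele=str(_BASES[alts[j]]),
                    variant_classification=str(kinds[j]),
                    sample_id=samples[sample_idx[j]],
                    cancer_type=cancer_type,
                )
            )

    all_accs = sorted({h.domain_acc for h in hits})
    rel_rate = {}
    for acc in all_accs:
        rel_rate[acc] = domain_rel_rate(acc) if acc in footprints else 1.0
    truth = SyntheticTruth(rel_rate=rel_rate, hot_domains=set(hot_domains))
    return records, truth


def generate_conservation_labels(
    coreness: Mapping[str, int], config: SimConfig
) -> List[ConservationLabel]:
    """Bernoulli conservation labels with core-order-dependent probability.

    P(conserved | coreness k) = clamp(base_prob + slope * k, 0, 1); one label
    per domain, deterministic under the config seed.
    """
    rng = np.random.default_rng([config.seed, 2])
    labels = []
    for acc in sorted(coreness):
        p = float(np.clip(
            config.conservation_base_prob + config.conservation_core_slope * coreness[acc],
            0.0, 1.0,
        ))
        labels.append(ConservationLabel(domain_acc=acc, conserved=bool(rng.random() < p)))
    return labels


@dataclass
class SyntheticDataset:
    """Everything one simulated study produces, plus ground truth."""

    config: SimConfig
    hits: List[DomainHit]
    models: List[GeneModel]
    dcn: "object"  # networkx.Graph
    decomposition: kcore.CoreDecomposition
    mutations: List[MutationRecord]
    conservation: List[ConservationLabel]
    truth: SyntheticTruth


def simulate_dataset(config: SimConfig, cancer_type: str = "SYN") -> SyntheticDataset:
    """Run the full generation chain: proteome -> DCN -> coreness -> mutations.

    The DCN is built from the generated hits at e <= 0.01 and decomposed; the
    resulting coreness drives the planted depletion, the hot-domain placement,
    and the conservation labels.  Truth conservation labels are recorded on
    the truth object.
    """
    hits, models = generate_proteome(config)
    dcn = network.build_dcn(hits)
    decomposition = kcore.decompose(dcn)
    mutations, truth = generate_mutations(hits, models, decomposition.coreness, config,
                                          cancer_type=cancer_type)
    conservation = generate_conservation_labels(decomposition.coreness, config)
    truth.conserved = {l.domain_acc: l.conserved for l in conservation}
    return SyntheticDataset(
        config=config,
        hits=hits,
        models=models,
        dcn=dcn,
        decomposition=decomposition,
        mutations=mutations,
        conservation=conservation,
        truth=truth,
    )
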