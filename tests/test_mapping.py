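import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import random_gene_model
from dcnmut.mapping import (
    MappingError,
    build_footprints,
    filter_mutations,
    genomic_to_residue,
    map_mutations,
    peptide_to_genomic,
)
from dcnmut.types import DomainHit, GeneModel, MutationRecord


def _hit(protein, start, end, acc="PF1"):
    return DomainHit(protein, acc, acc, start, end, 1e-9)


def per_base_oracle(hit: DomainHit, model: GeneModel) -> set:
    """Enumerate every genomic position of the domain one CDS nucleotide at a time."""
    order = []
    for s, e in model.blocks_in_translation_order():
        order.extend(range(s, e + 1) if model.strand == "+" else range(e, s - 1, -1))
    return set(order[3 * (hit.pep_start - 1): 3 * hit.pep_end])


def covered_positions(intervals) -> set:
    return {p for _, s, e in intervals for p in range(s, e + 1)}


def test_single_block_plus_strand():
    model = GeneModel("G1", "P1", "1", "+", ((1001, 1900),))
    assert peptide_to_genomic(_hit("P1", 1, 10), model) == [("1", 1001, 1030)]


def test_single_block_minus_strand():
    model = GeneModel("G1", "P1", "1", "-", ((1001, 1900),))
    assert peptide_to_genomic(_hit("P1", 1, 10), model) == [("1", 1871, 1900)]


def test_two_block_plus_strand_spans_intron():
    model = GeneModel("G1", "P1", "1", "+", ((100, 129), (200, 259)))
    # residues 6-15 -> CDS nt 16..45 -> 14 bp of block 1 then 15 bp of block 2
    assert peptide_to_genomic(_hit("P1", 6, 15), model) == [("1", 115, 129), ("1", 200, 214)]


def test_domain_past_cds_end_is_an_error():
    model = GeneModel("G1", "P1", "1", "+", ((100, 129),))  # 10 aa
    with pytest.raises(MappingError, match="extend past"):
        peptide_to_genomic(_hit("P1", 5, 11), model)


def test_protein_mismatch_is_an_error():
    model = GeneModel("G1", "P2", "1", "+", ((100, 129),))
    with pytest.raises(MappingError):
        peptide_to_genomic(_hit("P1", 1, 5), model)


def test_matches_per_base_oracle_on_random_models():
    rng = np.random.default_rng(0)
    for _ in range(300):
        model = random_gene_model(rng)
        aa = model.protein_length_aa
        start = int(rng.integers(1, aa + 1))
        end = int(rng.integers(start, aa + 1))
        hit = _hit("P1", start, end)
        ivs = peptide_to_genomic(hit, model)
        assert covered_positions(ivs) == per_base_oracle(hit, model)
        # intervals are ascending and disjoint; lengths sum to 3 x residues
        flat = [(s, e) for _, s, e in ivs]
        assert flat == sorted(flat)
        assert all(a[1] < b[0] for a, b in zip(flat, flat[1:]))
        assert sum(e - s + 1 for s, e in flat) == 3 * (end - start + 1)


@given(st.integers(0, 2**31 - 1))
def test_codon_round_trip_both_strands(seed):
    """Every genomic position of residue r maps back to residue r."""
    rng = np.random.default_rng(seed)
    model = random_gene_model(rng)
    aa = model.protein_length_aa
    r = int(rng.integers(1, aa + 1))
    ivs = peptide_to_genomic(_hit("P1", r, r), model)
    positions = covered_positions(ivs)
    assert len(positions) == 3
    assert all(genomic_to_residue(p, model) == r for p in positions)


def test_filter_removes_silent_and_rna_case_insensitively():
    recs = [
        MutationRecord("1", 1, "A", "G", "Missense_Mutation", "S"),
        MutationRecord("1", 2, "A", "G", "Silent", "S"),
        MutationRecord("1", 3, "A", "G", "RNA", "S"),
        MutationRecord("1", 4, "A", "G", "Nonsense_Mutation", "S"),
        MutationRecord("1", 5, "A", "G", "silent", "S"),
    ]
    kept = filter_mutations(recs)
    assert [r.variant_classification for r in kept] == ["Missense_Mutation", "Nonsense_Mutation"]
    assert filter_mutations([]) == []


def _footprints_for(hits, models):
    return build_footprints(hits, {m.protein_id: m for m in models})


def test_mapped_percentage_and_boundary_inclusivity():
    model = GeneModel("G1", "P1", "1", "+", ((1001, 1900),))
    fps = _footprints_for([_hit("P1", 1, 10)], [model])  # footprint 1001-1030
    recs = [
        MutationRecord("1", 1030, "A", "G", "Missense_Mutation", "S"),  # end boundary: inside
        MutationRecord("1", 1001, "A", "G", "Missense_Mutation", "S"),  # start boundary: inside
        MutationRecord("1", 1031, "A", "G", "Missense_Mutation", "S"),  # outside
    ]
    counts = map_mutations(recs, fps)
    assert counts.counts["PF1"] == 2
    assert counts.mapped == 2
    assert counts.mapped_percentage == pytest.approx(100 * 2 / 3)


def test_overlapping_domains_double_count_but_map_once():
    model = GeneModel("G1", "P1", "1", "+", ((1001, 1900),))
    hits = [_hit("P1", 1, 10, "PF1"), _hit("P1", 5, 20, "PF2")]
    fps = _footprints_for(hits, [model])
    rec = MutationRecord("1", 1020, "A", "G", "Missense_Mutation", "S")  # residue 7: both
    counts = map_mutations([rec], fps)
    assert counts.counts == {"PF1": 1, "PF2": 1}
    assert counts.mapped == 1


def linear_scan_counts(records, footprints):
    """O(n*m) membership oracle."""
    counts = {acc: 0 for acc in footprints}
    mapped = 0
    for r in records:
        doms = set()
        for acc, fp in footprints.items():
            for _, ivs in fp.occurrences:
                for chrom, s, e in ivs:
                    if chrom == r.chrom and s <= r.position <= e:
                        doms.add(acc)
        if doms:
            mapped += 1
            for d in doms:
                counts[d] += 1
    return counts, mapped


@pytest.mark.parametrize("seed", range(10))
def test_assignment_matches_linear_scan_oracle(seed):
    rng = np.random.default_rng(seed)
    models, hits = [], []
    for i in range(15):
        m = random_gene_model(rng, gene_id=f"G{i}", protein_id=f"P{i}")
        models.append(m)
        for j in range(int(rng.integers(1, 4))):
            aa = m.protein_length_aa
            s = int(rng.integers(1, aa + 1))
            e = int(rng.integers(s, aa + 1))
            hits.append(_hit(f"P{i}", s, e, acc=f"PF{rng.integers(1, 8)}"))
    fps = _footprints_for(hits, models)
    records = [
        MutationRecord(str(rng.integers(1, 23)), int(rng.integers(1, 120_000)),
                       "A", "G", "Missense_Mutation", "S")
        for _ in range(200)
    ]
    counts = map_mutations(records, fps)
    oracle_counts, oracle_mapped = linear_scan_counts(records, fps)
    assert counts.counts == oracle_counts
    assert counts.mapped == oracle_mapped


def test_map_mutations_order_invariant():
    rng = np.random.default_rng(99)
    model = random_gene_model(rng)
    fps = _footprints_for([_hit("P1", 1, model.protein_length_aa)], [model])
    records = [
        MutationRecord(model.chrom, int(rng.integers(1, 110_000)), "A", "G", "X", "S")
        for _ in range(100)
    ]
    a = map_mutations(records, fps)
    b = map_mutations(list(reversed(records)), fps)
    assert a.counts == b.counts and a.mapped == b.mapped


def test_cumulative_length_sums_all_occurrences():
    m1 = GeneModel("G1", "P1", "1", "+", ((100, 159),))
    m2 = GeneModel("G2", "P2", "2", "-", ((500, 559),))
    fps = _footprints_for([_hit("P1", 1, 10), _hit("P2", 3, 12)], [m1, m2])
    assert fps["PF1"].cumulative_length == 60
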