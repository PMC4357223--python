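import numpy as np
import pytest
from scipy import stats as sps

from dcnmut import io as dio
from dcnmut.simulate import (
    SimConfig,
    generate_conservation_labels,
    generate_mutations,
    generate_proteome,
    simulate_dataset,
)


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        SimConfig(silent_fraction=0.7, rna_fraction=0.4)
    with pytest.raises(ValueError):
        SimConfig(domains_per_protein=(3, 2))
    with pytest.raises(ValueError):
        SimConfig(baseline_rate=0.0)
    with pytest.raises(ValueError):
        SimConfig(n_proteins=0)


def test_counts_forced_by_config():
    cfg = SimConfig(n_domains=10, n_proteins=2, domains_per_protein=(2, 2), seed=0)
    hits, models = generate_proteome(cfg)
    assert len(hits) == 4
    assert len(models) == 2


def test_cds_length_is_three_times_protein_length():
    cfg = SimConfig(n_domains=50, n_proteins=40, seed=3)
    hits, models = generate_proteome(cfg)
    by_protein = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    for m in models:
        max_end = max(h.pep_end for h in by_protein[m.protein_id])
        assert m.cds_length % 3 == 0
        assert m.protein_length_aa >= max_end  # every hit fits inside the protein


def test_hits_non_overlapping_within_protein():
    cfg = SimConfig(n_domains=30, n_proteins=50, domains_per_protein=(2, 4), seed=4)
    hits, _ = generate_proteome(cfg)
    by_protein = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append((h.pep_start, h.pep_end))
    for ivs in by_protein.values():
        ivs.sort()
        assert all(a[1] < b[0] for a, b in zip(ivs, ivs[1:]))


def test_seed_determinism_byte_identical(tmp_path, small_config):
    paths = []
    for tag in ("a", "b"):
        ds = simulate_dataset(small_config)
        dio.write_pfamscan(ds.hits, tmp_path / f"hits.{tag}")
        dio.write_gene_models(ds.models, tmp_path / f"gm.{tag}")
        dio.write_maf(ds.mutations, tmp_path / f"maf.{tag}")
        dio.write_conservation(ds.conservation, tmp_path / f"cons.{tag}")
        paths.append(tag)
    for stem in ("hits", "gm", "maf", "cons"):
        assert (tmp_path / f"{stem}.a").read_bytes() == (tmp_path / f"{stem}.b").read_bytes()


def test_evalue_noise_fraction_injected():
    cfg = SimConfig(n_domains=100, n_proteins=400, seed=5)
    hits, _ = generate_proteome(cfg)
    frac = np.mean([h.e_value > 0.01 for h in hits])
    n = len(hits)
    lo, hi = sps.binom.ppf([0.005, 0.995], n, cfg.evalue_noise_fraction) / n
    assert lo <= frac <= hi
    assert all(h.e_value <= 1.0 for h in hits)


def test_silent_fraction_within_binomial_bounds(small_config):
    import dataclasses

    cfg = dataclasses.replace(small_config, silent_fraction=0.3, seed=6)
    ds = simulate_dataset(cfg)
    n = len(ds.mutations)
    assert n > 2000
    n_silent = sum(m.variant_classification == "Silent" for m in ds.mutations)
    lo, hi = sps.binom.ppf([0.005, 0.995], n, 0.3)
    assert lo <= n_silent <= hi


def test_mutations_fall_inside_cds_blocks(small_dataset):
    blocks_by_chrom = {}
    for m in small_dataset.models:
        blocks_by_chrom.setdefault(m.chrom, []).extend(m.cds_blocks)
    for rec in small_dataset.mutations:
        assert any(s <= rec.position <= e for s, e in blocks_by_chrom[rec.chrom]), rec


def test_beta_zero_counts_proportional_to_footprint(small_config):
    """With no depletion the expected count per domain is rate x footprint."""
    import dataclasses

    from dcnmut import mapping, network

    cfg = dataclasses.replace(small_config, core_depletion_beta=0.0, n_hot_domains=0,
                              silent_fraction=0.0, rna_fraction=0.0, seed=8)
    ds = simulate_dataset(cfg)
    models = {m.protein_id: m for m in ds.models}
    fps = mapping.build_footprints(network.filter_hits(ds.hits), models)
    counts = mapping.map_mutations(ds.mutations, fps)
    # pooled Poisson check across domains with a sizable footprint
    for acc, fp in fps.items():
        if fp.cumulative_length < 2000:
            continue
        expected = cfg.baseline_rate * fp.cumulative_length
        lo, hi = sps.poisson.ppf([0.0005, 0.9995], expected)
        assert lo <= counts.counts[acc] <= hi, acc


def test_planted_hot_domain_poisson_oracle(small_config):
    """A 10x hot domain's count lands in the Poisson band around 10 x baseline x L."""
    import dataclasses

    from dcnmut import mapping, network

    cfg = dataclasses.replace(small_config, seed=9)
    ds = simulate_dataset(cfg)
    models = {m.protein_id: m for m in ds.models}
    fps = mapping.build_footprints(network.filter_hits(ds.hits), models)
    counts = mapping.map_mutations(ds.mutations, fps)
    assert ds.truth.hot_domains
    for acc in ds.truth.hot_domains:
        L = fps[acc].cumulative_length
        expected = cfg.hot_factor * cfg.baseline_rate * L
        lo, hi = sps.poisson.ppf([0.005, 0.995], expected)
        assert lo <= counts.counts[acc] <= hi, (acc, L, counts.counts[acc], expected)
        assert ds.truth.rel_rate[acc] == cfg.hot_factor


def test_hot_domains_avoid_innermost_cores(small_dataset):
    k_max = small_dataset.decomposition.k_max
    cap = k_max - small_dataset.config.hot_core_exclusion
    for acc in small_dataset.truth.hot_domains:
        assert small_dataset.decomposition.coreness.get(acc, 0) <= cap


def test_truth_covers_every_annotated_domain(small_dataset):
    annotated = {h.domain_acc for h in small_dataset.hits}
    assert set(small_dataset.truth.rel_rate) == annotated


def test_depletion_gives_negative_density_trend(default_dataset):
    """Observed per-core mutation density decreases with core order (Spearman)."""
    from dcnmut import mapping, network

    ds = default_dataset
    models = {m.protein_id: m for m in ds.models}
    fps = mapping.build_footprints(network.filter_hits(ds.hits), models)
    counts = mapping.map_mutations(mapping.filter_mutations(ds.mutations), fps)
    decomp = ds.decomposition
    ks, densities = [], []
    for k in range(1, decomp.k_max + 1):
        members = [d for d in decomp.core_members(k) if d in fps]
        L = sum(fps[d].cumulative_length for d in members)
        m = sum(counts.counts[d] for d in members)
        if L:
            ks.append(k)
            densities.append(m / L)
    rho = sps.spearmanr(ks, densities)
    assert rho.statistic < 0
    assert rho.pvalue < 0.01


def test_conservation_probability_model():
    coreness = {f"D{i}": i % 12 for i in range(3000)}
    cfg = SimConfig(conservation_base_prob=0.2, conservation_core_slope=0.0, seed=10)
    labels = generate_conservation_labels(coreness, cfg)
    frac = np.mean([l.conserved for l in labels])
    lo, hi = sps.binom.ppf([0.005, 0.995], len(labels), 0.2) / len(labels)
    assert lo <= frac <= hi

    # slope pushes the probability to the clamp: base 0.2 + 0.08 * 10 = 1.0
    cfg2 = SimConfig(conservation_base_prob=0.2, conservation_core_slope=0.08, seed=11)
    high_k = {f"D{i}": 10 for i in range(200)}
    labels2 = generate_conservation_labels(high_k, cfg2)
    assert all(l.conserved for l in labels2)

    # positive slope: conserved fraction increases with k (Monte-Carlo)
    labels3 = generate_conservation_labels(coreness, cfg2)
    by_k = {}
    for l in labels3:
        by_k.setdefault(coreness[l.domain_acc], []).append(l.conserved)
    fracs = [np.mean(by_k[k]) for k in sorted(by_k)]
    rho = sps.spearmanr(sorted(by_k), fracs)
    assert rho.statistic > 0.9


def test_generate_mutations_rejects_unknown_hot_domain(small_config):
    hits, models = generate_proteome(small_config)
    with pytest.raises(ValueError, match="hot domains absent"):
        generate_mutations(hits, models, {}, small_config, hot_domains={"PF99999"})
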