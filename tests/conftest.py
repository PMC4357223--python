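import numpy as np
import pytest
from hypothesis import settings

from dcnmut import kcore, mapping, network, simulate
from dcnmut.types import GeneModel

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study conditions for fast unit tests."""
    return simulate.SimConfig(
        n_domains=120,
        n_proteins=300,
        baseline_rate=0.02,
        n_hot_domains=5,
        n_samples=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated study at the package's documented default scale."""
    return simulate.simulate_dataset(simulate.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_dataset):
    """Full downstream analysis of the default-scale dataset."""
    from dcnmut import stats as dstats

    ds = default_dataset
    main = network.largest_component(ds.dcn)
    decomp = kcore.decompose(main)
    ensembles = kcore.random_ensembles(main, decomp, n_replicates=100, seed=101)
    models = {m.protein_id: m for m in ds.models}
    footprints = mapping.build_footprints(network.filter_hits(ds.hits), models)
    kept = mapping.filter_mutations(ds.mutations)
    counts = mapping.map_mutations(kept, footprints)
    table, fit = dstats.compute_domain_stats(counts, footprints)
    from dcnmut.profile import profile_cores

    significant = set(dstats.call_significant(table))
    conservation = {l.domain_acc: l.conserved for l in ds.conservation}
    prof = profile_cores(decomp, ensembles, table, conservation, significant)
    return {
        "profile": prof,
        "significant": significant,
        "conservation": conservation,
        "dataset": ds,
        "main": main,
        "decomp": decomp,
        "ensembles": ensembles,
        "footprints": footprints,
        "filtered": kept,
        "counts": counts,
        "stats": table,
        "lfdr_fit": fit,
    }


def random_gene_model(rng: np.random.Generator, gene_id: str = "G1",
                      protein_id: str = "P1") -> GeneModel:
    """Random 1-5 block gene model on either strand, total length 3*aa."""
    aa = int(rng.integers(20, 300))
    cds_len = 3 * aa
    n_blocks = int(rng.integers(1, 6))
    if n_blocks > 1:
        cuts = np.sort(rng.choice(np.arange(1, cds_len), size=n_blocks - 1, replace=False))
        lengths = np.diff(np.concatenate(([0], cuts, [cds_len])))
    else:
        lengths = np.array([cds_len])
    pos = int(rng.integers(1, 100_000))
    blocks = []
    for bl in lengths:
        blocks.append((pos + 1, pos + int(bl)))
        pos += int(bl) + int(rng.integers(1, 500))
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(gene_id, protein_id, str(rng.integers(1, 23)), strand, tuple(blocks))
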