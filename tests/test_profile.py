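import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dcnmut import kcore, mapping, network
from dcnmut.kcore import CoreDecomposition
from dcnmut.mapping import DomainFootprint
from dcnmut.profile import chi_square_cores, profile_cores, trend_test
from dcnmut.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="module")
def toy_graph():
    g = nx.gnp_random_graph(40, 0.25, seed=0)
    g = nx.relabel_nodes(g, {n: f"D{n}" for n in g.nodes()})
    decomp = kcore.decompose(g)
    ens = kcore.random_ensembles(g, decomp, n_replicates=50, seed=1)
    return g, decomp, ens


def _stats_table(nodes, s_values):
    return pd.DataFrame({"domain_acc": list(nodes), "s": list(s_values)})


def test_all_conserved_gives_100pct_and_zero_z(toy_graph):
    g, decomp, ens = toy_graph
    stats = _stats_table(g.nodes(), np.ones(g.number_of_nodes()))
    cons = {n: True for n in g.nodes()}
    prof = profile_cores(decomp, ens, stats, conservation=cons, significant=set())
    assert np.allclose(prof["pct_conserved"], 100.0)
    assert np.allclose(prof["pct_conserved_z"], 0.0)
    assert np.allclose(prof["pct_significant"], 0.0)


def test_significant_set_outside_inner_cores_gives_zero_pct(toy_graph):
    g, decomp, ens = toy_graph
    k_split = decomp.k_max - 1
    inner = decomp.core_members(k_split)
    significant = set(g.nodes()) - inner  # disjoint from the inner cores
    stats = _stats_table(g.nodes(), np.ones(g.number_of_nodes()))
    prof = profile_cores(decomp, ens, stats, significant=significant)
    for k in (k_split, decomp.k_max):
        assert prof.loc[prof["k"] == k, "pct_significant"].iloc[0] == 0.0


def test_profile_requires_shared_universe(toy_graph):
    g, decomp, ens = toy_graph
    stats = _stats_table(["ZZZ1", "ZZZ2"], [1.0, 2.0])
    with pytest.raises(ValueError, match="no domains"):
        profile_cores(decomp, ens, stats)


def test_trend_statistic_is_minus_one_for_decreasing(toy_graph):
    g, decomp, ens = toy_graph
    ks = sorted(ens)
    prof = pd.DataFrame({"k": ks, "mean_s": [1.0 / k for k in ks]})
    res = trend_test(prof, ens, {n: 1.0 for n in g.nodes()})
    assert res.statistic == pytest.approx(-1.0)
    assert res.direction == "decreasing"


def test_trend_constant_quantity_is_none(toy_graph):
    g, decomp, ens = toy_graph
    prof = pd.DataFrame({"k": sorted(ens), "mean_s": 2.0})
    res = trend_test(prof, ens, {n: 2.0 for n in g.nodes()})
    assert res.direction == "none"
    assert res.p_empirical == 1.0


def test_trend_pvalues_calibrated_under_permutation(toy_graph):
    # per-core values permuted across core orders: p should be roughly uniform
    g, decomp, ens = toy_graph
    rng = np.random.default_rng(2)
    nodes = list(g.nodes())
    attr = dict(zip(nodes, rng.normal(size=len(nodes))))
    base_vals = rng.normal(size=len(ens))
    pvals = []
    for _ in range(60):
        prof = pd.DataFrame({"k": sorted(ens), "mean_s": rng.permutation(base_vals)})
        pvals.append(trend_test(prof, ens, attr).p_empirical)
    pvals = np.asarray(pvals)
    assert 0.3 < pvals.mean() < 0.7
    assert (pvals <= 0.1).mean() < 0.3


def _decomp(coreness):
    return CoreDecomposition(coreness=coreness)


def _fp(acc, length_bp):
    return DomainFootprint(acc, [("P", [("1", 1, length_bp)])])


def test_chi_square_zero_when_observed_equals_expected():
    decomp = _decomp({"A": 1, "B": 2})
    fps = {"A": _fp("A", 100), "B": _fp("B", 100)}
    gof = chi_square_cores(decomp, fps, {"A": 50, "B": 50})
    assert gof.statistic == pytest.approx(0.0)
    assert gof.p_value == pytest.approx(1.0)


def test_chi_square_hand_computed_example():
    decomp = _decomp({"A": 1, "B": 2})
    fps = {"A": _fp("A", 100), "B": _fp("B", 100)}
    gof = chi_square_cores(decomp, fps, {"A": 40, "B": 60})
    assert gof.statistic == pytest.approx(4.0)  # (10^2/50)*2
    assert gof.dof == 1
    assert np.isclose(gof.expected.sum(), gof.observed.sum())


def test_chi_square_pools_small_shells():
    decomp = _decomp({"A": 1, "B": 2, "C": 3})
    fps = {"A": _fp("A", 1000), "B": _fp("B", 1000), "C": _fp("C", 1)}
    gof = chi_square_cores(decomp, fps, {"A": 30, "B": 30, "C": 0})
    assert len(gof.shells) == 2  # C's shell pooled into B's
    assert np.isclose(gof.expected.sum(), gof.observed.sum())


def test_chi_square_calibrated_without_depletion():
    """Under beta = 0 the GOF p-values are approximately uniform."""
    pvals = []
    for seed in range(30):
        cfg = SimConfig(
            n_domains=60, n_proteins=150, baseline_rate=0.02,
            core_depletion_beta=0.0, n_hot_domains=0, n_samples=5, seed=1000 + seed,
        )
        ds = simulate_dataset(cfg)
        models = {m.protein_id: m for m in ds.models}
        fps = mapping.build_footprints(network.filter_hits(ds.hits), models)
        counts = mapping.map_mutations(mapping.filter_mutations(ds.mutations), fps)
        gof = chi_square_cores(ds.decomposition, fps, counts.counts)
        pvals.append(gof.p_value)
    pvals = np.asarray(pvals)
    assert sps.kstest(pvals, "uniform").pvalue > 0.01
    assert (pvals < 0.05).mean() <= 0.2  # rejection near the nominal rate


def test_end_to_end_core_profile_decreases_with_depletion(default_analysis):
    """Planted depletion shows up as a monotone drop of mean score with k."""
    from dcnmut import stats as dstats
    from dcnmut.profile import profile_cores

    a = default_analysis
    table = a["stats"]
    significant = set(dstats.call_significant(table))
    cons = {l.domain_acc: l.conserved for l in a["dataset"].conservation}
    prof = profile_cores(a["decomp"], a["ensembles"], table, cons, significant)
    rho = sps.spearmanr(prof["k"], prof["mean_s"]).statistic
    assert rho < -0.9
    # conservation gradient planted by the generator is recovered
    rho_c = sps.spearmanr(prof["k"], prof["pct_conserved"]).statistic
    assert rho_c > 0.9
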