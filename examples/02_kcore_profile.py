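"""Decompose a synthetic network into nested k-cores and profile conservation.

The generator plants a conservation gradient: the probability that a domain
is labeled conserved rises with its core order.  The profile compares the
empirical percentage per nested core with size-matched random node sets.
"""

from dcnmut import SimConfig, core_attribute_profile, decompose, largest_component, random_ensembles, simulate_dataset

ds = simulate_dataset(SimConfig(n_domains=300, n_proteins=700, seed=42))
main = largest_component(ds.dcn)
decomp = decompose(main)
print(f"main component: {main.number_of_nodes()} domains, {main.number_of_edges()} edges")
print(f"nested cores: k = 1..{decomp.k_max}")

ensembles = random_ensembles(main, decomp, n_replicates=100, seed=43)
conserved = {l.domain_acc: l.conserved for l in ds.conservation}
prof = core_attribute_profile(decomp, ensembles, {n: conserved.get(n, False) for n in main})

print("\nper-core conservation (statistic = % conserved in the nested k-core;")
print("ensemble columns show the same % over random size-matched node sets):")
print(prof.round(3).to_string(index=False))
# the empirical percentage climbs with k while the ensemble stays flat:
# deep-core domains are systematically more conserved than random sets.
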