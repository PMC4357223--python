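# dcnmut

Somatic mutation burden across the core–periphery structure of protein
domain co-occurrence networks.

## The problem

Most cancer-genomics driver searches are gene-centric, but selection acts on
functional units: protein domains. A **domain co-occurrence network (DCN)**
has one node per Pfam domain family and an edge between two domains whenever
they occur together in at least one protein, so every multi-domain protein
contributes a clique. The **k-core decomposition** of this network (the
maximal subgraph in which every node keeps ≥ k neighbors, obtained by
iterative pruning) exposes a core–periphery hierarchy: a small set of deeply
embedded, promiscuous domains versus a large periphery. `dcnmut` asks how
somatic mutation burden is distributed over that hierarchy — are the
network's inner-core domains mutation-depleted relative to the periphery,
and where do the significantly mutated domains live?

The package is aimed at computational biologists who want this analysis as a
reusable, tested library rather than a one-off script collection.

## The method

For each domain *d* with mutation count *m_d* and cumulative genomic
footprint *L_d* (bp summed over every occurrence of the domain in the
proteome):

- normalized score  s_d = m_d / L_d  (mutations per bp),
- simplex probability  p_d = s_d / Σ_d′ s_d′,
- Bernoulli signal-to-noise statistic  z_d = p_d / √(p_d (1 − p_d)),
- local false discovery rate  lfdr(z) = π₀ f₀(z) / f(z), with the marginal
  f fitted by Poisson regression of histogram counts on a polynomial basis
  and the empirical null f₀ = N(δ₀, σ₀) estimated by central matching;
  domains with lfdr < 0.1 are called significantly mutated.

Mutations reach domains through strand-aware conversion of peptide
coordinates to genomic CDS positions (residue *r* occupies CDS nucleotides
3(r−1)+1 … 3r); Silent and RNA records are filtered out first. Per-core
statistics (mean s, % conserved, % significant over each nested k-core) are
calibrated against ensembles of 100 random node sets matched in size to each
empirical k-core, giving ensemble z-scores and add-one empirical p-values, a
randomization trend test (Spearman of the per-core statistic against k), and
a chi-square goodness of fit of observed vs footprint-expected mutations
across core shells.

A first-class synthetic-data module generates proteomes, gene models,
conservation labels, and mutation sets with a planted multiplicative
depletion of mutation rate with coreness (rate = baseline · e^(−β·k)) plus a
few elevated-rate "hot" domains, so every stage is testable without external
data. See `docs/methods.md` for model details and assumptions.

## Worked example

`examples/03_map_and_score.py` runs the scoring chain on one synthetic study
(default scale: ~1,300 domain families in use, 4,000 proteins, ~50k
mutations, depletion β = 0.15, 25 planted hot domains at 10× baseline):

```
mutations: 52147 total, 36544 after removing Silent/RNA
mapped into domain footprints: 15730 (43.0%)

empirical null: pi0 = 0.942, mean = 0.0231, sd = 0.0077
significant at lfdr < 0.1: 26 domains
planted 10x-rate domains recovered: 25/25

top domains (s = mutations per bp of cumulative footprint):
domain_acc   m    L       s       z  lfdr
   PF00519  81  327 0.24771 0.11442   0.0
   PF01090 140  588 0.23810 0.11215   0.0
   ...
```

Reading: 30% of the raw records are Silent/RNA and are dropped; 43% of the
rest fall inside annotated domain space. The empirical null absorbs the bulk
of (small, strictly positive) z values; 26 domains clear lfdr < 0.1,
including all 25 planted hot domains — their normalized rates (~0.22–0.25
mutations/bp) sit an order of magnitude above the depleted bulk.

Other examples: `01_build_network.py` (clique construction and network
statistics), `02_kcore_profile.py` (nested cores and the conservation
gradient vs randomized ensembles), `04_full_pipeline.py` (the stage
orchestrator). The same pipeline is scriptable from a shell:

```bash
dcnmut run-all --seed 11 --outdir demo_out        # simulates inputs
dcnmut run-all --config run.yaml --outdir results # your own input files
```

Stages (`simulate`, `build`, `decompose`, `map`, `stats`, `profile`) can be
run individually; inputs are PfamScan tabular hits, a gene-model TSV, MAF
mutation tables (one per condition label), and an optional conservation TSV.

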