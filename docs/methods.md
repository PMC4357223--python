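# Methods

This note documents the models, estimators, and design choices behind
`dcnmut`, in the order the pipeline runs them.

## Network construction

Domain hits are PfamScan-style records in peptide coordinates; only the
alignment bounds are used, and hits with e-value > 0.01 are discarded (the
threshold is the `e_value_max` parameter; 0.01 is the conventional inclusion
cutoff for confident Pfam assignments). For every protein the set of
*distinct* surviving domain accessions forms a clique; repeated occurrences
of a domain in one protein create a node but never a self-loop. Edges are
unweighted in all downstream analysis because the k-core machinery is
degree-based; the number of supporting proteins is kept as an edge attribute
for export. Analysis runs on the largest connected component (ties broken by
the lexicographically smallest member accession, for determinism); isolated
domains are retained up to that step so the component choice is explicit.

## k-core decomposition and randomized ensembles

Coreness is computed by the linear-time bucket (Batagelj–Zavrsnik) algorithm,
which is exactly equivalent to iterative pruning: remove all nodes of degree
< k, re-examine, repeat, for k = 1, 2, …. The test suite checks the
implementation against an independent naive-pruning oracle and against
`networkx.core_number` on ensembles of random graphs, plus the structural
invariants (nestedness, internal degree ≥ k, monotonicity under edge
addition).

Statistical calibration of per-core quantities uses membership
randomization, not topology rewiring: for each core order k, ensembles of
node sets of size N_k (the empirical nested k-core size) are drawn uniformly
without replacement from the analyzed component's node set, 100 replicates
by default. Replicate index i is aligned across core orders, so the i-th
draws jointly act as one random network realization. For each k the
empirical statistic (mean for real attributes, percentage for boolean) is
compared with the replicate distribution, yielding an ensemble z-score and
an add-one empirical p-value, (1 + #{at least as extreme}) / (1 + R) — the
add-one form avoids p = 0 at 100 replicates. "At least as extreme" is
two-sided by default with one-sided options; the choice is exposed because
no convention is canonical here.

Profiles are computed over **nested cores** (coreness ≥ k). The chi-square
test below instead uses **shells** (coreness = k) because goodness of fit
needs disjoint categories; shell-based profiles are available behind a flag.

## Coordinate conversion

All internal coordinates are 1-based and inclusive, matching the MAF and
PfamScan dialects; BED export is the single place the convention changes.
Residue r occupies CDS nucleotides 3(r−1)+1 … 3r, with CDS nucleotide order
following translation: ascending genomic position on '+', descending on '−'.
The converter emits one genomic interval per overlapped CDS block, ascending;
the summed length is always 3 × residue count. A per-base enumeration oracle
and a residue round-trip property pin the arithmetic on both strands and on
multi-block models.

## Mutation filtering and assignment

Silent and RNA classifications are removed (case-insensitively) before any
counting, mirroring the assumption that they are unlikely to drive disease.
A mutation is assigned to domain d if its genomic position lies in any
interval of any occurrence of d (inclusive bounds). A position inside two
*different* overlapping domains increments both counts but contributes once
to the mapped total; inside two occurrences of the *same* domain it counts
once. This is the only reading that keeps per-domain counts and the mapped
percentage simultaneously consistent; it is a documented assumption, since
overlapping-domain bookkeeping is not otherwise determined. Lookup uses
per-chromosome interval trees, contractually identical to a linear scan
(enforced by test).

## Scoring and the empirical-null local FDR

s_d = m_d / L_d with L_d the cumulative genomic footprint in bp (3 bp per
residue summed over all occurrences; using residues instead would change L
by the constant 3 and leave p and z untouched). p_d = s_d / Σ s_d′ puts the
scores on a probability simplex — the only reading under which the values
act as a "success probability" — and z_d = p_d / √(p_d(1−p_d)) = √odds is a
strictly monotone transform, so the pre-lfdr ranking is exactly the
normalized-rate ranking.

These z values are small and strictly positive, nothing like a standard
normal; significance therefore rests on an **empirical null**. The marginal
density f is fitted by Poisson regression of histogram counts (120 equal
bins, degree-7 polynomial basis, both configurable) and the null
πo·N(δ₀, σ₀) by central matching: a quadratic is fitted to log f over the
central bins (between the 0.10 and 0.90 quantiles of z) and δ₀, σ₀, π₀ are
read off its coefficients. The 0.10–0.90 window is wider than the classical
quarter-quantile choice; it halves the variance of the quadratic fit and
keeps pure-null π₀ estimates near 1 at n ≈ 5000 while remaining dominated by
the null component when a small (~5%) non-null fraction is present. lfdr(z)
= clip(π₀ f₀(z)/f(z), 0, 1), interpolated between bin midpoints; π₀ itself
is stored unclipped (pure-null estimates can exceed 1 slightly, which is
informative). A `theoretical` null option (N(0,1), π₀ from f(0)) and a
log-transform dialect (fit on log z for strongly multiplicative score
distributions; zero-count domains get lfdr 1) are exposed. The fit refuses
fewer than 200 finite z values — below that a binned density estimate is not
trustworthy and exact small-sample methods should be used instead.

Domains with lfdr strictly below 0.1 are called significant, ordered by lfdr
then z then accession. When several mutation sets (conditions) are analyzed,
each gets its own stats table (and its own lfdr fit), and the overlap module
reports all Venn region cardinalities plus the full intersection.

## Per-core analyses

`profile_cores` joins everything: mean s, % conserved, % significant per
nested core, each against its randomized ensemble. The trend test computes
the Spearman correlation between core order and a profiled quantity and
compares it with the same statistic on each joint random replicate; note
that nested-core means are mechanically smoothed across k (cores share
members), so this p-value is specific to the profile-versus-random-sets
comparison, not a generic trend test on exchangeable data.

The chi-square goodness of fit distributes the total mapped assignments over
shells in proportion to each shell's cumulative footprint length — the null
implied by the length normalization itself, since no other expected-count
construction is determined — and pools shells with expected < 5 into the
next-lower core order (the innermost shells are the smallest). Degrees of
freedom are categories − 1.

## Synthetic data generator

The generator emulates the inputs the analysis assumes, not any particular
genome:

- **Domain usage** is a bounded Zipf law over `n_domains` families
  (exponent 1.0 by default), which reproduces a scale-free-like degree
  structure with a deep nested core. Each family has one fixed length drawn
  from 30–120 aa.
- **Proteins** carry 1–4 domains at non-overlapping peptide positions with
  random linkers and flanks; **gene models** place 3×(protein aa) of CDS on
  1–5 blocks with intronic gaps, on a uniformly random strand, genes
  non-overlapping along 23 synthetic chromosomes.
- **Hit quality**: e-values ≤ 0.01 except a 5% injected fraction in
  (0.01, 1] to exercise the inclusion filter; those footprints fall back to
  background mutation rate, since the analysis never sees them as domains.
- **Mutations**: per-region Poisson counts with rate
  baseline · e^(−β·coreness) inside domain footprints (baseline
  0.03 mutations/bp, β = 0.15) and baseline in the rest of the CDS;
  positions uniform within the region; 25% Silent and 5% RNA labels assigned
  independently of position so filtering thins the process uniformly;
  single-nucleotide substitutions only (the analysis uses only position and
  classification).
- **Hot domains**: 25 domains at 10× baseline (overriding, not multiplying,
  the depletion), drawn from families with ≥ 300 bp cumulative footprint and
  coreness at least 3 below the maximum. The core exclusion mirrors the
  modeled biology — deep-core domains are conserved and depleted, so
  driver-like elevated domains live toward the periphery — and the footprint
  floor keeps planted signals detectable in principle rather than drowned in
  Poisson noise.
- **Conservation labels**: Bernoulli with P(conserved | k) =
  clamp(0.2 + 0.08·k, 0, 1).

Default scale: 1,500 nominal families (~1,300 in use), 4,000 proteins, ~3
Mbp of CDS, ~50,000 mutations — a deliberately compressed analogue of a
proteome-wide study, sized so the full chain (including 100-replicate
ensembles) runs in seconds. What passing tests show is that the pipeline
recovers planted structure of realistic shape and strength; they do not
certify behavior on real data, which additionally has non-uniform mutational
signatures, overlapping genes and isoforms, assembly-specific coordinate
quirks, and domain families whose biological rates are not exchangeable
with the simulated ones.

Everything is a deterministic function of the seed: the generator derives
independent streams for proteome, mutations, and labels from
(seed, stream-index) pairs, and the pipeline fans a single global seed out
to stages by fixed offsets, so reruns are byte-identical.

## Degenerate inputs and numerical choices

- Readers reject invariant violations (unsorted CDS blocks, duplicate
  conservation rows, non-numeric fields) rather than repairing them.
- `z_scores` errors on all-zero scores and on the single-domain p = 1 case.
- Ensemble z-scores treat replicate spreads below a relative floor of 1e-9
  as zero to avoid dividing observed−mean ≈ 0 by floating-point noise when
  every replicate is the identical (full) node set.
- Component and output-table orderings are lexicographic throughout, so
  equal inputs give byte-identical artifacts.

## Known limitations

- The expected-count construction of the chi-square test and the
  overlapping-domain double-counting rule are assumptions, stated above.
- The lfdr fit depends on the empirical null; with very few domains or
  strongly discrete counts, binned density estimation is the weakest link.
- The membership-randomization null keeps topology fixed; it does not test
  against degree-preserving rewired networks.
- One protein per gene, one transcript; no isoform logic, no liftover, no
  consequence re-annotation.
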