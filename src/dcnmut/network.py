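"""Domain co-occurrence network (DCN) construction and descriptive statistics.

A DCN is an undirected simple graph whose nodes are Pfam domain accessions.
Two domains are joined by an edge when they co-occur in at least one protein,
so each multi-domain protein contributes a clique.  Edges are unweighted for
all downstream analysis; the number of supporting proteins is retained on
each edge as the ``support`` attribute for export only.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from typing import Dict, Iterable, List, Sequence

import networkx as nx
import pandas as pd

from .types import DomainHit

logger = logging.getLogger(__name__)

#: e-value threshold above which domain hits are discarded
DEFAULT_EVALUE_MAX = 0.01


def filter_hits(hits: Sequence[DomainHit], e_value_max: float = DEFAULT_EVALUE_MAX) -> List[DomainHit]:
    """Keep hits with e-value <= ``e_value_max`` (the network's inclusion rule)."""
    kept = [h for h in hits if h.e_value <= e_value_max]
    if len(kept) < len(hits):
        logger.info("discarded %d/%d hits with e-value > %g", len(hits) - len(kept), len(hits), e_value_max)
    return kept


def build_dcn(hits: Sequence[DomainHit], e_value_max: float = DEFAULT_EVALUE_MAX) -> nx.Graph:
    """Build the DCN from domain hits.

    Hits with e-value above the threshold are discarded.  For each protein the
    set of *distinct* surviving domain accessions forms a clique; repeated
    occurrences of one domain within a protein yield a node but never a
    self-loop.  ``support`` on each edge counts proteins (not hit pairs) in
    which the pair co-occurs.
    """
    if not hits:
        raise ValueError("build_dcn: no domain hits supplied")
    kept = filter_hits(hits, e_value_max)
    by_protein: Dict[str, set] = defaultdict(set)
    for h in kept:
        by_protein[h.protein_id].add(h.domain_acc)

    g = nx.Graph()
    support: Counter = Counter()
    for domains in by_protein.values():
        g.add_nodes_from(domains)
        for u, v in itertools.combinations(sorted(domains), 2):
            support[(u, v)] += 1
    for (u, v), count in support.items():
        g.add_edge(u, v, support=count)
    if g.number_of_nodes() == 0:
        logger.warning("build_dcn: all %d hits filtered out at e-value <= %g; empty graph", len(hits), e_value_max)
    return g


def largest_component(dcn: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Ties on component size are broken deterministically by the
    lexicographically smallest member accession.
    """
    if dcn.number_of_nodes() == 0:
        raise ValueError("largest_component: empty graph")
    best = min(nx.connected_components(dcn), key=lambda c: (-len(c), min(c)))
    return dcn.subgraph(best).copy()


def network_stats(dcn: nx.Graph) -> Dict[str, pd.DataFrame]:
    """Descriptive statistics: degree distribution, clustering, path lengths.

    Returns a dict of tidy DataFrames:

    ``degree_distribution``
        degree, n_nodes.
    ``clustering``
        node, degree, clustering coefficient.
    ``clustering_by_degree``
        degree, mean clustering coefficient (hierarchical-modularity plot).
    ``shortest_path_histogram``
        distance, n_pairs — unordered node pairs, computed within components.
    """
    degrees = dict(dcn.degree())
    deg_counts = Counter(degrees.values())
    degree_distribution = pd.DataFrame(
        sorted(deg_counts.items()), columns=["degree", "n_nodes"]
    )

    clust = nx.clustering(dcn)
    clustering = pd.DataFrame(
        [(n, degrees[n], clust[n]) for n in sorted(dcn.nodes())],
        columns=["node", "degree", "clustering"],
    )
    clustering_by_degree = (
        clustering.groupby("degree", as_index=False)["clustering"].mean()
        .rename(columns={"clustering": "mean_clustering"})
    )

    dist_counts: Counter = Counter()
    for source, lengths in nx.all_pairs_shortest_path_length(dcn):
        for target, d in lengths.items():
            if d > 0 and source < target:
                dist_counts[d] += 1
    shortest_path_histogram = pd.DataFrame(
        sorted(dist_counts.items()), columns=["distance", "n_pairs"]
    )
    return {
        "degree_distribution": degree_distribution,
        "clustering": clustering,
        "clustering_by_degree": clustering_by_degree,
        "shortest_path_histogram": shortest_path_histogram,
    }
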