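"""k-core decomposition and size-matched randomized core ensembles.

The k-core of a graph is the maximal subgraph in which every node has at
least k neighbors within the subgraph; it is obtained by iteratively pruning
nodes of degree < k.  The *coreness* (core order) of a node is the largest k
for which it survives, and the k-cores are nested.  Statistical significance
of per-core attribute profiles is assessed against ensembles of random node
sets matched in size to each empirical k-core (membership randomization, not
topology rewiring).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Hashable, List, Mapping, Optional, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CoreDecomposition:
    """Coreness per node plus nested k-core membership."""

    coreness: Dict[Hashable, int]

    @property
    def k_max(self) -> int:
        return max(self.coreness.values()) if self.coreness else 0

    def core_members(self, k: int) -> Set[Hashable]:
        """Nodes of the nested k-core: coreness >= k (all nodes for k <= 0)."""
        return {n for n, c in self.coreness.items() if c >= k}

    def shell_members(self, k: int) -> Set[Hashable]:
        """Nodes with coreness exactly k (shells partition the node set)."""
        return {n for n, c in self.coreness.items() if c == k}

    def core_sizes(self) -> Dict[int, int]:
        return {k: len(self.core_members(k)) for k in range(1, self.k_max + 1)}


def decompose(dcn: nx.Graph) -> CoreDecomposition:
    """Compute coreness for every node by the linear-time bucket algorithm.

    Equivalent to exhaustive iterative pruning: repeatedly remove the node of
    minimum remaining degree; when it is removed at degree d, its coreness is
    max(d, coreness of the previously removed node).
    """
    if dcn.number_of_nodes() == 0:
        raise ValueError("decompose: empty graph")
    nodes = sorted(dcn.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    degree = np.array([dcn.degree(v) for v in nodes], dtype=np.int64)
    max_deg = int(degree.max())

    # bucket sort nodes by degree
    bin_start = np.zeros(max_deg + 2, dtype=np.int64)
    for d in degree:
        bin_start[d + 1] += 1
    bin_start = np.cumsum(bin_start)
    pos = np.empty(n, dtype=np.int64)
    vert = np.empty(n, dtype=np.int64)
    fill = bin_start[:-1].copy()
    for i in range(n):
        d = degree[i]
        pos[i] = fill[d]
        vert[pos[i]] = i
        fill[d] += 1

    adjacency = [np.fromiter((index[w] for w in dcn.neighbors(v)), dtype=np.int64) for v in nodes]
    core = degree.copy()
    bin_ptr = bin_start[:-1].copy()
    for i in range(n):
        v = vert[i]
        for u in adjacency[v]:
            if core[u] > core[v]:
                # move u one bucket down: swap with the first node of its bucket
                du = core[u]
                pu, pw = pos[u], bin_ptr[du]
                w = vert[pw]
                if u != w:
                    vert[pu], vert[pw] = w, u
                    pos[u], pos[w] = pw, pu
                bin_ptr[du] += 1
                core[u] -= 1
    return CoreDecomposition(coreness={nodes[i]: int(core[i]) for i in range(n)})


@dataclass
class RandomCoreEnsemble:
    """Size-matched random node sets standing in for one empirical k-core."""

    k: int
    n_k: int
    replicates: List[Set[Hashable]]

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def random_ensembles(
    dcn: nx.Graph,
    decomposition: CoreDecomposition,
    n_replicates: int = 100,
    seed: int = 0,
) -> Dict[int, RandomCoreEnsemble]:
    """Uniform membership-randomization null for every core order.

    For each k in 1..k_max, draws ``n_replicates`` node sets of size
    N_k = |core_members(k)| uniformly without replacement from the analyzed
    graph's full node set.  Replicate index i is aligned across core orders so
    that the i-th draws jointly form one "random DCN" realization.
    """
    rng = np.random.default_rng(seed)
    universe = np.array(sorted(dcn.nodes()), dtype=object)
    out: Dict[int, RandomCoreEnsemble] = {}
    for k in range(1, decomposition.k_max + 1):
        n_k = len(decomposition.core_members(k))
        assert n_k <= len(universe)
        reps = [set(rng.choice(universe, size=n_k, replace=False)) for _ in range(n_replicates)]
        out[k] = RandomCoreEnsemble(k=k, n_k=n_k, replicates=reps)
    return out


def _statistic(values: np.ndarray, is_boolean: bool) -> float:
    if is_boolean:
        return 100.0 * float(np.mean(values))
    return float(np.mean(values))


def core_attribute_profile(
    decomposition: CoreDecomposition,
    ensembles: Mapping[int, RandomCoreEnsemble],
    attribute: Mapping[Hashable, float],
    missing_default: float = 0.0,
    alternative: str = "two-sided",
    nested: bool = True,
) -> pd.DataFrame:
    """Per-core attribute statistic with randomized-ensemble calibration.

    For each core order k the empirical statistic (mean for real-valued
    attributes, percentage true for boolean) is computed over the nested
    k-core members (or the shell when ``nested=False``) and compared with the
    same statistic over each size-matched random replicate.  The empirical
    p-value uses the add-one estimator (1 + #at-least-as-extreme) / (1 + R).

    Columns: k, N_k, statistic, ensemble_mean, ensemble_sd, z, p_empirical.
    """
    if alternative not in {"two-sided", "less", "greater"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    values = dict(attribute)
    is_boolean = bool(values) and all(isinstance(v, (bool, np.bool_)) for v in values.values())
    missing = [n for n in decomposition.coreness if n not in values]
    if missing:
        logger.info("attribute missing for %d nodes; using default %r", len(missing), missing_default)
    get = lambda n: float(values.get(n, missing_default))

    rows = []
    for k in range(1, decomposition.k_max + 1):
        members = decomposition.core_members(k) if nested else decomposition.shell_members(k)
        if not members:
            logger.warning("core order %d has no members; row omitted", k)
            continue
        obs = _statistic(np.array([get(n) for n in members]), is_boolean)
        ens = ensembles.get(k)
        if ens is None:
            rows.append((k, len(members), obs, np.nan, np.nan, np.nan, np.nan))
            continue
        rep_stats = np.array(
            [_statistic(np.array([get(n) for n in rep]), is_boolean) for rep in ens.replicates]
        )
        mean, sd = float(rep_stats.mean()), float(rep_stats.std(ddof=1))
        # guard against pure floating-point spread when every replicate is identical
        sd_floor = 1e-9 * max(1.0, abs(mean))
        if sd > sd_floor:
            zval = (obs - mean) / sd
        elif np.isclose(obs, mean, rtol=1e-9, atol=1e-12):
            zval = 0.0
        else:
            zval = np.inf * np.sign(obs - mean)
        if alternative == "two-sided":
            extreme = np.abs(rep_stats - mean) >= abs(obs - mean) - 1e-12
        elif alternative == "greater":
            extreme = rep_stats >= obs - 1e-12
        else:
            extreme = rep_stats <= obs + 1e-12
        p_emp = (1 + int(extreme.sum())) / (1 + len(rep_stats))
        rows.append((k, len(members), obs, mean, sd, zval, p_emp))
    return pd.DataFrame(
        rows, columns=["k", "N_k", "statistic", "ensemble_mean", "ensemble_sd", "z", "p_empirical"]
    )
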