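"""Per-core-order profiles of mutation burden, conservation, and significance.

Combines the k-core decomposition, the randomized core ensembles, per-domain
mutation statistics, and conservation labels into the pipeline's headline
analyses: the mutation-burden and conservation trends across nested cores,
the percentage of significantly mutated domains per core, a randomization
trend test, and a chi-square goodness-of-fit of observed vs
footprint-expected mutations across core shells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Hashable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kcore import CoreDecomposition, RandomCoreEnsemble, core_attribute_profile
from .mapping import DomainFootprint

logger = logging.getLogger(__name__)


def profile_cores(
    decomposition: CoreDecomposition,
    ensembles: Mapping[int, RandomCoreEnsemble],
    stats: pd.DataFrame,
    conservation: Optional[Mapping[str, bool]] = None,
    significant: Optional[Set[str]] = None,
    nested: bool = True,
) -> pd.DataFrame:
    """One row per core order with each profiled quantity and its null.

    Quantities: mean normalized mutation score ``mean_s``, percentage of
    conserved domains ``pct_conserved``, percentage of significantly mutated
    domains ``pct_significant``; each carries ensemble mean/sd, z, and the
    add-one empirical p.  Domains absent from ``stats`` contribute s = 0.
    """
    universe = set(decomposition.coreness)
    s_map = dict(zip(stats["domain_acc"], stats["s"]))
    if not universe & set(s_map):
        raise ValueError("profile_cores: stats table shares no domains with the decomposition")
    missing = len(universe - set(s_map))
    if missing:
        logger.info("%d network domains absent from stats; treated as s = 0", missing)

    quantities: Dict[str, Mapping[Hashable, object]] = {
        "mean_s": {n: float(s_map.get(n, 0.0)) for n in universe},
    }
    if conservation is not None:
        quantities["pct_conserved"] = {n: bool(conservation.get(n, False)) for n in universe}
    if significant is not None:
        quantities["pct_significant"] = {n: bool(n in significant) for n in universe}

    merged: Optional[pd.DataFrame] = None
    for name, attr in quantities.items():
        prof = core_attribute_profile(decomposition, ensembles, attr, nested=nested)
        prof = prof.rename(
            columns={
                "statistic": name,
                "ensemble_mean": f"{name}_ens_mean",
                "ensemble_sd": f"{name}_ens_sd",
                "z": f"{name}_z",
                "p_empirical": f"{name}_p_empirical",
            }
        )
        merged = prof if merged is None else merged.merge(prof, on=["k", "N_k"])
    return merged


@dataclass
class TrendTestResult:
    """Spearman trend of a per-core statistic against core order."""

    statistic: float
    p_empirical: float
    direction: str  # decreasing / increasing / none
    null_statistics: np.ndarray


def trend_test(
    profile: pd.DataFrame,
    ensembles: Mapping[int, RandomCoreEnsemble],
    attribute: Mapping[Hashable, float],
    quantity: str = "mean_s",
    alternative: str = "two-sided",
) -> TrendTestResult:
    """Randomization test for a monotone trend of a profiled quantity.

    The observed statistic is the Spearman correlation between core order k
    and ``profile[quantity]``.  The null recomputes the per-core mean of the
    node ``attribute`` on each replicate of the size-matched random ensembles
    (replicate i joins the i-th random set at every k, i.e. one "random DCN"
    per replicate).  p is the add-one empirical p-value.
    """
    rows = profile[profile["k"].isin(ensembles)]
    ks = rows["k"].tolist()
    if len(ks) < 3:
        raise ValueError("trend_test: need at least 3 core orders")
    get = lambda n: float(attribute.get(n, 0.0))

    def percore_means(sets: Sequence[Set[Hashable]]) -> np.ndarray:
        return np.array([np.mean([get(n) for n in s]) if s else np.nan for s in sets])

    obs_vals = rows[quantity].to_numpy(dtype=float)
    if np.nanstd(obs_vals) < 1e-15:
        return TrendTestResult(np.nan, 1.0, "none", np.array([]))
    rho_obs = sps.spearmanr(ks, obs_vals).statistic

    n_rep = min(e.n_replicates for e in ensembles.values())
    null = np.empty(n_rep)
    for i in range(n_rep):
        vals = percore_means([ensembles[k].replicates[i] for k in ks])
        if np.nanstd(vals) < 1e-15:
            null[i] = 0.0
        else:
            null[i] = sps.spearmanr(ks, vals).statistic
    if alternative == "two-sided":
        extreme = np.abs(null) >= abs(rho_obs) - 1e-12
    elif alternative == "less":
        extreme = null <= rho_obs + 1e-12
    elif alternative == "greater":
        extreme = null >= rho_obs - 1e-12
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + int(extreme.sum())) / (1 + n_rep)
    direction = "decreasing" if rho_obs < 0 else "increasing" if rho_obs > 0 else "none"
    return TrendTestResult(float(rho_obs), float(p), direction, null)


@dataclass
class GofResult:
    """Chi-square goodness of fit of observed vs expected mutations per shell."""

    shells: List[int]  # core order of each (possibly pooled) category
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    dof: int
    p_value: float


def chi_square_cores(
    decomposition: CoreDecomposition,
    footprints: Mapping[str, DomainFootprint],
    counts: Mapping[str, int],
    min_expected: float = 5.0,
) -> GofResult:
    """Test whether mutations fall across core shells in proportion to footprint.

    Categories are shells (coreness exactly k), which partition the domains;
    ``expected_k`` distributes the total mapped assignments over shells in
    proportion to each shell's cumulative footprint length — the null implied
    by the length normalization itself.  Shells with expected < ``min_expected``
    are pooled with the next-lower core order.  df = categories - 1.
    """
    members = set(decomposition.coreness) & set(footprints)
    if not members:
        raise ValueError("chi_square_cores: no domain is in both the network and the footprints")
    shells = sorted({decomposition.coreness[d] for d in members})
    obs, lens = [], []
    for k in shells:
        doms = [d for d in members if decomposition.coreness[d] == k]
        obs.append(float(sum(counts.get(d, 0) for d in doms)))
        lens.append(float(sum(footprints[d].cumulative_length for d in doms)))
    obs_arr, len_arr = np.array(obs), np.array(lens)
    total = obs_arr.sum()
    exp_arr = total * len_arr / len_arr.sum()

    # pool small-expected shells downward (innermost cores are the smallest)
    ks: List[int] = list(shells)
    i = len(ks) - 1
    while i > 0 and len(ks) > 2:
        if exp_arr[i] < min_expected:
            exp_arr[i - 1] += exp_arr[i]
            obs_arr[i - 1] += obs_arr[i]
            exp_arr = np.delete(exp_arr, i)
            obs_arr = np.delete(obs_arr, i)
            logger.info("pooled shell k=%d into k=%d (expected < %g)", ks[i], ks[i - 1], min_expected)
            del ks[i]
        i -= 1
    # a small lowest shell pools upward
    while len(ks) > 2 and exp_arr[0] < min_expected:
        exp_arr[1] += exp_arr[0]
        obs_arr[1] += obs_arr[0]
        exp_arr, obs_arr = np.delete(exp_arr, 0), np.delete(obs_arr, 0)
        del ks[0]
    if np.any(exp_arr == 0):
        raise ValueError("chi_square_cores: zero expected count after pooling")
    if len(ks) < 2:
        raise ValueError("chi_square_cores: fewer than 2 categories after pooling")
    stat, p = sps.chisquare(obs_arr, exp_arr)
    return GofResult(
        shells=ks,
        observed=obs_arr,
        expected=exp_arr,
        statistic=float(stat),
        dof=len(ks) - 1,
        p_value=float(p),
    )


# --------------------------------------------------------------------------
# Figure analogues (regenerable from the profile TSVs alone)
# --------------------------------------------------------------------------


def plot_core_profile(profile: pd.DataFrame, quantity: str, path, ylabel: str = "") -> None:
    """Per-core bars of one profiled quantity with ensemble error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(profile["k"], profile[quantity], color="#1f77b4", label="empirical")
    ax.errorbar(
        profile["k"],
        profile[f"{quantity}_ens_mean"],
        yerr=profile[f"{quantity}_ens_sd"],
        fmt="o",
        color="#d62728",
        capsize=3,
        label="randomized ensemble",
    )
    ax.set_xlabel("core order k")
    ax.set_ylabel(ylabel or quantity)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_observed_expected(gof: GofResult, path) -> None:
    """Observed vs footprint-expected mutation counts across core shells."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(gof.shells, gof.observed, "o-", color="#d62728", label="observed")
    ax.plot(gof.shells, gof.expected, "o-", color="#1f77b4", label="expected")
    ax.set_xlabel("core order k (shells, pooled)")
    ax.set_ylabel("mutations")
    ax.set_title(f"chi2 = {gof.statistic:.1f}, df = {gof.dof}, p = {gof.p_value:.3g}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
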