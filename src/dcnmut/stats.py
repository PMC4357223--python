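"""Length-normalized mutation scores, Bernoulli z-statistics, and local FDR.

The per-domain signal is the mutation count m_d divided by the domain's
cumulative genomic footprint L_d (mutations per bp).  Normalized scores are
converted to a probability simplex p_d = s_d / sum(s) and then to the
Bernoulli signal-to-noise statistic

    z_d = p_d / sqrt(p_d (1 - p_d))  (= sqrt(p_d / (1 - p_d)))

which is a strictly monotone transform of the normalized rate.  Significance
is called by the local false discovery rate: the marginal density f(z) is
fitted by Poisson regression of histogram bin counts on a polynomial basis,
the null component pi0 * N(delta0, sigma0) is estimated from the central bulk
of the distribution (central matching), and

    lfdr(z) = clip(pi0 * f0(z) / f(z), 0, 1),

with domains below a threshold (default 0.1) declared significantly mutated.
The empirical null absorbs the fact that these z values are small and
strictly positive rather than standard normal.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .mapping import DomainFootprint, DomainMutationCounts

logger = logging.getLogger(__name__)

DEFAULT_LFDR_THRESHOLD = 0.1


def normalize_counts(
    counts: DomainMutationCounts, footprints: Mapping[str, DomainFootprint]
) -> pd.DataFrame:
    """Per-domain normalized mutation score s_d = m_d / L_d.

    Domains with zero footprint are excluded (and logged); a positive count
    on a zero footprint is a consistency error.
    """
    rows = []
    for acc in sorted(footprints):
        m = counts.counts.get(acc, 0)
        L = footprints[acc].cumulative_length
        if L == 0:
            if m > 0:
                raise ValueError(f"domain {acc}: {m} mutations but zero footprint length")
            logger.info("domain %s has zero footprint; excluded", acc)
            continue
        rows.append((acc, m, L, m / L))
    return pd.DataFrame(rows, columns=["domain_acc", "m", "L", "s"])


def z_scores(s_table: pd.DataFrame) -> pd.DataFrame:
    """Add the simplex probability p_d and Bernoulli signal-to-noise z_d.

    p_d = s_d / sum(s); z_d = p_d / sqrt(p_d (1 - p_d)), with z = 0 when
    m = 0.  The degenerate single-domain case (p = 1) is an error.
    """
    total = s_table["s"].sum()
    if total <= 0:
        raise ValueError("z_scores: all normalized scores are zero")
    out = s_table.copy()
    p = out["s"] / total
    if np.any(p >= 1.0):
        raise ValueError("z_scores: a single domain carries all signal (p = 1); z undefined")
    out["p"] = p
    out["z"] = np.where(p > 0, p / np.sqrt(p * (1.0 - p)), 0.0)
    return out


@dataclass
class LfdrFit:
    """Empirical-null local-FDR fit.

    ``pi0`` is the estimated null proportion (stored unclipped; values
    slightly above 1 can occur on pure-null data), ``delta0``/``sigma0`` the
    empirical null mean and scale, ``bin_mids``/``f``/``f0`` the fitted
    marginal and null densities on the histogram grid.
    """

    pi0: float
    delta0: float
    sigma0: float
    bins: int
    poly_degree: int
    null_method: str
    bin_mids: np.ndarray
    bin_width: float
    f: np.ndarray
    f0: np.ndarray

    def lfdr(self, z: np.ndarray) -> np.ndarray:
        """lfdr at arbitrary z, interpolated between bin midpoints."""
        z = np.asarray(z, dtype=float)
        curve = np.clip(self.pi0 * self.f0 / np.maximum(self.f, 1e-300), 0.0, 1.0)
        return np.interp(z, self.bin_mids, curve)


def fit_lfdr(
    z: Sequence[float],
    bins: int = 120,
    poly_degree: int = 7,
    null_method: str = "central-matching",
    center_pct: float = 0.10,
) -> LfdrFit:
    """Fit the marginal density and empirical null for local-FDR estimation.

    The histogram of z on ``bins`` equal-width bins is smoothed by Poisson
    regression on a degree-``poly_degree`` polynomial of the bin midpoints.
    Under ``central-matching`` a quadratic is fitted to log f over the central
    bins (z between the ``center_pct`` and 1 - ``center_pct`` quantiles),
    giving the null mean, scale, and proportion; under ``theoretical`` the
    null is the standard normal and only pi0 is estimated from f(0).
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("fit_lfdr: non-finite z values")
    n = z.size
    if n < 200:
        raise ValueError(
            f"fit_lfdr: need >= 200 z values for a stable density fit, got {n}; "
            "use an exact small-sample method instead"
        )
    if np.std(z) < 1e-12:
        raise ValueError("fit_lfdr: degenerate z spread (sd ~ 0)")
    if null_method not in {"central-matching", "theoretical"}:
        raise ValueError(f"unknown null_method {null_method!r}")

    counts, edges = np.histogram(z, bins=bins)
    mids = 0.5 * (edges[:-1] + edges[1:])
    width = float(edges[1] - edges[0])

    # Poisson regression of bin counts on a standardized polynomial basis.
    x = (mids - mids.mean()) / mids.std()
    X = np.vander(x, poly_degree + 1, increasing=True)
    glm = sm.GLM(counts, X, family=sm.families.Poisson())
    res = glm.fit(maxiter=200, tol=1e-10)
    mu = np.asarray(res.mu, dtype=float)
    f = mu / (n * width)  # density on the bin grid

    log_f = np.log(np.maximum(f, 1e-300))
    if null_method == "central-matching":
        lo, hi = np.quantile(z, [center_pct, 1.0 - center_pct])
        central = (mids >= lo) & (mids <= hi)
        if central.sum() < 3:
            raise ValueError("fit_lfdr: too few central bins for central matching")
        coeffs = np.polyfit(mids[central], log_f[central], 2)  # c2 z^2 + c1 z + c0
        c2, c1, c0 = coeffs
        if c2 >= 0:
            raise ValueError(
                "fit_lfdr: central log-density is not concave; cannot match a normal null"
            )
        sigma0 = float(np.sqrt(-1.0 / (2.0 * c2)))
        delta0 = float(-c1 / (2.0 * c2))
        log_f_mode = c0 + c1 * delta0 + c2 * delta0**2
        pi0 = float(np.exp(log_f_mode) * sigma0 * np.sqrt(2.0 * np.pi))
    else:
        delta0, sigma0 = 0.0, 1.0
        log_f0_at_0 = np.interp(0.0, mids, log_f)
        pi0 = float(np.exp(log_f0_at_0) * np.sqrt(2.0 * np.pi))

    f0 = sps.norm.pdf(mids, loc=delta0, scale=sigma0)
    fit = LfdrFit(
        pi0=pi0,
        delta0=delta0,
        sigma0=sigma0,
        bins=bins,
        poly_degree=poly_degree,
        null_method=null_method,
        bin_mids=mids,
        bin_width=width,
        f=f,
        f0=f0,
    )
    total_mass = float(np.sum(f) * width)
    if abs(total_mass - 1.0) > 1e-3:
        logger.warning("fitted marginal density integrates to %.6f", total_mass)
    return fit


def compute_domain_stats(
    counts: DomainMutationCounts,
    footprints: Mapping[str, DomainFootprint],
    lfdr_threshold: float = DEFAULT_LFDR_THRESHOLD,
    bins: int = 120,
    poly_degree: int = 7,
    null_method: str = "central-matching",
    log_transform: bool = False,
) -> Tuple[pd.DataFrame, LfdrFit]:
    """Full per-domain statistics table: m, L, s, p, z, lfdr, significant.

    With ``log_transform`` the lfdr fit runs on log z over the domains with
    z > 0 (a dialect option for strongly multiplicative score distributions;
    zero-count domains are assigned lfdr 1).  Ranking by z is preserved either
    way because log is monotone.
    """
    table = z_scores(normalize_counts(counts, footprints))
    if log_transform:
        positive = table["z"] > 0
        fit = fit_lfdr(np.log(table.loc[positive, "z"]), bins=bins,
                       poly_degree=poly_degree, null_method=null_method)
        lfdr_vals = np.ones(len(table))
        lfdr_vals[positive.to_numpy()] = fit.lfdr(np.log(table.loc[positive, "z"]))
    else:
        fit = fit_lfdr(table["z"], bins=bins, poly_degree=poly_degree, null_method=null_method)
        lfdr_vals = fit.lfdr(table["z"])
    table["lfdr"] = lfdr_vals
    table["significant"] = table["lfdr"] < lfdr_threshold
    return table, fit


def call_significant(stats: pd.DataFrame, lfdr_threshold: float = DEFAULT_LFDR_THRESHOLD) -> List[str]:
    """Domains with lfdr strictly below the threshold.

    Sorted by lfdr ascending, ties broken by z descending then accession.
    """
    hits = stats[stats["lfdr"] < lfdr_threshold]
    hits = hits.sort_values(["lfdr", "z", "domain_acc"], ascending=[True, False, True])
    return hits["domain_acc"].tolist()


def overlap_sets(condition_sets: Mapping[str, Set[str]]) -> Dict[str, object]:
    """Region cardinalities of the Venn partition over per-condition sets.

    Returns ``regions`` mapping each nonempty membership pattern (a tuple of
    condition labels) to the number of elements exactly in those conditions,
    plus the full ``intersection`` membership list.
    """
    labels = sorted(condition_sets)
    if len(labels) < 2:
        raise ValueError("overlap_sets: need >= 2 conditions")
    universe = set().union(*condition_sets.values())
    regions: Dict[Tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(condition_sets[l] for l in combo))
            outside = set().union(*(condition_sets[l] for l in labels if l not in combo), set())
            regions[combo] = len(inside - outside)
    intersection = sorted(set.intersection(*(condition_sets[l] for l in labels)))
    return {"regions": regions, "intersection": intersection, "union_size": len(universe)}
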