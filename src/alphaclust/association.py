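"""Downstream statistics on the cluster-average power marker.

Once a significant cluster is found, its per-subject average power becomes
a scalar brain marker. This module covers the follow-up analyses: nested
OLS moderation models testing whether a binary group (genotype, age group)
moderates the exposure-power slope; Spearman correlations of the marker
with outcomes inside subgroups; and atlas-region coverage of a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import stratum_of
from .cluster import ClusterResult
from .grid import SourceGrid
from .stats import partial_spearman

__all__ = [
    "ModerationResult",
    "SubgroupCorrelation",
    "fit_moderation",
    "subgroup_correlations",
    "roi_coverage",
    "subgroup_mask",
]


@dataclass(frozen=True)
class ModerationResult:
    """Nested OLS comparison with and without the exposure x group term.

    Base model: marker ~ 1 + exposure + moderator. The full model adds
    exposure * moderator; ``interaction_p`` is the two-sided t-test p-value
    of that coefficient (df = n - 4) and ``delta_r2 = r2_full - r2_base``
    is the moderation effect size (nonnegative for nested OLS fits).
    """

    moderator_name: str
    base_coefficients: dict[str, float]
    full_coefficients: dict[str, float]
    r2_base: float
    r2_full: float
    delta_r2: float
    interaction_p: float
    n: int


@dataclass(frozen=True)
class SubgroupCorrelation:
    """Spearman correlation of the marker with one outcome in one subgroup.

    ``rho`` and ``pval`` are NaN (undefined) when fewer than 4 complete
    cases are available.
    """

    subgroup: str
    outcome: str
    n: int
    rho: float
    pval: float


def fit_moderation(
    avg_power: np.ndarray,
    exposure: np.ndarray,
    moderator: np.ndarray,
    moderator_name: str = "moderator",
) -> ModerationResult:
    """Fit the nested moderation models by ordinary least squares.

    ``moderator`` must be binary-coded 0/1 with both levels present.
    Raises on a single-level moderator or a collinear design.
    """
    y = np.asarray(avg_power, dtype=float)
    x = np.asarray(exposure, dtype=float)
    m = np.asarray(moderator, dtype=float)
    n = len(y)
    if len(x) != n or len(m) != n:
        raise ValueError("avg_power, exposure, moderator must align")
    if n < 5:
        raise ValueError("need at least 5 observations")
    levels = np.unique(m)
    if len(levels) < 2:
        raise ValueError("moderator must have both levels present")
    if not set(levels) <= {0.0, 1.0}:
        raise ValueError("moderator must be coded 0/1")

    names = ["const", "exposure", moderator_name, f"exposure:{moderator_name}"]
    X_full = np.column_stack([np.ones(n), x, m, x * m])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("collinear design matrix")

    base = sm.OLS(y, X_full[:, :3]).fit()
    full = sm.OLS(y, X_full).fit()
    return ModerationResult(
        moderator_name=moderator_name,
        base_coefficients=dict(zip(names[:3], map(float, base.params))),
        full_coefficients=dict(zip(names, map(float, full.params))),
        r2_base=float(base.rsquared),
        r2_full=float(full.rsquared),
        delta_r2=float(full.rsquared - base.rsquared),
        interaction_p=float(full.pvalues[3]),
        n=n,
    )


def subgroup_mask(cohort: pd.DataFrame, label: str) -> np.ndarray:
    """Boolean row mask for a subgroup label.

    Accepted labels: 'all', 'young', 'old', 'E3/E3', 'E3/E4', and combined
    strata such as 'young-E3/E3'.
    """
    if label == "all":
        return np.ones(len(cohort), dtype=bool)
    if label in ("young", "old"):
        return (cohort["age_group"] == label).to_numpy()
    if label in ("E3/E3", "E3/E4"):
        return (cohort["genotype"] == label).to_numpy()
    if "-" in label:
        return (stratum_of(cohort) == label).to_numpy()
    raise ValueError(f"unknown subgroup label: {label!r}")


def subgroup_correlations(
    avg_power: np.ndarray,
    cohort: pd.DataFrame,
    subgroups: list[str],
    outcomes: list[str],
    adjust_age: bool = False,
) -> list[SubgroupCorrelation]:
    """Spearman correlations of the marker with outcomes per subgroup.

    Rows with a missing outcome are dropped pairwise (complete cases), so
    ``n`` can vary across outcomes. With ``adjust_age`` the age covariate
    is partialled out. A subgroup-outcome pair with fewer than 4 complete
    cases is returned flagged undefined (NaN rho/p) rather than raising.
    """
    avg_power = np.asarray(avg_power, dtype=float)
    if len(avg_power) != len(cohort):
        raise ValueError("avg_power length must equal cohort size")
    if not subgroups:
        raise ValueError("subgroup list is empty")
    missing_cols = [c for c in outcomes if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"outcome columns not in cohort: {missing_cols}")

    results = []
    for label in subgroups:
        gmask = subgroup_mask(cohort, label)
        for outcome in outcomes:
            vals = cohort[outcome].to_numpy(dtype=float)
            cmask = gmask & np.isfinite(vals) & np.isfinite(avg_power)
            n = int(cmask.sum())
            if n < 4:
                results.append(
                    SubgroupCorrelation(label, outcome, n, np.nan, np.nan)
                )
                continue
            if adjust_age:
                rho, p = partial_spearman(
                    avg_power[cmask], vals[cmask], cohort.loc[cmask, "age"]
                )
            else:
                rho, p = partial_spearman(avg_power[cmask], vals[cmask])
            results.append(SubgroupCorrelation(label, outcome, n, rho, p))
    return results


def roi_coverage(cluster: ClusterResult, grid: SourceGrid) -> pd.DataFrame:
    """Percent of each labelled region's nodes occupied by the cluster.

    Each node counts once regardless of how many frequency steps it spans.
    Regions with no cluster node are omitted. Percentages are rounded to
    two decimals.
    """
    if grid.region_labels is None:
        raise ValueError("grid carries no region labels")
    cluster_nodes = np.unique(cluster.members[:, 0])
    labels = grid.region_labels
    rows = []
    for region in pd.unique(labels[cluster_nodes]):
        region_nodes = np.flatnonzero(labels == region)
        occupied = np.intersect1d(region_nodes, cluster_nodes, assume_unique=True)
        rows.append(
            {
                "region": region,
                "percent": round(100.0 * len(occupied) / len(region_nodes), 2),
                "n_cluster_nodes": len(occupied),
                "n_region_nodes": len(region_nodes),
            }
        )
    return pd.DataFrame(rows).sort_values("percent", ascending=False).reset_index(
        drop=True
    )
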