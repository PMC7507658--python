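"""Spatio-spectral cluster-mass permutation inference.

The core procedure: correlate exposure with relative power at every
(node, frequency step) cell with a covariate-adjusted Spearman coefficient;
keep cells significant at ``p_thresh`` that sit, at their node, inside a
same-sign run of at least ``min_consecutive_steps`` consecutive significant
steps; merge kept cells of equal sign into clusters by spatial adjacency
(Euclidean neighbours) and frequency adjacency (step +/- 1); trim frequency
layers occupied by fewer than ``max(1, floor(min_nodes_fraction * n_nodes))``
nodes and re-check the run criterion; score each cluster by its mass, the
sum of member correlation coefficients. Family-wise error control comes
from a max-statistic permutation scheme: the exposure vector is shuffled
across subjects (the covariate stays attached to each subject's power), the
entire pipeline re-runs, and the largest absolute surrogate cluster mass of
each permutation forms the null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

from .grid import SourceGrid
from .stats import rho_threshold, spearman_pvalue
from .tensor import PowerTensor

__all__ = [
    "ClusterParams",
    "CorrelationMap",
    "ClusterResult",
    "NullDistribution",
    "correlation_map",
    "eligible_cells",
    "build_clusters",
    "permutation_test",
    "extract_avg_power",
    "cluster_profile",
]


@dataclass(frozen=True)
class ClusterParams:
    """Tuning parameters of the cluster statistic.

    p_thresh : per-cell two-sided significance threshold for eligibility.
    min_consecutive_steps : minimum same-sign significant run length, in
        frequency steps, required at a node (3 steps = 0.75 Hz at 0.25 Hz
        resolution).
    min_nodes_fraction : a cluster's frequency layer must contain at least
        ``max(1, floor(min_nodes_fraction * n_nodes))`` nodes (1% of 1202
        nodes = 12).
    spatial_neighbor_dist : spatial adjacency radius in mm; None means
        1.1 x grid spacing (face adjacency on the lattice).
    n_permutations : permutations of the exposure vector for the null.
    alpha_fwer : family-wise significance level for reporting.
    under_threshold_policy : 'trim' drops under-populated frequency layers
        and re-checks the run criterion; 'reject' discards the whole
        cluster instead.
    p_estimator : 'proportion' is the plain count/n estimate (p = 0
        possible); 'smoothed' uses (count + 1)/(n + 1).
    permute_scheme : 'exposure' shuffles the exposure values;
        'freedman_lane' permutes exposure rank residuals about the
        covariate fit.
    """

    p_thresh: float = 0.01
    min_consecutive_steps: int = 3
    min_nodes_fraction: float = 0.01
    spatial_neighbor_dist: float | None = None
    n_permutations: int = 5000
    alpha_fwer: float = 0.05
    seed: int | None = None
    under_threshold_policy: str = "trim"
    p_estimator: str = "proportion"
    permute_scheme: str = "exposure"

    def __post_init__(self):
        if not 0 < self.p_thresh < 1:
            raise ValueError("p_thresh must be in (0, 1)")
        if self.min_consecutive_steps < 1:
            raise ValueError("min_consecutive_steps must be >= 1")
        if not 0 <= self.min_nodes_fraction <= 1:
            raise ValueError("min_nodes_fraction must be in [0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.under_threshold_policy not in ("trim", "reject"):
            raise ValueError("under_threshold_policy must be 'trim' or 'reject'")
        if self.p_estimator not in ("proportion", "smoothed"):
            raise ValueError("p_estimator must be 'proportion' or 'smoothed'")
        if self.permute_scheme not in ("exposure", "freedman_lane"):
            raise ValueError("permute_scheme must be 'exposure' or 'freedman_lane'")

    def min_nodes_per_step(self, n_nodes: int) -> int:
        return max(1, int(np.floor(self.min_nodes_fraction * n_nodes)))


@dataclass(frozen=True)
class CorrelationMap:
    """Per-(node, freq) partial Spearman rho and p-values."""

    rho: np.ndarray    # (n_nodes, n_freqs); NaN where undefined
    pval: np.ndarray   # (n_nodes, n_freqs); NaN where rho undefined
    n_subjects: int
    covariate_name: str | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.rho.shape


@dataclass
class ClusterResult:
    """One spatio-spectral cluster.

    ``members`` is an (m, 2) integer array of (node index, freq step index)
    pairs after layer trimming; ``mass`` the sum of member rho values;
    ``nodes_per_step`` the node count of each retained frequency step.
    ``fwer_p`` is filled by the permutation test.
    """

    members: np.ndarray
    sign: int
    mass: float
    nodes_per_step: dict[int, int]
    fwer_p: float | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def member_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(f)) for i, f in self.members}


@dataclass(frozen=True)
class NullDistribution:
    """Max absolute surrogate cluster mass per permutation (0 if none)."""

    max_abs_mass: np.ndarray
    n_permutations: int

    def __post_init__(self):
        if len(self.max_abs_mass) != self.n_permutations:
            raise ValueError("length must equal n_permutations")


# ---------------------------------------------------------------------------
# vectorized rank machinery


def _std_ranks_rows(x2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise zero-mean unit-norm ranks; second output flags valid rows."""
    r = rankdata(x2d, axis=1)
    r = r - r.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(r, axis=1)
    valid = nrm > 0
    r[valid] /= nrm[valid, None]
    r[~valid] = 0.0
    return r, valid


def _std_ranks_vec(x: np.ndarray) -> np.ndarray:
    r = rankdata(np.asarray(x, dtype=float))
    r = r - r.mean()
    nrm = np.linalg.norm(r)
    if nrm == 0:
        raise ValueError("vector is constant; correlations are undefined")
    return r / nrm


def _partial_rho_rows(
    P: np.ndarray,
    valid: np.ndarray,
    u: np.ndarray,
    v: np.ndarray | None,
    r_xz: np.ndarray | None,
) -> np.ndarray:
    """Partial (or plain) Spearman rho of every row of P against u."""
    r_xy = P @ u
    if v is None:
        rho = r_xy
    else:
        r_yz = float(u @ v)
        with np.errstate(divide="ignore", invalid="ignore"):
            den = (1.0 - r_xz**2) * (1.0 - r_yz**2)
            rho = np.where(den > 0, (r_xy - r_xz * r_yz) / np.sqrt(den), np.nan)
    rho = np.where(valid, rho, np.nan)
    return rho


def _align(series, subject_ids: np.ndarray, what: str) -> np.ndarray:
    """Align a per-subject vector with the tensor's subject order."""
    if isinstance(series, pd.Series):
        missing = [s for s in subject_ids if s not in series.index]
        if missing:
            raise ValueError(f"{what} is missing subject ids: {missing[:5]}")
        return series.reindex(list(subject_ids)).to_numpy(dtype=float)
    arr = np.asarray(series, dtype=float)
    if len(arr) != len(subject_ids):
        raise ValueError(
            f"{what} length {len(arr)} does not match tensor subjects "
            f"{len(subject_ids)}; pass a pandas Series indexed by subject_id "
            "to align by id"
        )
    return arr


def correlation_map(
    tensor: PowerTensor,
    exposure,
    covariate=None,
    covariate_name: str | None = "age",
) -> CorrelationMap:
    """Partial Spearman correlation of exposure with every tensor cell.

    ``exposure`` and ``covariate`` may be pandas Series indexed by
    subject_id (aligned to the tensor, erroring on missing ids) or plain
    arrays in tensor subject order. Cells with zero variance across
    subjects are flagged undefined (NaN).
    """
    n = tensor.n_subjects
    if n < 4:
        raise ValueError("need at least 4 subjects")
    x = _align(exposure, tensor.subject_ids, "exposure")
    u = _std_ranks_vec(x)
    if covariate is not None:
        z = _align(covariate, tensor.subject_ids, "covariate")
        if np.ptp(z) == 0:
            covariate = None  # constant covariate: ordinary Spearman
    P, valid = _std_ranks_rows(tensor.values.reshape(-1, n))
    if covariate is None:
        rho = _partial_rho_rows(P, valid, u, None, None)
        dof = n - 2
        covariate_name = None
    else:
        v = _std_ranks_vec(z)
        r_xz = P @ v
        rho = _partial_rho_rows(P, valid, u, v, r_xz)
        dof = n - 3
    shape = (tensor.n_nodes, tensor.n_freqs)
    pval = np.array([spearman_pvalue(r, dof) for r in rho]).reshape(shape)
    return CorrelationMap(
        rho=rho.reshape(shape),
        pval=pval,
        n_subjects=n,
        covariate_name=covariate_name,
    )


# ---------------------------------------------------------------------------
# eligibility and clustering


def _keep_runs(sig: np.ndarray, k: int) -> np.ndarray:
    """Keep cells inside runs of >= k consecutive True values along axis 1."""
    if k <= 1:
        return sig.copy()
    n, f = sig.shape
    padded = np.zeros((n, f + 2), dtype=np.int8)
    padded[:, 1:-1] = sig
    d = np.diff(padded, axis=1)
    rs, cs = np.nonzero(d == 1)    # run starts
    _, ce = np.nonzero(d == -1)    # run ends (exclusive); row-major pairing
    out = np.zeros_like(sig, dtype=bool)
    length = ce - cs
    for row, c0, c1 in zip(rs[length >= k], cs[length >= k], ce[length >= k]):
        out[row, c0:c1] = True
    return out


def _signed_mask(rho: np.ndarray, sig: np.ndarray, k: int) -> np.ndarray:
    """int8 mask: +1/-1 for eligible cells, 0 otherwise.

    A cell is eligible iff significant and inside a run of >= k consecutive
    significant steps of its own sign at its node (an opposite-sign
    significant cell breaks the run).
    """
    pos = _keep_runs(sig & (rho > 0), k)
    neg = _keep_runs(sig & (rho < 0), k)
    return pos.astype(np.int8) - neg.astype(np.int8)


def eligible_cells(cmap: CorrelationMap, params: ClusterParams) -> np.ndarray:
    """Signed eligibility mask over the (node, freq) grid."""
    with np.errstate(invalid="ignore"):
        sig = cmap.pval < params.p_thresh
    return _signed_mask(cmap.rho, sig, params.min_consecutive_steps)


def _consecutive_run_ok(steps: np.ndarray, k: int) -> bool:
    """True if the sorted step indices contain >= k consecutive values."""
    if len(steps) == 0:
        return False
    if k <= 1:
        return True
    breaks = np.flatnonzero(np.diff(steps) != 1)
    run_lengths = np.diff(np.concatenate(([-1], breaks, [len(steps) - 1])))
    return bool(run_lengths.max() >= k)


def _raw_clusters(
    mask: np.ndarray,
    rho: np.ndarray,
    pairs: np.ndarray,
    params: ClusterParams,
):
    """Connected components of the signed mask plus per-cluster filtering.

    Returns a list of (members (m,2) array, sign, mass, nodes_per_step).
    Shared verbatim by the observed pass and every permutation.
    """
    n_nodes, n_freqs = mask.shape
    cells = np.flatnonzero(mask.ravel())
    if cells.size == 0:
        return []

    # frequency-adjacency edges between same-sign eligible cells
    a = mask[:, :-1]
    b = mask[:, 1:]
    ei, ef = np.nonzero((a != 0) & (a == b))
    u = ei * n_freqs + ef
    v = u + 1
    # spatial-adjacency edges at each frequency step
    if pairs.size:
        ma = mask[pairs[:, 0], :]
        mb = mask[pairs[:, 1], :]
        ek, ef2 = np.nonzero((ma != 0) & (ma == mb))
        u = np.concatenate([u, pairs[ek, 0] * n_freqs + ef2])
        v = np.concatenate([v, pairs[ek, 1] * n_freqs + ef2])

    n_cells = n_nodes * n_freqs
    graph = coo_matrix(
        (np.ones(len(u), dtype=np.int8), (u, v)), shape=(n_cells, n_cells)
    )
    _, labels = connected_components(graph, directed=False)

    comp_labels, inverse = np.unique(labels[cells], return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    bounds = np.searchsorted(inverse[order], np.arange(len(comp_labels) + 1))

    thr = params.min_nodes_per_step(n_nodes)
    k = params.min_consecutive_steps
    rho_flat = rho.ravel()
    results = []
    for c in range(len(comp_labels)):
        flat = cells[order[bounds[c] : bounds[c + 1]]]
        nodes = flat // n_freqs
        steps = flat % n_freqs
        counts = np.bincount(steps, minlength=n_freqs)
        present = np.flatnonzero(counts)
        ok_layers = counts[present] >= thr
        if params.under_threshold_policy == "reject":
            if not ok_layers.all():
                continue
            kept_steps = present
        else:
            kept_steps = present[ok_layers]
        if not _consecutive_run_ok(kept_steps, k):
            continue
        keep = np.isin(steps, kept_steps)
        flat = flat[keep]
        nodes = nodes[keep]
        steps = steps[keep]
        mass = float(rho_flat[flat].sum())
        sign = int(np.sign(mass))
        members = np.column_stack([nodes, steps])
        nodes_per_step = {
            int(s): int(n) for s, n in zip(kept_steps, counts[kept_steps])
        }
        results.append((members, sign, mass, nodes_per_step))
    return results


def build_clusters(
    mask: np.ndarray,
    rho: np.ndarray,
    grid: SourceGrid,
    params: ClusterParams,
) -> list[ClusterResult]:
    """Clusters (without FWER p-values) from a signed eligibility mask.

    Adjacency: (node i, step f) touches (node i, step f +/- 1) and
    (node j, step f) for spatial neighbours j; only equal-sign eligible
    cells connect. Returned sorted by decreasing |mass|.
    """
    if mask.shape != rho.shape or mask.shape[0] != grid.n_nodes:
        raise ValueError("mask, rho and grid shapes are inconsistent")
    pairs = grid.neighbor_pairs(params.spatial_neighbor_dist)
    raw = _raw_clusters(mask, rho, pairs, params)
    clusters = [
        ClusterResult(members=m, sign=s, mass=ms, nodes_per_step=nps)
        for m, s, ms, nps in raw
    ]
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


# ---------------------------------------------------------------------------
# permutation inference


def permutation_test(
    tensor: PowerTensor,
    exposure,
    covariate,
    grid: SourceGrid,
    params: ClusterParams,
    permutation_source: np.ndarray | None = None,
) -> tuple[list[ClusterResult], NullDistribution]:
    """Observed clusters with max-statistic FWER p-values.

    Per permutation the exposure is shuffled across subjects while the
    covariate stays attached to each subject's power, the full
    map -> eligibility -> clustering pipeline re-runs, and the largest
    absolute surrogate mass (0 when no surrogate cluster forms) enters the
    null distribution. ``fwer_p`` is the proportion of permutations whose
    maximum reaches the observed |mass|. ``permutation_source`` may supply
    explicit permutation index rows (e.g. an exhaustive enumeration);
    otherwise ``params.n_permutations`` random shuffles are drawn from
    ``params.seed``. Results are sorted by fwer_p, then |mass|.
    """
    n = tensor.n_subjects
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if tensor.n_nodes != grid.n_nodes:
        raise ValueError("tensor and grid node counts differ")

    x = _align(exposure, tensor.subject_ids, "exposure")
    u0 = _std_ranks_vec(x)
    if covariate is not None:
        z = _align(covariate, tensor.subject_ids, "covariate")
        if np.ptp(z) == 0:
            covariate = None
    P, valid = _std_ranks_rows(tensor.values.reshape(-1, n))
    if covariate is not None:
        v = _std_ranks_vec(z)
        r_xz = P @ v
        dof = n - 3
    else:
        v = None
        r_xz = None
        dof = n - 2
    rho_crit = rho_threshold(params.p_thresh, dof)
    pairs = grid.neighbor_pairs(params.spatial_neighbor_dist)
    shape = (tensor.n_nodes, tensor.n_freqs)

    def clusters_for(u: np.ndarray):
        rho = _partial_rho_rows(P, valid, u, v, r_xz).reshape(shape)
        with np.errstate(invalid="ignore"):
            sig = np.abs(rho) > rho_crit
        mask = _signed_mask(rho, sig, params.min_consecutive_steps)
        return _raw_clusters(mask, rho, pairs, params)

    observed = [
        ClusterResult(members=m, sign=s, mass=ms, nodes_per_step=nps)
        for m, s, ms, nps in clusters_for(u0)
    ]

    if permutation_source is not None:
        perms = np.asarray(permutation_source)
        n_perm = len(perms)
    else:
        rng = np.random.default_rng(params.seed)
        perms = None
        n_perm = params.n_permutations

    if params.permute_scheme == "freedman_lane" and v is not None:
        fit = float(u0 @ v) * v
        resid = u0 - fit
    else:
        fit = resid = None

    null = np.zeros(n_perm)
    for bperm in range(n_perm):
        order = perms[bperm] if perms is not None else rng.permutation(n)
        if resid is not None:
            u = fit + resid[order]
        else:
            u = u0[order]
        raw = clusters_for(u)
        if raw:
            null[bperm] = max(abs(ms) for _, _, ms, _ in raw)

    for c in observed:
        count = int((null >= abs(c.mass)).sum())
        if params.p_estimator == "smoothed":
            c.fwer_p = (count + 1) / (n_perm + 1)
        else:
            c.fwer_p = count / n_perm
    observed.sort(key=lambda c: (c.fwer_p, -abs(c.mass)))
    return observed, NullDistribution(max_abs_mass=null, n_permutations=n_perm)


def extract_avg_power(tensor: PowerTensor, cluster: ClusterResult) -> np.ndarray:
    """Per-subject mean power over all member (node, freq) cells."""
    if cluster.n_members == 0:
        raise ValueError("cluster has no members")
    m = cluster.members
    if m[:, 0].max() >= tensor.n_nodes or m[:, 1].max() >= tensor.n_freqs:
        raise ValueError("cluster members outside tensor index range")
    return tensor.values[m[:, 0], m[:, 1], :].mean(axis=0)


def cluster_profile(cluster: ClusterResult) -> pd.Series:
    """Node count per retained frequency step (cluster-extent profile)."""
    s = pd.Series(cluster.nodes_per_step, name="n_nodes").sort_index()
    s.index.name = "freq_step"
    return s
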