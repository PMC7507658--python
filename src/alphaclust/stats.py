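"""Covariate-adjusted Spearman correlation.

The partial Spearman coefficient between x and y given a covariate z is the
Pearson correlation of the residuals of the ranks of x and of y after least
squares on [intercept, ranks of z]. With a single covariate this equals the
closed-form identity

    rho = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))

on the rank correlations, which is how it is computed here (and, vectorized,
in the cluster module). The two-sided p-value uses the t approximation with
n - 3 degrees of freedom (n - 2 for the unadjusted fall-back).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata
from scipy.stats import t as t_dist

__all__ = ["partial_spearman", "spearman_pvalue", "rho_threshold"]


def spearman_pvalue(rho: float, dof: int) -> float:
    """Two-sided p from the t approximation with ``dof`` degrees of freedom."""
    if not np.isfinite(rho):
        return np.nan
    r = min(max(rho, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(dof / (1.0 - r * r))
    return float(2.0 * t_dist.sf(abs(t), dof))


def rho_threshold(p_thresh: float, dof: int) -> float:
    """|rho| above which the t-approximation p-value is < p_thresh."""
    t_crit = t_dist.ppf(1.0 - p_thresh / 2.0, dof)
    return float(t_crit / np.sqrt(dof + t_crit**2))


def _std_ranks(x: np.ndarray) -> np.ndarray | None:
    """Zero-mean, unit-norm ranks; None if x is constant."""
    r = rankdata(x)
    r = r - r.mean()
    nrm = np.linalg.norm(r)
    if nrm == 0:
        return None
    return r / nrm


def partial_spearman(x, y, z=None) -> tuple[float, float]:
    """Spearman correlation of x and y, partialling out the covariate z.

    Returns ``(rho, pval)``. A constant x or y yields ``(nan, nan)``
    (flagged undefined; such cells are never eligible downstream). A
    constant or absent z falls back to the ordinary Spearman coefficient.
    Ties receive average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n or (z is not None and len(np.asarray(z)) != n):
        raise ValueError("x, y, z must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    u = _std_ranks(x)
    w = _std_ranks(y)
    if u is None or w is None:
        return (np.nan, np.nan)
    v = _std_ranks(np.asarray(z, dtype=float)) if z is not None else None
    if v is None:
        rho = float(u @ w)
        return rho, spearman_pvalue(rho, n - 2)
    r_xy = float(u @ w)
    r_xz = float(u @ v)
    r_yz = float(w @ v)
    den = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if den <= 0:
        return (np.nan, np.nan)
    rho = (r_xy - r_xz * r_yz) / np.sqrt(den)
    return float(rho), spearman_pvalue(rho, n - 3)
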