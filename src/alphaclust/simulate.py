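"""Synthetic source-space relative power with planted exposure effects.

The generator emulates resting-state source-reconstructed relative power in
the alpha analysis window: a 1/f background plus an alpha bump, with
subject-level variability that is smooth across frequency (peak frequency,
bump amplitude and background slope vary per subject) and across space
(a low-dimensional smooth amplitude field), plus a small cell-level residual.
Real source spectra are strongly correlated between neighbouring nodes and
frequency steps; reproducing that dependence matters because the cluster
statistic downstream exploits exactly this structure.

Exposure effects are planted with a Gaussian-copula construction on ranks:
inside the target (nodes x band x strata) cells, the subject variation is a
monotone transform of ``r * z_x + sqrt(1 - r^2) * eps`` where ``z_x`` are
normal scores of the exposure ranks and ``r = 2 sin(pi * rho_s / 6)`` maps
the target Spearman correlation to the latent Pearson one. Spearman
correlations are invariant to the monotone transform, so the realized
exposure-power rank correlation approaches the target regardless of the
marginal power distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .cohort import STRATA, stratum_of
from .grid import SourceGrid
from .tensor import PowerTensor, freq_grid


@dataclass(frozen=True)
class EffectSpec:
    """A planted exposure-power association.

    target_nodes : node indices carrying the effect.
    freq_band : (lo, hi) Hz, inclusive, within the analysis band.
    target_rho : desired Spearman correlation between exposure and power
        inside the planted cells, |rho| < 1.
    affected_strata : "all" or a list of stratum labels ('young-E3/E3', ...).
    noise_sd : log-scale of the power modulation carrying the effect
        (dimensionless; 0.4 is comparable to the baseline subject
        variability of the alpha bump).
    noise_share_subject : fraction of the residual (non-exposure) variance
        that is shared across all planted cells of a subject rather than
        drawn independently per cell. Real spectra move together within a
        subject, so most of the residual is subject-level; with a high
        share the cluster-average power keeps a correlation close to the
        per-cell target instead of averaging the noise away.
    """

    target_nodes: np.ndarray
    freq_band: tuple[float, float]
    target_rho: float
    affected_strata: str | tuple[str, ...] = "all"
    noise_sd: float = 0.4
    noise_share_subject: float = 0.8

    def __post_init__(self):
        nodes = np.asarray(self.target_nodes, dtype=np.intp)
        object.__setattr__(self, "target_nodes", nodes)
        if not abs(self.target_rho) < 1:
            raise ValueError("|target_rho| must be < 1")
        if self.freq_band[0] > self.freq_band[1]:
            raise ValueError("freq_band must be (lo, hi) with lo <= hi")
        if self.affected_strata != "all":
            strata = tuple(self.affected_strata)
            unknown = set(strata) - set(STRATA)
            if unknown:
                raise ValueError(f"unknown strata: {sorted(unknown)}")
            object.__setattr__(self, "affected_strata", strata)


@dataclass(frozen=True)
class BaselineParams:
    """Spectral baseline and subject-variability parameters.

    The mean per-bin relative power is ``bg_amp * (10/f)^bg_exponent +
    alpha_amp * exp(-(f - alpha_center)^2 / (2 alpha_width^2))``; with the
    defaults the 25 alpha-window bins carry roughly 20% of total power,
    typical of eyes-closed rest. Subject variability: global amplitude,
    alpha amplitude, peak-frequency shift and background slope jitter, plus
    a smooth spatial modulation of the bump built from ``n_spatial_kernels``
    Gaussian kernels, and an independent per-cell log-normal residual.
    """

    alpha_center: float = 10.0       # Hz
    alpha_width: float = 1.2         # Hz
    alpha_amp: float = 0.012         # relative power per 0.25-Hz bin at peak
    bg_amp: float = 0.004            # background relative power per bin at 10 Hz
    bg_exponent: float = 1.0
    global_log_sd: float = 0.2       # per-subject overall amplitude
    alpha_log_sd: float = 0.3        # per-subject bump amplitude
    peak_shift_sd: float = 0.5       # Hz, per-subject alpha peak jitter
    slope_sd: float = 0.15           # per-subject background exponent jitter
    n_spatial_kernels: int = 8
    spatial_kernel_mm: float = 30.0
    spatial_mod_sd: float = 0.3      # amplitude of the smooth spatial field
    cell_log_sd: float = 0.1         # independent residual per cell


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Van der Waerden normal scores of the ranks of x (average ranks)."""
    n = len(x)
    return ndtri((rankdata(x) - 0.5) / n)


def spearman_to_pearson(rho_s: float) -> float:
    """Latent bivariate-normal Pearson r realizing Spearman rho_s."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _affected_mask(cohort: pd.DataFrame, affected) -> np.ndarray:
    if affected == "all":
        return np.ones(len(cohort), dtype=bool)
    return stratum_of(cohort).isin(list(affected)).to_numpy()


def generate_power(
    grid: SourceGrid,
    cohort: pd.DataFrame,
    effect: EffectSpec | None = None,
    band: tuple[float, float] = (8.0, 14.0),
    df: float = 0.25,
    seed: int | np.random.Generator | None = None,
    baseline: BaselineParams = BaselineParams(),
) -> PowerTensor:
    """Generate a relative-power tensor, optionally with a planted effect.

    Values are clipped to [0, 1]. With identical seed and parameters the
    output is bit-identical.
    """
    rng = np.random.default_rng(seed)
    freqs = freq_grid(band, df)
    n_nodes, n_freqs, n_sub = grid.n_nodes, len(freqs), len(cohort)
    if n_sub == 0:
        raise ValueError("empty cohort")
    bp = baseline

    # per-subject spectral latents
    g = rng.normal(0.0, bp.global_log_sd, n_sub)          # global log-amplitude
    a = rng.normal(0.0, bp.alpha_log_sd, n_sub)           # bump log-amplitude
    delta = rng.normal(0.0, bp.peak_shift_sd, n_sub)      # peak shift, Hz
    gamma = bp.bg_exponent + rng.normal(0.0, bp.slope_sd, n_sub)

    # smooth spatial modulation of the bump: Gaussian kernels at random
    # in-mask centres, per-subject coefficients
    centers = grid.coords[
        rng.choice(n_nodes, size=min(bp.n_spatial_kernels, n_nodes), replace=False)
    ]
    d2 = ((grid.coords[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    phi = np.exp(-d2 / (2.0 * bp.spatial_kernel_mm**2))   # (nodes, K)
    coef = rng.normal(0.0, 1.0, (phi.shape[1], n_sub))
    w = phi @ coef                                        # (nodes, subjects)
    w /= max(np.std(w), 1e-12)
    spatial_mod = np.clip(1.0 + bp.spatial_mod_sd * w, 0.1, None)

    bump_shape = np.exp(
        -((freqs[:, None] - bp.alpha_center - delta[None, :]) ** 2)
        / (2.0 * bp.alpha_width**2)
    )                                                     # (freqs, subjects)
    background = bp.bg_amp * (10.0 / freqs[:, None]) ** gamma[None, :]
    bump_amp = bp.alpha_amp * np.exp(a)                   # (subjects,)

    eps = rng.normal(0.0, bp.cell_log_sd, (n_nodes, n_freqs, n_sub))
    values = (
        background[None, :, :]
        + spatial_mod[:, None, :] * (bump_amp * bump_shape)[None, :, :]
    ) * np.exp(g[None, None, :] + eps)

    if effect is not None and len(effect.target_nodes) > 0:
        if effect.target_nodes.max() >= n_nodes or effect.target_nodes.min() < 0:
            raise ValueError("effect.target_nodes outside the grid")
        lo, hi = effect.freq_band
        fmask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
        if not fmask.any():
            raise ValueError("effect.freq_band selects no frequency steps")
        smask = _affected_mask(cohort, effect.affected_strata)
        m = int(smask.sum())
        if m >= 4:
            r = spearman_to_pearson(effect.target_rho)
            z_x = _normal_scores(cohort.loc[smask, "tpa"].to_numpy())
            n_t, n_f = len(effect.target_nodes), int(fmask.sum())
            share = effect.noise_share_subject
            eps_subj = rng.normal(0.0, 1.0, m)
            eps_cell = rng.normal(0.0, 1.0, (n_t, n_f, m))
            eps_e = np.sqrt(share) * eps_subj[None, None, :] + np.sqrt(
                1.0 - share
            ) * eps_cell
            y = r * z_x[None, None, :] + np.sqrt(1.0 - r**2) * eps_e
            # population baseline profile at the planted cells, modulated by
            # a monotone transform of the copula variable
            profile = (
                bp.bg_amp * (10.0 / freqs[fmask]) ** bp.bg_exponent
                + bp.alpha_amp
                * np.exp(
                    -((freqs[fmask] - bp.alpha_center) ** 2)
                    / (2.0 * bp.alpha_width**2)
                )
            )
            planted = profile[None, :, None] * np.exp(effect.noise_sd * y)
            ix = np.ix_(effect.target_nodes, np.flatnonzero(fmask), np.flatnonzero(smask))
            values[ix] = planted

    tensor = PowerTensor(
        values=np.clip(values, 0.0, 1.0),
        freqs=freqs,
        subject_ids=cohort["subject_id"].to_numpy(dtype=object),
    )
    tensor.validate()
    return tensor


#: Plausible outcome marginals (mean, sd): memory indices and volumes (mm^3).
OUTCOME_MARGINALS = {
    "episodic_memory": (24.3, 5.1),
    "working_memory": (10.3, 2.1),
    "total_gm": (5730.0, 510.0),
    "precuneus": (8460.0, 1040.0),
    "hippocampus": (3710.0, 410.0),
}


def generate_outcomes(
    cohort: pd.DataFrame,
    avg_power: np.ndarray,
    outcome_specs: dict[str, tuple[float, str]],
    seed: int | np.random.Generator | None = None,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Add outcome columns correlated with ``avg_power`` within a stratum.

    ``outcome_specs`` maps an outcome name (a key of OUTCOME_MARGINALS) to
    ``(target_rho, stratum)`` where stratum is a label like 'old-E3/E4' or
    'all'. Within the designated stratum the outcome is a monotone function
    of the avg_power rank mixed with noise via the Gaussian copula (with
    |target_rho| = 1 and hence zero noise it is strictly monotone); outside
    it is independent noise with the same marginal. ``missing_rate``
    randomly blanks outcome entries (emulating incomplete assessments).
    """
    avg_power = np.asarray(avg_power, dtype=float)
    if len(avg_power) != len(cohort):
        raise ValueError("avg_power length must equal cohort size")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    strata = stratum_of(cohort).to_numpy()
    for name, (target_rho, stratum) in outcome_specs.items():
        if name not in OUTCOME_MARGINALS:
            raise ValueError(f"unknown outcome name: {name!r}")
        if not abs(target_rho) <= 1:
            raise ValueError("|target_rho| must be <= 1")
        mean, sd = OUTCOME_MARGINALS[name]
        y = rng.normal(0.0, 1.0, len(cohort))
        mask = (
            np.ones(len(cohort), dtype=bool)
            if stratum == "all"
            else strata == stratum
        )
        m = int(mask.sum())
        if m >= 2:
            r = spearman_to_pearson(target_rho) if abs(target_rho) < 1 else np.sign(
                target_rho
            )
            z = _normal_scores(avg_power[mask])
            y[mask] = r * z + np.sqrt(max(0.0, 1.0 - r**2)) * y[mask]
        vals = mean + sd * y
        if missing_rate > 0:
            vals = np.where(rng.random(len(cohort)) < missing_rate, np.nan, vals)
        out[name] = vals
    return out
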