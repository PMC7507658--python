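"""Power spectra from segmented source time series.

Spectra are estimated by averaging Hann-tapered periodograms over
non-overlapping fixed-length segments (4-s segments at native resolution
give 0.25-Hz bins). Relative power normalizes by the summed power over a
reference range (1.5-45 Hz by default downstream), making spectra
comparable across subjects; band selection is inclusive at both edges.
The pipeline order is fixed: normalize over the reference range first,
then select the analysis band.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sp_signal


class InsufficientDataError(ValueError):
    """Raised when a recording yields fewer clean segments than required."""


@dataclass(frozen=True)
class SegmentedSeries:
    """Equal-length non-overlapping segments of one source time series."""

    segments: np.ndarray  # (n_segments, n_samples)
    fs: float             # Hz
    seg_len_s: float      # seconds

    def __post_init__(self):
        seg = np.asarray(self.segments, dtype=float)
        if seg.ndim != 2:
            raise ValueError("segments must be a 2-D (n_segments, n_samples) array")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if seg.shape[1] != int(round(self.fs * self.seg_len_s)):
            raise ValueError("segment length must equal fs * seg_len_s samples")
        object.__setattr__(self, "segments", seg)

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]


@dataclass(frozen=True)
class Spectrum:
    """A power spectrum on a regular frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    df: float
    is_relative: bool = False
    norm_range: tuple[float, float] | None = None

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freqs.shape != power.shape or freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D with equal length")
        if len(freqs) > 1 and not np.allclose(np.diff(freqs), self.df):
            raise ValueError("freqs must increase with constant step df")
        if (power < 0).any():
            raise ValueError("power must be nonnegative")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)


def segment(
    series: np.ndarray,
    fs: float,
    seg_len_s: float = 4.0,
    min_segments: int = 20,
) -> SegmentedSeries:
    """Cut a sample vector into non-overlapping segments.

    The trailing remainder shorter than one segment is discarded. Fewer
    than ``min_segments`` full segments raises InsufficientDataError
    (mirroring the requirement of at least 20 clean 4-s segments, i.e.
    80 s of usable activity).
    """
    series = np.asarray(series, dtype=float)
    n_per = int(round(fs * seg_len_s))
    if n_per < 1:
        raise ValueError("segment length must be at least one sample")
    n_seg = len(series) // n_per
    if n_seg < min_segments:
        raise InsufficientDataError(
            f"only {n_seg} segments available, need at least {min_segments}"
        )
    segs = series[: n_seg * n_per].reshape(n_seg, n_per)
    return SegmentedSeries(segments=segs, fs=float(fs), seg_len_s=float(seg_len_s))


def compute_psd(seg: SegmentedSeries, df_target: float | None = None) -> Spectrum:
    """Averaged Hann-tapered periodogram of the segments.

    The native resolution is 1/seg_len_s Hz. ``df_target`` must be the
    native resolution (default) or an integer multiple of it, in which
    case adjacent bins are averaged down to the requested resolution.
    """
    if seg.n_segments == 0:
        raise ValueError("no segments to average")
    native_df = 1.0 / seg.seg_len_s
    if df_target is None:
        df_target = native_df
    if df_target < native_df - 1e-12:
        raise ValueError("df_target cannot be finer than 1/seg_len_s")
    ratio = df_target / native_df
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("df_target must be an integer multiple of 1/seg_len_s")
    ratio = int(round(ratio))

    freqs, pxx = sp_signal.periodogram(
        seg.segments, fs=seg.fs, window="hann", detrend=False, axis=1
    )
    power = pxx.mean(axis=0)
    if ratio > 1:
        n_out = len(freqs) // ratio
        power = power[: n_out * ratio].reshape(n_out, ratio).mean(axis=1)
        freqs = freqs[: n_out * ratio].reshape(n_out, ratio).mean(axis=1)
        df = df_target
    else:
        df = native_df
    return Spectrum(freqs=freqs, power=power, df=float(df))


def _range_mask(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)


def relative_power(
    spec: Spectrum, norm_range: tuple[float, float] = (1.5, 45.0)
) -> Spectrum:
    """Normalize by total power over ``norm_range`` (inclusive).

    After normalization the power summed over the range equals 1. Applying
    the operation twice equals applying it once.
    """
    mask = _range_mask(spec.freqs, *norm_range)
    total = spec.power[mask].sum()
    if total <= 0:
        raise ValueError("zero total power in the normalization range")
    return Spectrum(
        freqs=spec.freqs,
        power=spec.power / total,
        df=spec.df,
        is_relative=True,
        norm_range=(float(norm_range[0]), float(norm_range[1])),
    )


def band_select(spec: Spectrum, band: tuple[float, float]) -> Spectrum:
    """Keep bins with band[0] <= f <= band[1], inclusive at both edges."""
    mask = _range_mask(spec.freqs, *band)
    if not mask.any():
        raise ValueError(f"band {band} selects no frequency bins")
    return Spectrum(
        freqs=spec.freqs[mask],
        power=spec.power[mask],
        df=spec.df,
        is_relative=spec.is_relative,
        norm_range=spec.norm_range,
    )
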