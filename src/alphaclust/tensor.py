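"""The relative-power tensor: (node, frequency step, subject)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PowerTensor:
    """Relative power values indexed by (node, frequency step, subject).

    ``values`` holds relative power in [0, 1]; ``freqs`` the frequency of
    each step in Hz; ``subject_ids`` aligns the last axis with a cohort
    table. Node ``i`` corresponds to row ``i`` of the companion SourceGrid.
    """

    values: np.ndarray       # (n_nodes, n_freqs, n_subjects)
    freqs: np.ndarray        # (n_freqs,), Hz
    subject_ids: np.ndarray  # (n_subjects,), str

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        freqs = np.asarray(self.freqs, dtype=float)
        subject_ids = np.asarray(self.subject_ids, dtype=object)
        if values.ndim != 3:
            raise ValueError("values must be 3-dimensional (node, freq, subject)")
        if freqs.shape != (values.shape[1],):
            raise ValueError("freqs length must match the frequency axis")
        if subject_ids.shape != (values.shape[2],):
            raise ValueError("subject_ids length must match the subject axis")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "subject_ids", subject_ids)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_freqs(self) -> int:
        return self.values.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[2]

    def validate(self) -> None:
        """Raise ValueError listing offending indices on NaN or out-of-range."""
        bad = ~np.isfinite(self.values)
        if bad.any():
            idx = np.argwhere(bad)[:5]
            raise ValueError(
                "non-finite power values at (node, freq, subject) indices "
                f"{[tuple(map(int, i)) for i in idx]}"
            )
        out = (self.values < 0) | (self.values > 1)
        if out.any():
            idx = np.argwhere(out)[:5]
            raise ValueError(
                "power values outside [0, 1] at (node, freq, subject) indices "
                f"{[tuple(map(int, i)) for i in idx]}"
            )


def freq_grid(band: tuple[float, float], df: float) -> np.ndarray:
    """Inclusive frequency grid band[0], band[0]+df, ..., band[1].

    Raises if the band is not an integer number of steps wide.
    """
    lo, hi = band
    n_steps = (hi - lo) / df
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"band {band} is not an integer multiple of df={df}")
    return lo + df * np.arange(int(round(n_steps)) + 1)
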