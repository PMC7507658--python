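"""File formats: TSV tables, HDF5 power tensors, JSON reports.

Tables (grid, cohort, result tables) are tab-separated UTF-8 with '.'
decimals; missing values are empty fields. The power tensor lives in an
HDF5 container with dimension labels stored alongside the values so the
on-disk axis order is free; loading normalizes to (node, freq, subject).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cohort import validate_cohort
from .cluster import ClusterResult, NullDistribution
from .grid import SourceGrid
from .spectral import Spectrum
from .tensor import PowerTensor

_DIMS = ("node", "freq_hz", "subject_id")


def write_grid_tsv(grid: SourceGrid, path) -> None:
    grid.to_frame().to_csv(path, sep="\t", index=False)


def read_grid_tsv(path) -> SourceGrid:
    df = pd.read_csv(path, sep="\t", dtype={"region_label": str})
    coords = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    labels = df["region_label"].fillna("").to_numpy(dtype=object)
    # infer lattice spacing from the smallest nonzero coordinate gap
    diffs = []
    for k in range(3):
        ax = np.unique(coords[:, k])
        if len(ax) > 1:
            diffs.append(np.diff(ax).min())
    spacing = float(min(diffs)) if diffs else 10.0
    return SourceGrid(coords=coords, spacing=spacing, region_labels=labels)


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="")


def read_cohort_tsv(path) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    validate_cohort(cohort)
    return cohort


def write_spectrum_tsv(spec: Spectrum, path) -> None:
    pd.DataFrame({"freq_hz": spec.freqs, "power": spec.power}).to_csv(
        path, sep="\t", index=False
    )


def read_spectrum_tsv(path, is_relative: bool = False, norm_range=None) -> Spectrum:
    df = pd.read_csv(path, sep="\t")
    freqs = df["freq_hz"].to_numpy(dtype=float)
    if len(freqs) < 2:
        raise ValueError("spectrum needs at least two bins to infer df")
    return Spectrum(
        freqs=freqs,
        power=df["power"].to_numpy(dtype=float),
        df=float(freqs[1] - freqs[0]),
        is_relative=is_relative,
        norm_range=norm_range,
    )


def write_power_tensor(tensor: PowerTensor, path) -> None:
    """Write the tensor with dimension labels; deterministic bytes per input."""
    with h5py.File(path, "w", track_order=False) as f:
        dset = f.create_dataset("power", data=tensor.values, track_times=False)
        dset.attrs["dims"] = _DIMS
        f.create_dataset("freq_hz", data=tensor.freqs, track_times=False)
        f.create_dataset(
            "subject_id",
            data=np.array([str(s) for s in tensor.subject_ids], dtype="S"),
            track_times=False,
        )
        f.create_dataset(
            "node", data=np.arange(tensor.n_nodes), track_times=False
        )


def read_power_tensor(path) -> PowerTensor:
    """Load and validate a power tensor, normalizing axis order.

    The container must carry a ``dims`` attribute naming the axes of the
    ``power`` dataset as a permutation of (node, freq_hz, subject_id).
    NaN values or values outside [0, 1] raise a validation error listing
    the offending indices.
    """
    with h5py.File(path, "r") as f:
        if "power" not in f:
            raise ValueError("container has no 'power' dataset")
        dset = f["power"]
        if "dims" not in dset.attrs:
            raise ValueError("power dataset is missing the 'dims' labels")
        dims = tuple(
            d.decode() if isinstance(d, bytes) else str(d)
            for d in dset.attrs["dims"]
        )
        if sorted(dims) != sorted(_DIMS):
            raise ValueError(
                f"dims must be a permutation of {_DIMS}, got {dims}"
            )
        values = np.transpose(dset[()], [dims.index(d) for d in _DIMS])
        freqs = f["freq_hz"][()]
        subject_ids = np.array(
            [s.decode() if isinstance(s, bytes) else str(s) for s in f["subject_id"][()]],
            dtype=object,
        )
    tensor = PowerTensor(values=values, freqs=freqs, subject_ids=subject_ids)
    tensor.validate()
    return tensor


def cluster_to_dict(cluster: ClusterResult, freqs: np.ndarray) -> dict:
    return {
        "sign": cluster.sign,
        "mass": cluster.mass,
        "fwer_p": cluster.fwer_p,
        "n_members": cluster.n_members,
        "n_nodes": int(len(np.unique(cluster.members[:, 0]))),
        "freq_range_hz": [
            float(freqs[cluster.members[:, 1].min()]),
            float(freqs[cluster.members[:, 1].max()]),
        ],
        "nodes_per_step": {
            f"{freqs[step]:g}": count
            for step, count in sorted(cluster.nodes_per_step.items())
        },
        "members": [[int(i), int(f)] for i, f in cluster.members],
    }


def write_clusters_json(clusters, freqs, path) -> None:
    payload = [cluster_to_dict(c, freqs) for c in clusters]
    Path(path).write_text(json.dumps(payload, indent=2))


def write_null_tsv(null: NullDistribution, path) -> None:
    pd.DataFrame({"max_abs_mass": null.max_abs_mass}).to_csv(
        path, sep="\t", index=False
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2))
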