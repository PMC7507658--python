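"""End-to-end orchestration: simulate -> analyze -> report.

``run_simulate`` writes a synthetic dataset (grid TSV, cohort TSV, power
tensor) from a config; ``run_analyze`` runs the full inference chain on a
dataset (correlation map, eligibility, clustering, max-statistic
permutation FWER, then per significant cluster: average power extraction,
moderation models, subgroup correlations, region coverage) and writes a
JSON report plus TSV tables. Both are pure functions of the config,
including its master seed, which expands into per-stage child seeds.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import fit_moderation, roi_coverage, subgroup_correlations
from .cluster import (
    ClusterParams,
    cluster_profile,
    extract_avg_power,
    permutation_test,
)
from .cohort import DEFAULT_STRATA_SIZES, generate_cohort
from .grid import SourceGrid, generate_grid
from .io import (
    cluster_to_dict,
    read_cohort_tsv,
    read_grid_tsv,
    read_power_tensor,
    write_cohort_tsv,
    write_clusters_json,
    write_grid_tsv,
    write_json,
    write_null_tsv,
    write_power_tensor,
)
from .simulate import BaselineParams, EffectSpec, generate_outcomes, generate_power

DEFAULT_SUBGROUPS = [
    "all",
    "E3/E3",
    "E3/E4",
    "young",
    "old",
    "young-E3/E3",
    "young-E3/E4",
    "old-E3/E3",
    "old-E3/E4",
]

DEFAULT_OUTCOMES = [
    "total_gm",
    "precuneus",
    "hippocampus",
    "episodic_memory",
    "working_memory",
]

#: Outcome effects planted by default: marker-outcome associations confined
#: to the highest-risk stratum, mirroring the structure the subgroup stage
#: is meant to detect.
DEFAULT_OUTCOME_SPECS = {
    "total_gm": (0.6, "old-E3/E4"),
    "precuneus": (0.5, "old-E3/E4"),
    "hippocampus": (0.25, "old-E3/E4"),
    "episodic_memory": (0.85, "old-E3/E4"),
    "working_memory": (0.6, "old-E3/E4"),
}


@dataclass
class SimulateParams:
    """Synthetic-dataset parameters (defaults emulate the study conditions)."""

    grid_shape: tuple[int, int, int] = (12, 12, 9)
    spacing: float = 10.0
    mask_fraction: float = 0.93
    strata_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_STRATA_SIZES)
    )
    tpa_mean: float = 0.012
    tpa_sd: float = 0.012
    effect_enabled: bool = True
    n_effect_nodes: int = 30
    effect_band: tuple[float, float] = (10.75, 13.0)
    effect_rho: float = 0.5
    affected_strata: str | tuple[str, ...] = "all"
    effect_noise_sd: float = 0.4
    outcome_specs: dict[str, tuple[float, str]] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_SPECS)
    )


@dataclass
class PipelineConfig:
    """Everything a simulate+analyze run depends on, seed included."""

    output_dir: str = "alphaclust_output"
    grid_path: str | None = None
    cohort_path: str | None = None
    tensor_path: str | None = None
    band: tuple[float, float] = (8.0, 14.0)
    df: float = 0.25
    cluster: ClusterParams = field(default_factory=ClusterParams)
    moderators: list[str] = field(
        default_factory=lambda: ["genotype", "age_group"]
    )
    subgroups: list[str] = field(default_factory=lambda: list(DEFAULT_SUBGROUPS))
    outcomes: list[str] = field(default_factory=lambda: list(DEFAULT_OUTCOMES))
    adjust_age_subgroups: bool = False
    simulate: SimulateParams = field(default_factory=SimulateParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cluster = ClusterParams(**raw.pop("cluster", {}))
        sim_raw = raw.pop("simulate", {})
        for key in ("grid_shape", "effect_band"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        if "outcome_specs" in sim_raw:
            sim_raw["outcome_specs"] = {
                k: tuple(v) for k, v in sim_raw["outcome_specs"].items()
            }
        simulate = SimulateParams(**sim_raw)
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        return cls(cluster=cluster, simulate=simulate, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic per-stage child seeds from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("grid", "cohort", "power", "outcomes", "permutation")
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, ss.spawn(len(names)))
        }


def pick_contiguous_nodes(
    grid: SourceGrid, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """A spatially contiguous set of ``n`` node indices, grown at random."""
    if n > grid.n_nodes:
        raise ValueError("requested more nodes than the grid contains")
    rng = np.random.default_rng(seed)
    pairs = grid.neighbor_pairs()
    adj: list[list[int]] = [[] for _ in range(grid.n_nodes)]
    for i, j in pairs:
        adj[i].append(int(j))
        adj[j].append(int(i))
    start = int(rng.integers(grid.n_nodes))
    selected = {start}
    frontier = sorted(set(adj[start]))
    while len(selected) < n and frontier:
        k = int(rng.integers(len(frontier)))
        node = frontier.pop(k)
        selected.add(node)
        for j in adj[node]:
            if j not in selected and j not in frontier:
                frontier.append(j)
    if len(selected) < n:
        raise ValueError("grid is too fragmented to grow a contiguous region")
    return np.array(sorted(selected), dtype=np.intp)


def _dataset_paths(config: PipelineConfig) -> dict[str, Path]:
    out = Path(config.output_dir)
    return {
        "grid": Path(config.grid_path) if config.grid_path else out / "grid.tsv",
        "cohort": Path(config.cohort_path)
        if config.cohort_path
        else out / "cohort.tsv",
        "tensor": Path(config.tensor_path)
        if config.tensor_path
        else out / "power.h5",
    }


def run_simulate(config: PipelineConfig) -> dict[str, str]:
    """Generate and write a synthetic dataset; returns the file paths."""
    sp = config.simulate
    if sum(sp.strata_sizes.values()) == 0:
        raise ValueError("simulate.strata_sizes request zero subjects")
    seeds = config.stage_seeds()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    grid = generate_grid(
        *sp.grid_shape,
        spacing=sp.spacing,
        mask_fraction=sp.mask_fraction,
        seed=seeds["grid"],
    )
    cohort = generate_cohort(
        strata_sizes=sp.strata_sizes,
        tpa_mean=sp.tpa_mean,
        tpa_sd=sp.tpa_sd,
        seed=seeds["cohort"],
    )
    effect = None
    if sp.effect_enabled:
        target = pick_contiguous_nodes(grid, sp.n_effect_nodes, seeds["grid"] + 1)
        effect = EffectSpec(
            target_nodes=target,
            freq_band=sp.effect_band,
            target_rho=sp.effect_rho,
            affected_strata=sp.affected_strata,
            noise_sd=sp.effect_noise_sd,
        )
    tensor = generate_power(
        grid, cohort, effect, band=config.band, df=config.df, seed=seeds["power"]
    )
    if sp.outcome_specs:
        # outcomes follow the average power over the planted support (or the
        # whole-tensor average when no effect is planted)
        if effect is not None:
            fmask = (tensor.freqs >= sp.effect_band[0] - 1e-9) & (
                tensor.freqs <= sp.effect_band[1] + 1e-9
            )
            marker = tensor.values[np.ix_(effect.target_nodes, np.flatnonzero(fmask))].mean(
                axis=(0, 1)
            )
        else:
            marker = tensor.values.mean(axis=(0, 1))
        cohort = generate_outcomes(
            cohort, marker, sp.outcome_specs, seed=seeds["outcomes"]
        )

    paths = _dataset_paths(config)
    write_grid_tsv(grid, paths["grid"])
    write_cohort_tsv(cohort, paths["cohort"])
    write_power_tensor(tensor, paths["tensor"])
    write_json(
        {"config": config.to_dict(), "stage_seeds": seeds, "software_version": __version__},
        out / "simulate_manifest.json",
    )
    if effect is not None:
        write_json(
            {
                "target_nodes": effect.target_nodes,
                "freq_band": list(effect.freq_band),
                "target_rho": effect.target_rho,
                "affected_strata": effect.affected_strata,
            },
            out / "planted_effect.json",
        )
    return {k: str(v) for k, v in paths.items()}


def run_analyze(config: PipelineConfig) -> dict:
    """Run the full inference chain on a dataset and write the report.

    Subjects are aligned between cohort and tensor by id (never by row
    order); a mismatch raises naming the offending ids. Absence of a
    significant cluster yields a report with an empty cluster section.
    """
    t0 = time.time()
    paths = _dataset_paths(config)
    grid = read_grid_tsv(paths["grid"])
    cohort = read_cohort_tsv(paths["cohort"])
    tensor = read_power_tensor(paths["tensor"])

    tensor_ids = [str(s) for s in tensor.subject_ids]
    cohort_ids = set(cohort["subject_id"])
    missing = [s for s in tensor_ids if s not in cohort_ids]
    extra = sorted(cohort_ids - set(tensor_ids))
    if missing or extra:
        raise ValueError(
            f"subject id mismatch: tensor-only {missing[:5]}, cohort-only {extra[:5]}"
        )
    cohort = cohort.set_index("subject_id").loc[tensor_ids].reset_index()

    seeds = config.stage_seeds()
    params = dataclasses.replace(config.cluster, seed=seeds["permutation"])
    timings = {}
    t = time.time()
    clusters, null = permutation_test(
        tensor, cohort["tpa"].to_numpy(), cohort["age"].to_numpy(), grid, params
    )
    timings["permutation_s"] = time.time() - t

    significant = [c for c in clusters if c.fwer_p < params.alpha_fwer]
    cluster_reports = []
    for rank, cluster in enumerate(significant):
        avg_power = extract_avg_power(tensor, cluster)
        entry = cluster_to_dict(cluster, tensor.freqs)
        entry["rank"] = rank
        entry["avg_power_by_subject"] = {
            str(s): float(v) for s, v in zip(tensor.subject_ids, avg_power)
        }

        moderations = {}
        for moderator in config.moderators:
            if moderator == "genotype":
                m = (cohort["genotype"] == "E3/E4").astype(float).to_numpy()
            elif moderator == "age_group":
                m = (cohort["age_group"] == "old").astype(float).to_numpy()
            else:
                raise ValueError(f"unknown moderator: {moderator!r}")
            res = fit_moderation(
                avg_power, cohort["tpa"].to_numpy(), m, moderator_name=moderator
            )
            moderations[moderator] = dataclasses.asdict(res)
        entry["moderation"] = moderations

        outcomes_present = [c for c in config.outcomes if c in cohort.columns]
        subgroup_rows = [
            dataclasses.asdict(r)
            for r in subgroup_correlations(
                avg_power,
                cohort,
                config.subgroups,
                ["tpa"] + outcomes_present,
                adjust_age=config.adjust_age_subgroups,
            )
        ]
        entry["subgroup_correlations"] = subgroup_rows
        entry["roi_coverage"] = roi_coverage(cluster, grid).to_dict("records")
        cluster_reports.append(entry)

    report = {
        "schema_version": 1,
        "software_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "n_subjects": tensor.n_subjects,
        "n_nodes": tensor.n_nodes,
        "n_freqs": tensor.n_freqs,
        "all_clusters": [
            {
                "sign": c.sign,
                "mass": c.mass,
                "fwer_p": c.fwer_p,
                "n_members": c.n_members,
            }
            for c in clusters
        ],
        "significant_clusters": cluster_reports,
        "null_distribution": {
            "n_permutations": null.n_permutations,
            "quantiles": {
                q: float(np.quantile(null.max_abs_mass, float(q)))
                for q in ("0.5", "0.9", "0.95", "0.99")
            },
            "fraction_zero": float((null.max_abs_mass == 0).mean()),
        },
        "timings_s": {**timings, "total_s": time.time() - t0},
    }

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(report, out / "report.json")
    write_null_tsv(null, out / "null_distribution.tsv")
    write_clusters_json(clusters, tensor.freqs, out / "clusters.json")
    write_report_tables(report, out)
    return report


def write_report_tables(report: dict, out_dir) -> None:
    """Emit per-cluster TSV tables (subgroup correlations, region coverage,
    cluster-extent profile) from a report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for entry in report.get("significant_clusters", []):
        rank = entry["rank"]
        pd.DataFrame(entry["subgroup_correlations"]).to_csv(
            out / f"cluster{rank}_subgroup_correlations.tsv", sep="\t", index=False
        )
        pd.DataFrame(entry["roi_coverage"]).to_csv(
            out / f"cluster{rank}_roi_coverage.tsv", sep="\t", index=False
        )
        profile = pd.DataFrame(
            {
                "freq_hz": list(entry["nodes_per_step"].keys()),
                "n_nodes": list(entry["nodes_per_step"].values()),
            }
        )
        profile.to_csv(out / f"cluster{rank}_profile.tsv", sep="\t", index=False)
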