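"""Operating-characteristic experiments for the cluster pipeline.

Self-contained experiments that measure, on synthetic data with known
ground truth, the two properties a permutation cluster test must have:
correct family-wise error under the null and the ability to recover a
planted spatio-spectral effect. Problem sizes default to a desk-scale
setting (a ~150-node grid, 25 frequency steps) that keeps a full
calibration run in the minutes range on one CPU.
"""

from __future__ import annotations

import numpy as np

from .cluster import ClusterParams, permutation_test
from .cohort import generate_cohort
from .grid import generate_grid
from .pipeline import pick_contiguous_nodes
from .simulate import EffectSpec, generate_power

#: 60-subject cohort used by the null calibration, strata roughly in the
#: proportions of the full design.
CALIBRATION_STRATA = {
    "young-E3/E3": 24,
    "young-E3/E4": 11,
    "old-E3/E3": 16,
    "old-E3/E4": 9,
}


def _calibration_grid(seed: int):
    # 8 x 8 x 3 lattice at 78% mask -> 150 nodes
    return generate_grid(8, 8, 3, spacing=10.0, mask_fraction=0.78, seed=seed)


def _child_seeds(seed: int, n: int, k: int = 4) -> np.ndarray:
    """n x k table of independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return np.array(
        [child.generate_state(k) % (2**31) for child in ss.spawn(n)], dtype=np.int64
    )


def fwer_calibration(
    n_datasets: int = 100,
    n_subjects_strata: dict | None = None,
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical family-wise error rate on null synthetic datasets.

    Generates ``n_datasets`` datasets with no planted effect (exposure
    independent of power), runs the full permutation pipeline on each, and
    reports the fraction of datasets yielding any cluster with
    ``fwer_p < alpha``. For a calibrated max-statistic test this fraction
    should sit near ``alpha``.
    """
    strata = n_subjects_strata or dict(CALIBRATION_STRATA)
    seeds = _child_seeds(seed, n_datasets)
    rejections = 0
    any_cluster = 0
    for k in range(n_datasets):
        grid = _calibration_grid(int(seeds[k, 0]))
        cohort = generate_cohort(strata, seed=int(seeds[k, 1]))
        tensor = generate_power(grid, cohort, effect=None, seed=int(seeds[k, 2]))
        params = ClusterParams(n_permutations=n_permutations, seed=int(seeds[k, 3]))
        clusters, _ = permutation_test(
            tensor,
            cohort["tpa"].to_numpy(),
            cohort["age"].to_numpy(),
            grid,
            params,
        )
        if clusters:
            any_cluster += 1
        if any(c.fwer_p < alpha for c in clusters):
            rejections += 1
    return {
        "rejection_rate": rejections / n_datasets,
        "n_rejections": rejections,
        "n_datasets": n_datasets,
        "fraction_with_any_cluster": any_cluster / n_datasets,
        "alpha": alpha,
    }


def planted_recovery(
    n_seeds: int = 20,
    target_rho: float = 0.5,
    n_effect_nodes: int = 30,
    effect_band: tuple[float, float] = (10.75, 13.0),
    n_permutations: int = 500,
    alpha: float = 0.05,
    jaccard_min: float = 0.5,
    seed: int = 0,
) -> dict:
    """Recovery of a planted effect: significance and spatial overlap.

    For each seed, plants an exposure-power correlation of ``target_rho``
    in a contiguous ``n_effect_nodes``-node region over ``effect_band`` in
    a 113-subject cohort, runs the pipeline, and scores whether the
    largest cluster is significant at ``alpha`` with Jaccard overlap of at
    least ``jaccard_min`` against the planted (node, freq) support.
    """
    seeds = _child_seeds(seed, n_seeds, k=5)
    successes = 0
    jaccards = []
    pvals = []
    for k in range(n_seeds):
        grid = _calibration_grid(int(seeds[k, 0]))
        cohort = generate_cohort(seed=int(seeds[k, 1]))
        nodes = pick_contiguous_nodes(grid, n_effect_nodes, int(seeds[k, 2]))
        effect = EffectSpec(
            target_nodes=nodes, freq_band=effect_band, target_rho=target_rho
        )
        tensor = generate_power(grid, cohort, effect, seed=int(seeds[k, 3]))
        fsteps = np.flatnonzero(
            (tensor.freqs >= effect_band[0] - 1e-9)
            & (tensor.freqs <= effect_band[1] + 1e-9)
        )
        planted = {(int(i), int(f)) for i in nodes for f in fsteps}
        params = ClusterParams(n_permutations=n_permutations, seed=int(seeds[k, 4]))
        clusters, _ = permutation_test(
            tensor,
            cohort["tpa"].to_numpy(),
            cohort["age"].to_numpy(),
            grid,
            params,
        )
        if not clusters:
            jaccards.append(0.0)
            pvals.append(1.0)
            continue
        top = max(clusters, key=lambda c: abs(c.mass))
        overlap = top.member_set & planted
        jac = len(overlap) / len(top.member_set | planted)
        jaccards.append(jac)
        pvals.append(top.fwer_p)
        if top.fwer_p < alpha and jac >= jaccard_min:
            successes += 1
    return {
        "recovery_rate": successes / n_seeds,
        "n_successes": successes,
        "n_seeds": n_seeds,
        "median_jaccard": float(np.median(jaccards)),
        "median_top_p": float(np.median(pvals)),
    }
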