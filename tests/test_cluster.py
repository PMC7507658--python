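"""Eligibility masks, cluster construction, and the flood-fill oracle."""

import numpy as np
import pytest

from alphaclust import (
    ClusterParams,
    CorrelationMap,
    build_clusters,
    cluster_profile,
    correlation_map,
    eligible_cells,
    extract_avg_power,
    generate_cohort,
    generate_grid,
    generate_power,
)
from alphaclust.cluster import ClusterResult, _signed_mask
from alphaclust.tensor import PowerTensor
from conftest import oracle_clusters


def map_from(rho, pval):
    return CorrelationMap(rho=rho, pval=pval, n_subjects=50)


class TestEligibleCells:
    def _map(self, sig_steps, signs, n_freqs=10):
        rho = np.zeros((1, n_freqs))
        pval = np.ones((1, n_freqs))
        for step, sign in zip(sig_steps, signs):
            rho[0, step] = 0.5 * sign
            pval[0, step] = 0.001
        return map_from(rho, pval)

    def test_run_of_two_is_too_short(self):
        cmap = self._map([4, 5], [1, 1])
        mask = eligible_cells(cmap, ClusterParams())
        assert not mask.any()

    def test_ten_step_run_fully_eligible(self):
        cmap = self._map(range(10), [1] * 10)
        mask = eligible_cells(cmap, ClusterParams())
        assert mask.sum() == 10

    def test_sign_flip_breaks_run(self):
        cmap = self._map([3, 4, 5], [1, 1, -1])
        mask = eligible_cells(cmap, ClusterParams())
        assert not mask.any()

    def test_undefined_cells_never_eligible(self):
        rho = np.full((2, 5), np.nan)
        pval = np.full((2, 5), np.nan)
        mask = eligible_cells(map_from(rho, pval), ClusterParams())
        assert not mask.any()

    def test_mask_monotone_in_p_threshold(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            rho = rng.uniform(-1, 1, (10, 12))
            pval = rng.uniform(0, 0.05, (10, 12))
            strict = eligible_cells(map_from(rho, pval), ClusterParams(p_thresh=0.01))
            lenient = eligible_cells(map_from(rho, pval), ClusterParams(p_thresh=0.04))
            assert np.all((strict != 0) <= (lenient != 0))


class TestCorrelationMap:
    def test_cell_equal_to_exposure_has_rho_one(self, chain_grid, small_cohort):
        tensor = generate_power(chain_grid, small_cohort, seed=0)
        values = tensor.values.copy()
        tpa = small_cohort["tpa"].to_numpy()
        values[2, 3, :] = tpa / (2 * tpa.max())
        tensor = PowerTensor(values, tensor.freqs, tensor.subject_ids)
        cmap = correlation_map(tensor, tpa, np.ones(len(small_cohort)))
        assert cmap.rho[2, 3] == pytest.approx(1.0)
        assert cmap.shape == (chain_grid.n_nodes, tensor.n_freqs)

    def test_misaligned_subject_ids_error(self, chain_grid, small_cohort):
        import pandas as pd

        tensor = generate_power(chain_grid, small_cohort, seed=0)
        exposure = pd.Series(
            small_cohort["tpa"].to_numpy(), index=small_cohort["subject_id"]
        ).iloc[:-2]
        with pytest.raises(ValueError, match="missing subject ids"):
            correlation_map(tensor, exposure, small_cohort["age"].to_numpy())

    def test_type_one_error_rate_calibrated(self):
        # null tensor: fraction of cells with p < 0.01 within binomial bounds
        from scipy.stats import binom

        rng = np.random.default_rng(12)
        n, cells, reps = 60, 200, 40
        hits, total = 0, 0
        for _ in range(reps):
            values = rng.random((cells, 1, n)) * 0.5
            tensor = PowerTensor(
                values, np.array([10.0]), np.array([f"s{i}" for i in range(n)])
            )
            cmap = correlation_map(tensor, rng.normal(size=n), rng.normal(size=n))
            hits += int((cmap.pval < 0.01).sum())
            total += cells
        lo, hi = binom.ppf([0.005, 0.995], total, 0.01)
        assert lo <= hits <= hi


class TestBuildClusters:
    def test_empty_mask_gives_no_clusters(self, chain_grid):
        mask = np.zeros((5, 6), dtype=np.int8)
        assert build_clusters(mask, np.zeros((5, 6)), chain_grid, ClusterParams()) == []

    def test_block_with_isolated_cell_matches_oracle(self, chain_grid):
        # 3-node x 4-step positive block plus one isolated cell
        mask = np.zeros((5, 6), dtype=np.int8)
        mask[0:3, 1:5] = 1
        mask[4, 0] = 1
        rng = np.random.default_rng(1)
        rho = rng.uniform(0.3, 0.9, (5, 6)) * (mask != 0)
        params = ClusterParams(spatial_neighbor_dist=11.0)
        clusters = build_clusters(mask, rho, chain_grid, params)
        assert len(clusters) == 1
        assert clusters[0].n_members == 12
        oracle = oracle_clusters(mask, rho, chain_grid.coords, 11.0, 3, 1)
        assert len(oracle) == 1
        assert clusters[0].member_set == set(oracle[0][0])
        assert clusters[0].mass == pytest.approx(oracle[0][1])

    def test_separated_blocks_form_two_clusters(self, chain_grid):
        mask = np.zeros((5, 6), dtype=np.int8)
        mask[0:2, 0:3] = 1   # nodes 0-1
        mask[3:5, 3:6] = 1   # nodes 3-4, disjoint in space and frequency
        rho = 0.5 * mask
        clusters = build_clusters(
            mask, rho, chain_grid, ClusterParams(spatial_neighbor_dist=11.0)
        )
        assert len(clusters) == 2

    def test_opposite_sign_blocks_stay_separate(self, chain_grid):
        mask = np.zeros((5, 6), dtype=np.int8)
        mask[0:2, 0:3] = 1
        mask[2:4, 0:3] = -1
        rho = 0.5 * mask
        clusters = build_clusters(
            mask, rho, chain_grid, ClusterParams(spatial_neighbor_dist=11.0)
        )
        assert len(clusters) == 2
        assert {c.sign for c in clusters} == {1, -1}
        for c in clusters:
            assert np.sign(c.mass) == c.sign

    @pytest.mark.parametrize("policy", ["trim", "reject"])
    def test_random_masks_match_flood_fill_oracle(self, policy):
        rng = np.random.default_rng(42)
        coords = np.column_stack(
            [np.repeat(np.arange(5), 4) * 10.0, np.tile(np.arange(4), 5) * 10.0,
             np.zeros(20)]
        )
        from alphaclust import SourceGrid

        grid = SourceGrid(coords=coords, spacing=10.0)
        params = ClusterParams(
            spatial_neighbor_dist=11.0,
            min_consecutive_steps=2,
            min_nodes_fraction=0.1,  # threshold = max(1, floor(2)) = 2 nodes
            under_threshold_policy=policy,
        )
        for _ in range(30):
            rho = rng.uniform(-1, 1, (20, 6))
            mask = ((np.abs(rho) > 0.55) * np.sign(rho)).astype(np.int8)
            got = build_clusters(mask, rho, grid, params)
            want = oracle_clusters(mask, rho, coords, 11.0, 2, 2, policy)
            assert len(got) == len(want)
            want_sets = {m for m, _ in want}
            for c in got:
                assert frozenset(c.member_set) in want_sets

    def test_min_nodes_threshold_matches_study_scale(self):
        assert ClusterParams().min_nodes_per_step(1202) == 12


class TestClusterHelpers:
    @pytest.fixture
    def toy_cluster(self):
        members = np.array([[i, f] for i in range(3) for f in range(2, 6)])
        return ClusterResult(
            members=members,
            sign=1,
            mass=6.0,
            nodes_per_step={2: 3, 3: 3, 4: 3, 5: 3},
        )

    def test_profile_counts_and_conservation(self, toy_cluster):
        profile = cluster_profile(toy_cluster)
        assert (profile == 3).all()
        assert profile.sum() == toy_cluster.n_members

    def test_avg_power_constant_inside_members(self, toy_cluster, chain_grid, small_cohort):
        tensor = generate_power(chain_grid, small_cohort, seed=3)
        values = tensor.values.copy()
        m = toy_cluster.members
        values[m[:, 0], m[:, 1], :] = 0.125
        tensor = PowerTensor(values, tensor.freqs, tensor.subject_ids)
        avg = extract_avg_power(tensor, toy_cluster)
        assert np.allclose(avg, 0.125)

    def test_two_member_average(self, chain_grid, small_cohort):
        tensor = generate_power(chain_grid, small_cohort, seed=4)
        cluster = ClusterResult(
            members=np.array([[0, 0], [1, 0]]), sign=1, mass=1.0,
            nodes_per_step={0: 2},
        )
        avg = extract_avg_power(tensor, cluster)
        expected = (tensor.values[0, 0] + tensor.values[1, 0]) / 2
        assert np.allclose(avg, expected)

    def test_empty_cluster_errors(self, chain_grid, small_cohort):
        tensor = generate_power(chain_grid, small_cohort, seed=5)
        cluster = ClusterResult(
            members=np.empty((0, 2), dtype=int), sign=1, mass=0.0, nodes_per_step={}
        )
        with pytest.raises(ValueError):
            extract_avg_power(tensor, cluster)
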