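"""Max-statistic permutation inference: exactness, determinism, exchangeability."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata, t as t_dist

from alphaclust import (
    ClusterParams,
    EffectSpec,
    generate_cohort,
    generate_grid,
    generate_power,
    permutation_test,
    pick_contiguous_nodes,
)
from alphaclust.grid import SourceGrid
from alphaclust.tensor import PowerTensor


def exhaustive_oracle(values, x, z, p_thresh, min_steps):
    """Exact exhaustive-permutation p for a single-node tensor.

    Independent implementation: ordinary loops, scipy ranks, the
    rank-residual partial correlation, a run-based cluster rule along
    frequency, enumeration of all orderings of the exposure.
    """
    n = len(x)

    def pcorr(a, b, c):
        ra, rb, rc = rankdata(a), rankdata(b), rankdata(c)
        design = np.column_stack([np.ones(n), rc])
        ea = ra - design @ np.linalg.lstsq(design, ra, rcond=None)[0]
        eb = rb - design @ np.linalg.lstsq(design, rb, rcond=None)[0]
        return float(ea @ eb / np.sqrt((ea @ ea) * (eb @ eb)))

    def pval(r):
        if abs(r) >= 1:
            return 0.0
        tt = r * np.sqrt((n - 3) / (1 - r * r))
        return 2 * t_dist.sf(abs(tt), n - 3)

    def max_mass(xx):
        rhos = [pcorr(xx, values[0, f, :], z) for f in range(values.shape[1])]
        sig = [pval(r) < p_thresh for r in rhos]
        best = 0.0
        f = 0
        n_f = len(rhos)
        while f < n_f:
            if sig[f]:
                s = np.sign(rhos[f])
                g = f
                while g < n_f and sig[g] and np.sign(rhos[g]) == s:
                    g += 1
                if g - f >= min_steps:
                    best = max(best, abs(sum(rhos[f:g])))
                f = g
            else:
                f += 1
        return best

    observed = max_mass(x)
    perms = list(itertools.permutations(range(n)))
    null = np.array([max_mass(x[np.array(p)]) for p in perms])
    p_exact = float((null >= observed).mean()) if observed > 0 else None
    return observed, null, p_exact


@pytest.fixture
def planted_setup():
    grid = generate_grid(6, 6, 2, mask_fraction=0.9, seed=0)
    cohort = generate_cohort(seed=1)
    effect = EffectSpec(
        target_nodes=pick_contiguous_nodes(grid, 12, seed=2),
        freq_band=(10.75, 13.0),
        target_rho=0.6,
    )
    tensor = generate_power(grid, cohort, effect, seed=3)
    return grid, cohort, tensor


class TestPermutationTest:
    def test_exhaustive_enumeration_matches_exact_p(self):
        # one node, 3 steps, n = 5: all 120 orderings enumerated
        rng = np.random.default_rng(8)
        n = 5
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        # strong monotone association at every step so a cluster forms
        values = 0.3 + 0.1 * np.tile(rankdata(x) / n, (1, 3, 1))
        values += rng.normal(0, 0.005, values.shape)
        tensor = PowerTensor(
            values, np.array([10.0, 10.25, 10.5]),
            np.array([f"s{i}" for i in range(n)]),
        )
        grid = SourceGrid(coords=np.array([[0.0, 0.0, 0.0]]), spacing=10.0)
        params = ClusterParams(
            p_thresh=0.3, min_consecutive_steps=1, min_nodes_fraction=0.0,
            n_permutations=120,
        )
        perms = np.array(list(itertools.permutations(range(n))))
        clusters, null = permutation_test(
            tensor, x, z, grid, params, permutation_source=perms
        )
        obs, null_oracle, p_exact = exhaustive_oracle(values, x, z, 0.3, 1)
        assert p_exact is not None
        assert len(clusters) >= 1
        top = max(clusters, key=lambda c: abs(c.mass))
        assert abs(top.mass) == pytest.approx(obs, abs=1e-12)
        assert np.allclose(np.sort(null.max_abs_mass), np.sort(null_oracle))
        assert top.fwer_p == pytest.approx(p_exact, abs=1e-12)

    def test_exact_p_invariant_to_subject_relabelling(self):
        rng = np.random.default_rng(3)
        n = 5
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        values = 0.3 + 0.1 * np.tile(rankdata(x) / n, (1, 3, 1))
        values += rng.normal(0, 0.01, values.shape)
        grid = SourceGrid(coords=np.array([[0.0, 0.0, 0.0]]), spacing=10.0)
        params = ClusterParams(
            p_thresh=0.3, min_consecutive_steps=1, min_nodes_fraction=0.0,
            n_permutations=120,
        )
        perms = np.array(list(itertools.permutations(range(n))))

        def run(order):
            tensor = PowerTensor(
                values[:, :, order], np.array([10.0, 10.25, 10.5]),
                np.array([f"s{i}" for i in range(n)]),
            )
            clusters, _ = permutation_test(
                tensor, x[order], z[order], grid, params, permutation_source=perms
            )
            return [c.fwer_p for c in clusters]

        assert run(np.arange(n)) == run(np.array([3, 1, 4, 0, 2]))

    def test_identical_seed_reproduces_p_values(self, planted_setup):
        grid, cohort, tensor = planted_setup
        params = ClusterParams(n_permutations=100, seed=5)
        tpa = cohort["tpa"].to_numpy()
        age = cohort["age"].to_numpy()
        c1, n1 = permutation_test(tensor, tpa, age, grid, params)
        c2, n2 = permutation_test(tensor, tpa, age, grid, params)
        assert [c.fwer_p for c in c1] == [c.fwer_p for c in c2]
        assert np.array_equal(n1.max_abs_mass, n2.max_abs_mass)

    @pytest.fixture
    def flat_setup(self):
        # independent cell noise only (no smooth subject fields): surrogate
        # clusters are essentially impossible, so the observed planted mass
        # dominates every permutation
        from alphaclust import BaselineParams

        flat = BaselineParams(
            global_log_sd=0.0, alpha_log_sd=0.0, peak_shift_sd=0.0,
            slope_sd=0.0, spatial_mod_sd=0.0, cell_log_sd=0.3,
        )
        grid = generate_grid(6, 6, 2, mask_fraction=0.9, seed=0)
        cohort = generate_cohort(seed=1)
        effect = EffectSpec(
            target_nodes=pick_contiguous_nodes(grid, 12, seed=2),
            freq_band=(10.75, 13.0),
            target_rho=0.85,
        )
        tensor = generate_power(grid, cohort, effect, seed=3, baseline=flat)
        return grid, cohort, tensor

    def test_strong_effect_reaches_p_zero(self, flat_setup):
        # plain-proportion convention: observed above every surrogate -> p = 0
        grid, cohort, tensor = flat_setup
        params = ClusterParams(n_permutations=50, seed=6)
        clusters, null = permutation_test(
            tensor, cohort["tpa"].to_numpy(), cohort["age"].to_numpy(), grid, params
        )
        top = clusters[0]
        assert abs(top.mass) > null.max_abs_mass.max()
        assert top.fwer_p == 0.0

    def test_smoothed_estimator_never_zero(self, flat_setup):
        grid, cohort, tensor = flat_setup
        params = ClusterParams(n_permutations=50, seed=6, p_estimator="smoothed")
        clusters, _ = permutation_test(
            tensor, cohort["tpa"].to_numpy(), cohort["age"].to_numpy(), grid, params
        )
        assert clusters[0].fwer_p == pytest.approx(1 / 51)

    def test_freedman_lane_variant_runs(self, planted_setup):
        grid, cohort, tensor = planted_setup
        params = ClusterParams(
            n_permutations=50, seed=7, permute_scheme="freedman_lane"
        )
        clusters, _ = permutation_test(
            tensor, cohort["tpa"].to_numpy(), cohort["age"].to_numpy(), grid, params
        )
        assert clusters and clusters[0].fwer_p < 0.05

    def test_too_few_subjects_error(self, chain_grid):
        values = np.full((5, 3, 3), 0.1)
        tensor = PowerTensor(
            values, np.array([10.0, 10.25, 10.5]), np.array(["a", "b", "c"])
        )
        with pytest.raises(ValueError):
            permutation_test(
                tensor, np.arange(3.0), np.arange(3.0), chain_grid, ClusterParams()
            )
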