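"""Loading competition, firing kinetics, and replication profiles."""

import numpy as np
import pytest
from scipy import stats

from mcmkit.genome import GenomeSpec
from mcmkit.loading import (
    FiringConfig,
    LoadingConfig,
    mean_field_loading,
    replicate_profile,
    retained_fraction,
    sample_firing_times,
    simulate_loading,
)

from conftest import build_origins


class TestSimulateLoading:
    def test_saturation_when_pool_exceeds_capacity(self):
        a = np.array([1.0, 2.0, 0.5])
        c = np.array([5.0, 3.0, 4.0])
        m, info = simulate_loading(a, c, LoadingConfig(pool=100, t_g1=1e6, seed=0))
        np.testing.assert_array_equal(m, c)
        assert info["n_free"] == 100 - 12

    def test_empty_pool_loads_nothing(self):
        m, _ = simulate_loading(
            np.array([1.0]), np.array([5.0]), LoadingConfig(pool=0, t_g1=10.0, seed=0)
        )
        assert m[0] == 0

    def test_zero_activity_warns(self):
        m, info = simulate_loading(
            np.zeros(3), np.full(3, np.inf),
            LoadingConfig(pool=10, t_g1=10.0, variant="orc_activity", seed=0),
        )
        assert not m.any()
        assert info["warnings"]

    def test_pool_conservation(self):
        a = np.array([0.5, 1.5, 1.0])
        c = np.array([10.0, 10.0, 10.0])
        m, info = simulate_loading(a, c, LoadingConfig(pool=20, t_g1=2.0, seed=3))
        assert m.sum() + info["n_free"] == 20

    def test_orc_activity_split_is_multinomial(self):
        # with constant relative propensities the final split of an
        # exhausted pool is multinomial(N, a / sum a)
        a = np.array([2.0, 1.0])
        c = np.full(2, np.inf)
        n, runs = 300, 400
        totals = np.zeros(2)
        for s in range(runs):
            m, _ = simulate_loading(
                a, c, LoadingConfig(pool=n, t_g1=1e12, variant="orc_activity", seed=s)
            )
            totals += m
        p = 2 / 3
        sigma = np.sqrt(runs * n * p * (1 - p))
        assert abs(totals[0] - runs * n * p) < 3 * sigma

    def test_variant_constraints_enforced(self):
        with pytest.raises(ValueError, match="infinite"):
            simulate_loading(
                np.array([1.0]), np.array([5.0]),
                LoadingConfig(pool=10, t_g1=10.0, variant="orc_activity"),
            )
        with pytest.raises(ValueError, match="equal"):
            simulate_loading(
                np.array([1.0, 2.0]), np.array([5.0, 5.0]),
                LoadingConfig(pool=10, t_g1=10.0, variant="capacity"),
            )


class TestMeanField:
    def test_single_origin_closed_form(self):
        # dm/dt = a * n, n = N - m  =>  m(t) = N (1 - exp(-a t))
        a, n, t = 0.5, 100, 3.0
        m = mean_field_loading(
            np.array([a]), np.array([np.inf]),
            LoadingConfig(pool=n, t_g1=t, variant="orc_activity"),
        )
        assert m[0] == pytest.approx(n * (1 - np.exp(-a * t)), rel=1e-9)

    def test_saturation_matches_stochastic(self):
        a = np.array([1.0, 2.0])
        c = np.array([4.0, 6.0])
        m = mean_field_loading(a, c, LoadingConfig(pool=50, t_g1=1e6))
        np.testing.assert_allclose(m, c)

    def test_exact_mean_for_unbounded_capacities(self):
        # without capacity freezing the propensities are linear, so the
        # stochastic mean follows the mean-field ODE exactly
        rng_master = np.random.default_rng(4)
        a = rng_master.uniform(0.1, 1.0, 5)
        c = np.full(5, np.inf)
        config = LoadingConfig(pool=30, t_g1=0.8, variant="hybrid")
        mf = mean_field_loading(a, c, config)
        runs = 4_000
        acc = np.zeros(5)
        acc2 = np.zeros(5)
        for s in range(runs):
            m, _ = simulate_loading(a, c, config, rng=np.random.default_rng(s))
            acc += m
            acc2 += m.astype(float) ** 2
        mean = acc / runs
        sem = np.sqrt(np.maximum(acc2 / runs - mean**2, 1e-12) / runs)
        np.testing.assert_array_less(np.abs(mf - mean), 3.5 * sem)

    def test_close_to_stochastic_mean_when_saturation_is_rare(self):
        # with finite capacities the mean-field freeze is a deterministic
        # approximation; in a regime where few origins saturate it tracks
        # the Monte-Carlo mean closely
        rng_master = np.random.default_rng(5)
        a = rng_master.uniform(0.1, 0.5, 5)
        c = np.full(5, 12.0)
        config = LoadingConfig(pool=25, t_g1=1.0)
        mf = mean_field_loading(a, c, config)
        runs = 2_000
        acc = np.zeros(5)
        for s in range(runs):
            m, _ = simulate_loading(a, c, config, rng=np.random.default_rng(10_000 + s))
            acc += m
        mean = acc / runs
        np.testing.assert_allclose(mf, mean, atol=0.2)


class TestRetainedFraction:
    def test_equal_occupancies_give_one(self):
        out = retained_fraction(np.array([3.0, 5.0]), np.array([3.0, 5.0]))
        np.testing.assert_allclose(out, 1.0)

    def test_zero_full_occupancy_is_nan(self):
        out = retained_fraction(np.array([0.0, 4.0]), np.array([0.0, 2.0]))
        assert np.isnan(out[0]) and out[1] == 0.5

    def test_orc_activity_reduction_is_proportional(self):
        # under the pure ORC-activity model a halved pool reduces every
        # origin by the same factor (within sampling noise): the rank
        # correlation between activity and retained fraction is null
        rng_master = np.random.default_rng(77)
        a = rng_master.uniform(0.5, 5.0, 20)
        c = np.full(20, np.inf)
        significant = 0
        for s in range(60):
            rng = np.random.default_rng(s)
            full, _ = simulate_loading(
                a, c, LoadingConfig(pool=2_000, t_g1=1e12, variant="orc_activity"),
                rng=rng,
            )
            red, _ = simulate_loading(
                a, c, LoadingConfig(pool=1_000, t_g1=1e12, variant="orc_activity"),
                rng=rng,
            )
            ret = retained_fraction(full, red)
            ok = np.isfinite(ret)
            if stats.spearmanr(a[ok], ret[ok]).pvalue < 0.05:
                significant += 1
        assert significant <= 12  # ~5% expected under the null

    def test_hybrid_reduction_favors_active_origins(self):
        from mcmkit.experiment import endogenous_pool, toy_origin_map
        from mcmkit.loading import origins_to_arrays

        _, origins = toy_origin_map(seed=5)
        act, cap = origins_to_arrays(origins)
        n0 = endogenous_pool(origins)
        positives = 0
        for s in range(40):
            rng = np.random.default_rng(s)
            full, _ = simulate_loading(act, cap, LoadingConfig(pool=n0, t_g1=90.0), rng=rng)
            red, _ = simulate_loading(
                act, cap, LoadingConfig(pool=int(0.07 * n0), t_g1=90.0), rng=rng
            )
            ret = retained_fraction(full, red)
            ok = np.isfinite(ret)
            positives += stats.spearmanr(act[ok], ret[ok]).statistic > 0
        assert positives >= 38


class TestFiring:
    def test_zero_occupancy_never_fires(self):
        ft = sample_firing_times(
            np.array([0.0, 2.0]), FiringConfig(rate=0.1, fork_speed=1_000, n_cells=5),
            seed=1,
        )
        assert np.isinf(ft[:, 0]).all() and np.isfinite(ft[:, 1]).all()

    def test_single_mcm_mean_rate(self):
        firing = FiringConfig(rate=0.1, fork_speed=1_000, n_cells=20_000)
        ft = sample_firing_times(np.array([1.0]), firing, seed=2)
        sem = 10.0 / np.sqrt(firing.n_cells)
        assert abs(ft.mean() - 10.0) < 3 * sem

    def test_multiple_mcms_accelerate_firing(self):
        # min of m exponential clocks: occupancy 4 at rate 0.1 -> mean 2.5
        firing = FiringConfig(rate=0.1, fork_speed=1_000, n_cells=10_000)
        ft = sample_firing_times(np.array([4.0]), firing, seed=3)
        sem = 2.5 / np.sqrt(firing.n_cells)
        assert abs(ft.mean() - 2.5) < 3 * sem


class TestReplicateProfile:
    def test_single_deterministic_origin_closed_form(self):
        genome = GenomeSpec(chromosomes={"chr1": 50_000})
        origins = build_origins([{"midpoint": 20_000, "acs": 20_000}])
        firing = FiringConfig(rate=0.1, fork_speed=1_000, n_cells=1)
        ft = np.array([[5.0]])
        prof, completion = replicate_profile(origins, ft, firing, genome)
        centers = np.arange(50) * 1_000 + 500
        expected = 5.0 + np.abs(centers - 20_000) / 1_000
        np.testing.assert_allclose(prof.trep["chr1"], expected)
        assert completion[0] == pytest.approx(expected.max())

    def test_two_origins_match_brute_force(self):
        genome = GenomeSpec(chromosomes={"chr1": 50_000})
        origins = build_origins(
            [{"midpoint": 10_000, "acs": 10_000}, {"midpoint": 35_000, "acs": 35_000}]
        )
        firing = FiringConfig(rate=0.1, fork_speed=1_500, n_cells=3)
        ft = np.array([[2.0, 9.0], [7.0, 1.0], [4.0, 4.0]])
        prof, _ = replicate_profile(origins, ft, firing, genome)
        for b in range(50):
            x = b * 1_000 + 500
            per_cell = sorted(
                min(
                    t + abs(x - pos) / 1_500
                    for t, pos in zip(cell, [10_000, 35_000])
                )
                for cell in ft
            )
            assert prof.trep["chr1"][b] == pytest.approx(per_cell[1])  # 2/3 median

    def test_passive_replication_fills_valley(self):
        # an origin that never fires is replicated passively by its neighbour
        genome = GenomeSpec(chromosomes={"chr1": 30_000})
        origins = build_origins(
            [{"midpoint": 5_000, "acs": 5_000}, {"midpoint": 25_000, "acs": 25_000}]
        )
        firing = FiringConfig(rate=0.1, fork_speed=1_000, n_cells=1)
        ft = np.array([[3.0, np.inf]])
        prof, _ = replicate_profile(origins, ft, firing, genome)
        assert np.isfinite(prof.trep["chr1"]).all()
        assert prof.trep["chr1"][24] == pytest.approx(3.0 + 19.5)

    def test_reduced_pool_delays_genome_mean(self):
        from mcmkit.experiment import endogenous_pool, toy_origin_map
        from mcmkit.loading import origins_to_arrays

        _, origins = toy_origin_map(seed=6)
        act, cap = origins_to_arrays(origins)
        genome = GenomeSpec(chromosomes={"chr1": 300_000, "chr2": 300_000})
        n0 = endogenous_pool(origins)
        firing = FiringConfig(rate=0.05, fork_speed=1_500, n_cells=30)
        wins = 0
        for s in range(25):
            rng = np.random.default_rng(s)
            means = []
            for pool in (n0, int(0.07 * n0)):
                occ = np.stack(
                    [
                        simulate_loading(act, cap, LoadingConfig(pool=pool, t_g1=90.0),
                                         rng=rng)[0]
                        for _ in range(firing.n_cells)
                    ]
                )
                ft = sample_firing_times(occ, firing, rng=rng)
                prof, _ = replicate_profile(origins, ft, firing, genome)
                means.append(np.nanmean(np.concatenate(list(prof.trep.values()))))
            wins += means[1] > means[0]
        assert wins >= 24
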