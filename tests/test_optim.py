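import numpy as np
import pytest
from scipy import stats as sps

from stentrisk.optim import (
    ALGORITHMS,
    OptimizerConfig,
    SearchSpace,
    baseline_optimize,
    init_population,
    iseq_optimize,
    logistic_chaos_sequence,
    mantegna_levy,
    mantegna_sigma,
    random_search,
    step_scale,
)


def sphere(X):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return (X**2).sum(axis=1)


class TestChaos:
    def test_direct_iteration(self):
        np.testing.assert_allclose(
            logistic_chaos_sequence(0.7, 2), [0.84, 0.5376], atol=1e-12
        )

    @pytest.mark.parametrize("x0", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_degenerate_orbits_rejected(self, x0):
        # e.g. 4 * 0.75 * 0.25 = 0.75 is a fixed point
        with pytest.raises(ValueError, match="redraw"):
            logistic_chaos_sequence(x0, 5)

    def test_values_stay_in_open_interval(self):
        seq = logistic_chaos_sequence(0.123, 10_000)
        assert (seq > 0).all() and (seq < 1).all()

    def test_long_run_histogram_matches_arcsine_density(self):
        seq = logistic_chaos_sequence(np.pi / 10, 100_000)
        # invariant density of the r=4 logistic map is Beta(1/2, 1/2)
        ks = sps.kstest(seq, sps.beta(0.5, 0.5).cdf)
        assert ks.statistic < 0.01


class TestLevy:
    def test_sigma_closed_form(self):
        assert mantegna_sigma(1.5) == pytest.approx(0.6966, abs=2e-4)

    def test_beta_two_limit_is_gaussian(self):
        # sin(pi * beta / 2) -> 0 as beta -> 2: the numerator scale vanishes
        # and the step tail approaches Gaussian; compare tail mass directly
        assert mantegna_sigma(2.0) == pytest.approx(0.0, abs=1e-6)
        heavy = mantegna_levy(1.5, 200_000, 11)
        light = mantegna_levy(1.95, 200_000, 11)
        # tail index ~beta: mass beyond 20x the median scales like 20^-beta
        tail = lambda s: np.mean(np.abs(s) > 20 * np.median(np.abs(s)))
        assert tail(heavy) > 2 * tail(light)

    @pytest.mark.parametrize("beta", [0.5, 1.0, 2.5])
    def test_invalid_beta_rejected(self, beta):
        with pytest.raises(ValueError):
            mantegna_levy(beta, 10, 0)

    def test_heavy_tail_variance_grows_with_n(self):
        steps = mantegna_levy(1.5, 200_000, 3)
        assert np.isfinite(np.median(np.abs(steps)))
        v_small = np.var(steps[:2_000])
        v_large = np.var(steps)
        assert v_large > 2 * v_small  # alpha-stable: sample variance diverges


class TestStepScale:
    def test_endpoints(self):
        assert step_scale(0, 100, 0.5) == 0.5
        assert step_scale(100, 100, 0.5) == pytest.approx(0.5 * np.exp(-4))

    def test_strictly_decreasing(self):
        vals = [step_scale(t, 50, 1.0) for t in range(51)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            step_scale(11, 10, 1.0)


class TestInitPopulation:
    def test_containment_and_determinism(self):
        space = SearchSpace(2, 0.0, 1.0)
        cfg = OptimizerConfig(pop_size=30, max_iters=10, seed=9)
        P1 = init_population(space, cfg)
        P2 = init_population(space, cfg)
        assert P1.shape == (30, 2)
        assert (P1 >= 0).all() and (P1 <= 1).all()
        np.testing.assert_array_equal(P1, P2)

    def test_chaotic_spreads_at_least_as_well_as_uniform(self):
        from scipy.spatial.distance import pdist

        space = SearchSpace(2, 0.0, 1.0)
        wins = 0
        trials = 30
        for seed in range(trials):
            chaotic = init_population(space, OptimizerConfig(pop_size=400, max_iters=1, seed=seed))
            uniform = init_population(
                space, OptimizerConfig(pop_size=400, max_iters=1, seed=seed, chaotic_init=False)
            )
            wins += pdist(chaotic).min() >= pdist(uniform).min()
        assert wins >= 0.5 * trials


class TestOptimizers:
    space2 = SearchSpace(2, -5.0, 5.0)
    cfg = OptimizerConfig(pop_size=30, max_iters=200, seed=1)

    def test_improved_sequoia_reaches_fine_precision_on_sphere(self):
        res = iseq_optimize(sphere, self.space2, self.cfg)
        assert res.best_fitness < 1e-6
        assert len(res.history) == 200

    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_every_algorithm_solves_sphere(self, algo):
        res = baseline_optimize(algo, sphere, self.space2, self.cfg)
        assert res.best_fitness < 1e-3

    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_history_monotone_and_consistent(self, algo):
        res = baseline_optimize(algo, sphere, self.space2,
                                OptimizerConfig(pop_size=12, max_iters=60, seed=3))
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))
        assert res.best_fitness == res.history[-1]
        assert ((res.best_position >= -5) & (res.best_position <= 5)).all()

    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_seeded_determinism(self, algo):
        cfg = OptimizerConfig(pop_size=10, max_iters=40, seed=7)
        r1 = baseline_optimize(algo, sphere, self.space2, cfg)
        r2 = baseline_optimize(algo, sphere, self.space2, cfg)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)
        assert r1.history == r2.history

    def test_nan_objective_discarded_with_warning(self):
        def bad(X):
            f = sphere(X)
            f[np.atleast_2d(X)[:, 0] > 4.0] = np.nan
            return f

        with pytest.warns(UserWarning, match="non-finite"):
            res = iseq_optimize(bad, self.space2, OptimizerConfig(pop_size=20, max_iters=30, seed=0))
        assert np.isfinite(res.best_fitness)

    def test_beats_random_search_on_rastrigin(self):
        def rastrigin(X):
            X = np.atleast_2d(np.asarray(X, dtype=float))
            return (X**2 - 10 * np.cos(2 * np.pi * X) + 10).sum(axis=1)

        space = SearchSpace(10, -5.12, 5.12)
        iseq_final, rand_final = [], []
        for seed in range(8):
            cfg = OptimizerConfig(pop_size=30, max_iters=150, seed=seed)
            res = iseq_optimize(rastrigin, space, cfg)
            rs = random_search(rastrigin, space, evals=res.evals, seed=seed)
            iseq_final.append(res.best_fitness)
            rand_final.append(rs.best_fitness)
        assert np.median(iseq_final) < np.median(rand_final)
        w = sps.wilcoxon(iseq_final, rand_final, alternative="less")
        assert w.pvalue < 0.01

    def test_gwo_vs_ga_comparison_recorded(self):
        # directional observation, not a hard contract
        space = SearchSpace(10, -100.0, 100.0)
        gwo = [baseline_optimize("GWO", sphere, space,
                                 OptimizerConfig(pop_size=20, max_iters=100, seed=s)).best_fitness
               for s in range(5)]
        ga = [baseline_optimize("GA", sphere, space,
                                OptimizerConfig(pop_size=20, max_iters=100, seed=s)).best_fitness
              for s in range(5)]
        assert np.isfinite(np.median(gwo)) and np.isfinite(np.median(ga))

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            baseline_optimize("SGD", sphere, self.space2, self.cfg)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            OptimizerConfig(pop_size=1)
        with pytest.raises(ValueError):
            OptimizerConfig(levy_beta=2.5)
        with pytest.raises(ValueError):
            SearchSpace(2, 1.0, 1.0)
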