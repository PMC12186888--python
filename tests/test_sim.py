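"""Unit and property tests for the stochastic heteroplasmy simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtdrift.sim import (
    PopulationState,
    SimulationParams,
    cell_phenotype,
    daughter_counts,
    init_population,
    run_simulation,
    step,
    summarize,
)


class TestCellPhenotype:
    @pytest.mark.parametrize(
        "w, m, tau, expected",
        [
            (9, 11, 0.5, "petite"),  # mutant majority
            (20, 0, 0.5, "grande"),  # homoplasmic wild type
            (10, 10, 0.5, "grande"),  # tie at the threshold is grande
            (0, 20, 0.5, "petite"),
            (1, 19, 0.96, "grande"),  # 0.95 not > 0.96
        ],
    )
    def test_threshold_rule(self, w, m, tau, expected):
        assert cell_phenotype(w, m, tau) == expected

    def test_rho0_cell_rejected(self):
        with pytest.raises(ValueError):
            cell_phenotype(0, 0, 0.5)


class TestDaughterCounts:
    def test_each_daughter_has_n_molecules(self, rng):
        for mode in ("independent_binomial", "partition_hypergeometric"):
            (w1, m1), (w2, m2) = daughter_counts(12, 8, 1.4, 20, mode=mode, rng=rng)
            assert w1 + m1 == 20 and w2 + m2 == 20
            assert min(w1, m1, w2, m2) >= 0

    @pytest.mark.parametrize("mode", ["independent_binomial", "partition_hypergeometric"])
    @pytest.mark.parametrize("w, m", [(0, 20), (20, 0)])
    def test_homoplasmic_parent_stays_homoplasmic(self, rng, mode, w, m):
        for _ in range(20):
            (w1, m1), (w2, m2) = daughter_counts(w, m, 0.7, 20, mode=mode, rng=rng)
            assert (w1, m1) == (w, m) and (w2, m2) == (w, m)

    def test_mismatched_total_rejected(self, rng):
        with pytest.raises(ValueError):
            daughter_counts(5, 5, 1.0, 20, rng=rng)

    def test_negative_fitness_rejected(self, rng):
        with pytest.raises(ValueError):
            daughter_counts(10, 10, -0.1, 20, rng=rng)

    def test_amplified_mean_with_advantage(self, rng):
        # w=10, m=10, f=1.5: amplified mutant fraction p = 15/25 = 0.6,
        # so the expected daughter mutant count is 12.
        n_draws = 4000
        muts = np.empty(2 * n_draws)
        for i in range(n_draws):
            (_, m1), (_, m2) = daughter_counts(10, 10, 1.5, 20, rng=rng)
            muts[2 * i] = m1
            muts[2 * i + 1] = m2
        se = np.sqrt(20 * 0.6 * 0.4 / muts.size)
        assert abs(muts.mean() - 12.0) < 3 * se

    def test_zero_fitness_purges_mutants(self, rng):
        for _ in range(20):
            (_, m1), (_, m2) = daughter_counts(10, 10, 0.0, 20, rng=rng)
            assert m1 == 0 and m2 == 0

    def test_hypergeometric_small_n_distribution(self, rng):
        # w=1, m=1, f=1, n=2: amplified pool {W=2, M=2}; daughter mutant
        # count is Hypergeometric(4, 2, 2) with pmf {0: 1/6, 1: 4/6, 2: 1/6}.
        counts = np.zeros(3)
        n_draws = 30000
        for _ in range(n_draws):
            (_, m1), _ = daughter_counts(1, 1, 1.0, 2, mode="partition_hypergeometric", rng=rng)
            counts[m1] += 1
        expected = np.array([1 / 6, 4 / 6, 1 / 6])
        tvd = 0.5 * np.abs(counts / n_draws - expected).sum()
        assert tvd < 0.02


class TestInitPopulation:
    def test_deterministic_composition(self, rng):
        params = SimulationParams(n_cells_init=100, h0=0.25)
        state = init_population(params, rng)
        assert state.n_cells == 100
        assert np.all(state.wt == 15)
        assert np.all(state.mut == 5)

    @pytest.mark.parametrize("h0, wt", [(0.0, 20), (1.0, 0)])
    def test_homoplasmic_extremes(self, rng, h0, wt):
        params = SimulationParams(n_cells_init=50, h0=h0)
        state = init_population(params, rng)
        assert np.all(state.wt == wt)

    def test_initial_ages_below_doubling_time(self, rng):
        params = SimulationParams(n_cells_init=500, h0=0.8)  # petite cells
        state = init_population(params, rng)
        assert np.all(state.ages_min >= 0)
        assert np.all(state.ages_min < params.t_petite_min)

    def test_binomial_init_mode(self, rng):
        params = SimulationParams(n_cells_init=2000, h0=0.3, init_mode="binomial")
        state = init_population(params, rng)
        assert not np.all(state.mut == state.mut[0])  # composition varies
        assert abs(state.mut.mean() / 20 - 0.3) < 0.02


class TestStep:
    def test_grande_divides_at_140(self, rng):
        params = SimulationParams(h0=0.0)
        state = PopulationState(
            wt=np.array([20]), birth_min=np.array([-139.5]), t_now_min=0.0, n_copies=20
        )
        out = step(state, params, rng)
        assert out.n_cells == 2
        assert np.all(out.ages_min == 0.0)

    def test_petite_waits_for_210(self, rng):
        params = SimulationParams()
        state = PopulationState(
            wt=np.array([0]), birth_min=np.array([-139.5]), t_now_min=0.0, n_copies=20
        )
        out = step(state, params, rng)
        assert out.n_cells == 1
        assert out.ages_min[0] == pytest.approx(140.5)

    @settings(max_examples=25, deadline=None)
    @given(
        wt=st.lists(st.integers(0, 20), min_size=1, max_size=30),
        age_frac=st.floats(0, 0.999),
    )
    def test_population_never_shrinks_and_copy_number_conserved(self, wt, age_frac):
        params = SimulationParams()
        rng = np.random.default_rng(0)
        wt_arr = np.array(wt)
        state = PopulationState(
            wt=wt_arr,
            birth_min=-age_frac * np.full(len(wt), 139.0),
            t_now_min=0.0,
            n_copies=20,
        )
        sizes = [state.n_cells]
        for _ in range(5):
            state = step(state, params, rng)
            sizes.append(state.n_cells)
            assert np.all(state.wt >= 0) and np.all(state.wt <= 20)
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))


class TestSummarize:
    def test_three_fraction_partition(self):
        state = PopulationState(
            wt=np.array([0, 20, 10]), birth_min=np.zeros(3), t_now_min=0.0, n_copies=20
        )
        s = summarize(state)
        assert s.suppressivity == pytest.approx(1 / 3)
        assert s.wt_fixed_fraction == pytest.approx(1 / 3)
        assert s.het_fraction == pytest.approx(1 / 3)
        assert s.suppressivity + s.wt_fixed_fraction + s.het_fraction == pytest.approx(1.0)

    def test_all_mutant_population(self):
        state = PopulationState(
            wt=np.array([0, 0]), birth_min=np.zeros(2), t_now_min=0.0, n_copies=20
        )
        s = summarize(state)
        assert s.mean_mut_freq == 1.0
        assert s.suppressivity == 1.0

    def test_empty_population_rejected(self):
        state = PopulationState(
            wt=np.array([], dtype=int), birth_min=np.array([]), t_now_min=0.0, n_copies=20
        )
        with pytest.raises(ValueError):
            summarize(state)


class TestRunSimulation:
    @pytest.mark.parametrize("fitness", [0.0, 1.0, 2.0])
    def test_h0_zero_gives_zero_suppressivity(self, fitness):
        r = run_simulation(SimulationParams(h0=0.0, fitness=fitness, n_cells_init=100, seed=3))
        assert r.suppressivity == 0.0
        assert r.wt_fixed_fraction == 1.0

    @pytest.mark.parametrize("fitness", [0.0, 1.0, 2.0])
    def test_h0_one_gives_full_suppressivity(self, fitness):
        r = run_simulation(SimulationParams(h0=1.0, fitness=fitness, n_cells_init=100, seed=3))
        assert r.suppressivity == 1.0

    def test_deterministic_given_seed(self, fast_params):
        a = run_simulation(fast_params)
        b = run_simulation(fast_params)
        assert a.suppressivity == b.suppressivity
        assert np.array_equal(a.final_state.wt, b.final_state.wt)
        assert a.seed == fast_params.seed

    def test_population_grows(self, fast_params):
        r = run_simulation(fast_params)
        assert r.final_state.n_cells > fast_params.n_cells_init

    def test_trajectory_fractions_sum_to_one(self, fast_params):
        r = run_simulation(fast_params, record_every_min=60.0)
        tr = r.trajectory
        total = tr["suppressivity"] + tr["wt_fixed_fraction"] + tr["het_fraction"]
        assert np.allclose(total, 1.0)
        assert tr["time_min"].iloc[0] == 0.0

    def test_dt_insensitivity_of_mean_mut_freq(self):
        # the minute scheduler should not bias results vs a half-minute tick
        means = {}
        for dt in (0.5, 1.0):
            vals = [
                run_simulation(
                    SimulationParams(
                        h0=0.5, fitness=1.0, t_petite_min=140.0,
                        n_cells_init=200, t_total_min=700.0, dt_min=dt, seed=s,
                    )
                ).mean_mut_freq
                for s in range(5)
            ]
            means[dt] = np.mean(vals)
        assert abs(means[0.5] - means[1.0]) < 0.03

    def test_step_loop_matches_run_distributionally(self):
        # the event-driven runner and the literal per-tick loop agree on the
        # deterministic part of the dynamics: total cell count for h0=0
        params = SimulationParams(h0=0.0, n_cells_init=30, t_total_min=300.0, seed=11)
        rng = np.random.default_rng(params.seed)
        state = init_population(params, rng)
        for _ in range(300):
            state = step(state, params, rng)
        assert state.n_cells == run_simulation(params).final_state.n_cells


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_copies": 0},
            {"fitness": -1.0},
            {"threshold": 1.5},
            {"h0": -0.1},
            {"t_total_min": 100.0},  # below one grande doubling
            {"dt_min": 0.0},
            {"division_mode": "bogus"},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationParams(**kwargs)
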