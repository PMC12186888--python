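"""Tests for the suppressivity grid and kNN fitness inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtdrift.fitness import (
    StrainObservation,
    build_suppressivity_grid,
    estimate_panel,
    knn_fitness,
    neutral_curve,
    zygote_heteroplasmy,
)
from mtdrift.sim import SimulationParams

from conftest import make_toy_grid


class TestZygoteHeteroplasmy:
    @pytest.mark.parametrize(
        "cn_mut, cn_wt, expected", [(60, 20, 0.75), (0, 20, 0.0), (20, 20, 0.5)]
    )
    def test_copy_number_ratio(self, cn_mut, cn_wt, expected):
        assert zygote_heteroplasmy(cn_mut, cn_wt) == pytest.approx(expected)

    @pytest.mark.parametrize("cn_mut, cn_wt", [(0, 0), (-1, 20), (20, -1)])
    def test_invalid_inputs(self, cn_mut, cn_wt):
        with pytest.raises(ValueError):
            zygote_heteroplasmy(cn_mut, cn_wt)


class TestBuildGrid:
    # tiny but real simulations: 2 division rounds, 50 cells
    template = SimulationParams(n_cells_init=50, t_total_min=300.0)

    def test_homoplasmic_rows_are_exact(self):
        g = build_suppressivity_grid([0.0, 1.0], [0.5, 1.0], reps=2, template=self.template)
        pts = g.points.set_index(["h0", "fitness"])
        for f in (0.5, 1.0):
            assert pts.loc[(0.0, f), "suppressivity_mean"] == 0.0
            assert pts.loc[(1.0, f), "suppressivity_mean"] == 1.0

    def test_order_invariance(self):
        a = build_suppressivity_grid([0.2, 0.8], [0.5, 1.5], reps=2,
                                     template=self.template, master_seed=9)
        b = build_suppressivity_grid([0.8, 0.2], [1.5, 0.5], reps=2,
                                     template=self.template, master_seed=9)
        key = ["h0", "fitness", "rep"]
        left = a.replicates.sort_values(key).reset_index(drop=True)
        right = b.replicates.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(left, right)

    def test_empty_value_lists_rejected(self):
        with pytest.raises(ValueError):
            build_suppressivity_grid([], [1.0], reps=1, template=self.template)
        with pytest.raises(ValueError):
            build_suppressivity_grid([0.5], [], reps=1, template=self.template)


class TestNeutralCurve:
    def test_slice_endpoints(self, toy_grid):
        curve = neutral_curve(toy_grid)
        assert curve["h0"].is_monotonic_increasing
        assert curve.iloc[0]["suppressivity"] == pytest.approx(0.0)
        assert curve.iloc[-1]["suppressivity"] == pytest.approx(1.0)

    def test_missing_neutral_slice_rejected(self):
        g = make_toy_grid([(0.5, 0.5, 0.2), (0.5, 1.5, 0.8)])
        with pytest.raises(ValueError):
            neutral_curve(g)


class TestKnnFitness:
    def test_mean_of_identical_neighbours(self):
        g = make_toy_grid([(h, 1.2, s) for h, s in zip(np.linspace(0.2, 0.7, 6),
                                                       np.linspace(0.1, 0.9, 6))])
        est = knn_fitness(StrainObservation("s1", 0.5, 0.5), g, k=6)
        assert est.fitness_hat == pytest.approx(1.2)
        assert est.k == 6

    def test_k_exceeding_grid_rejected(self):
        g = make_toy_grid([(0.1 * i, 1.0, 0.1 * i) for i in range(5)])
        with pytest.raises(ValueError):
            knn_fitness(StrainObservation("s1", 0.5, 0.5), g, k=6)

    def test_fitness_window_filters_neighbours(self):
        rows = [(0.5, 3.0, 0.5)] * 6 + [(0.4, 1.0, 0.4)] * 6
        g = make_toy_grid(rows)
        est = knn_fitness(StrainObservation("s1", 0.5, 0.5), g, k=6, fitness_window=(0, 2))
        assert est.fitness_hat == pytest.approx(1.0)  # f=3 points excluded

    def test_distance_ties_break_to_lower_fitness_then_h0(self):
        # four equidistant points; with k=2 the two lowest-fitness win
        rows = [(0.4, 2.0, 0.5), (0.6, 0.5, 0.5), (0.4, 0.5, 0.5), (0.6, 2.0, 0.5)]
        g = make_toy_grid(rows)
        est = knn_fitness(StrainObservation("s1", 0.5, 0.5), g, k=2)
        assert est.fitness_hat == pytest.approx(0.5)

    def test_estimate_within_neighbour_hull(self, toy_grid):
        rng = np.random.default_rng(5)
        for _ in range(25):
            obs = StrainObservation("s", rng.random(), rng.random())
            est = knn_fitness(obs, toy_grid)
            fvals = toy_grid.replicates.loc[list(est.neighbor_ids), "fitness"]
            assert fvals.min() - 1e-12 <= est.fitness_hat <= fvals.max() + 1e-12

    def test_row_order_invariance(self, toy_grid):
        shuffled = toy_grid.replicates.sample(frac=1.0, random_state=1).reset_index(drop=True)
        g2 = make_toy_grid(
            list(shuffled[["h0", "fitness", "suppressivity"]].itertuples(index=False, name=None))
        )
        obs = StrainObservation("s1", 0.37, 0.42)
        assert knn_fitness(obs, toy_grid).fitness_hat == pytest.approx(
            knn_fitness(obs, g2).fitness_hat
        )

    def test_observation_on_neutral_curve_recovers_one(self, toy_grid):
        # toy grid has suppressivity = h0 * fitness, so points on the f=1
        # diagonal should estimate close to 1
        est = knn_fitness(StrainObservation("s1", suppressivity=0.5, h0=0.5), toy_grid)
        assert abs(est.fitness_hat - 1.0) <= 0.15


class TestEstimatePanel:
    def test_single_strain_panel_has_no_test(self, toy_grid):
        estimates, summary = estimate_panel(
            [StrainObservation("s1", 0.5, 0.5)], toy_grid
        )
        assert len(estimates) == 1
        assert summary.n_strains == 1
        assert summary.wilcoxon_p is None

    def test_panel_summary_statistics(self, toy_grid):
        obs = [
            StrainObservation(f"s{i}", min(1.0, 1.4 * h), h)
            for i, h in enumerate(np.linspace(0.2, 0.7, 8))
        ]
        estimates, summary = estimate_panel(obs, toy_grid)
        values = [e.fitness_hat for e in estimates]
        assert summary.mean_fitness == pytest.approx(np.mean(values))
        assert summary.median_fitness == pytest.approx(np.median(values))
        assert summary.wilcoxon_p is not None and 0 <= summary.wilcoxon_p <= 1

    def test_empty_panel_rejected(self, toy_grid):
        with pytest.raises(ValueError):
            estimate_panel([], toy_grid)


class TestObservationValidation:
    @pytest.mark.parametrize("supp, h0", [(1.2, 0.5), (-0.1, 0.5), (0.5, 1.7)])
    def test_out_of_range_rejected(self, supp, h0):
        with pytest.raises(ValueError):
            StrainObservation("s", supp, h0)
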