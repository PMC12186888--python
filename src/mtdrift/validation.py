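"""Self-validation experiments for the simulator and estimators.

Each function runs one reduced-scale computational experiment -- a sanity
check of the stochastic model (martingale, boundary, monotonicity
behaviour) or an end-to-end parameter-recovery study through the synthetic
generators and estimators -- and returns the measured quantities as a flat
dict.  They are deterministic given their seed and sized to run on a single
CPU in minutes; the test suite asserts on their outputs and the
reproduction script reports them.

Study conditions
----------------
Grids are simulated at 200 initial cells (150 for the robustness sweeps)
instead of the model's reference 1000, with 2-3 replicates per grid point;
strain panels draw mutant copy numbers uniformly from 60-380 against a
wild-type parental copy number of 20 (zygote heteroplasmy 0.75-0.95),
emulating the several-fold mtDNA excess of deletion strains, with binomial
assay noise over 100 colonies.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .fitness import (
    StrainObservation,
    SuppressivityGrid,
    build_suppressivity_grid,
    estimate_panel,
)
from .growth import GrowthCurve, mu_max
from .copynum import mtdna_ratio
from .sim import SimulationParams, daughter_counts, run_simulation
from .synth import SynthConfig, gen_depth_profiles, gen_growth_curve, gen_strain_panel

__all__ = [
    "small_n_division_tvd",
    "neutral_martingale",
    "boundary_suppressivity",
    "suppressivity_monotonicity",
    "build_inference_grid",
    "make_fitness_panel",
    "fitness_recovery",
    "panel_test_calibration",
    "copy_number_round_trip",
    "growth_rate_recovery",
    "robustness_sweep",
]

#: Mutant copy-number range of synthetic strain panels (wild-type parent
#: fixed at 20): several-fold mtDNA excess, zygote heteroplasmy 0.75-0.95.
PANEL_CN_RANGE = (60.0, 380.0)
PANEL_WT_CN = 20.0
PANEL_COLONIES = 100


def _subseed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def small_n_division_tvd(seed: int, n_draws: int = 50_000) -> dict:
    """Total variation distance between the sampled daughter-composition
    distribution for a (w=1, m=1, f=1, n=2) parent and the exact
    Binomial(2, 1/2) law {0: 1/4, 1: 1/2, 2: 1/4}."""
    rng = np.random.default_rng(seed)
    counts = np.zeros(3)
    for _ in range(n_draws):
        (_, m1), (_, m2) = daughter_counts(1, 1, 1.0, 2, rng=rng)
        counts[m1] += 1
        counts[m2] += 1
    observed = counts / counts.sum()
    exact = np.array([0.25, 0.5, 0.25])
    return {"tvd": float(0.5 * np.abs(observed - exact).sum()), "n_draws": 2 * n_draws}


def neutral_martingale(seed: int, n_seeds: int = 10) -> dict:
    """Neutral drift check at reference scale: f = 1, equal doubling times,
    h0 = 0.5.  The population-mean mutant frequency should stay at 0.5 and
    mutant fixation (suppressivity) should mirror wild-type fixation."""
    freqs, supps, fixes = [], [], []
    for i in range(n_seeds):
        params = SimulationParams(
            h0=0.5, fitness=1.0, t_petite_min=140.0, n_cells_init=1000,
            seed=_subseed(seed, 2, i),
        )
        r = run_simulation(params)
        freqs.append(r.mean_mut_freq)
        supps.append(r.suppressivity)
        fixes.append(r.wt_fixed_fraction)
    return {
        "mean_mut_freq": float(np.mean(freqs)),
        "mut_freq_deviation": float(abs(np.mean(freqs) - 0.5)),
        "mean_suppressivity": float(np.mean(supps)),
        "mean_wt_fixation": float(np.mean(fixes)),
        "symmetry_gap": float(abs(np.mean(supps) - np.mean(fixes))),
        "n_seeds": n_seeds,
    }


def boundary_suppressivity(seed: int, fitness_values=(0.0, 1.0, 2.0)) -> dict:
    """Homoplasmic starts are absorbing: h0 = 0 must give suppressivity 0
    and h0 = 1 must give suppressivity 1, for every fitness."""
    supp0, supp1 = [], []
    for i, f in enumerate(fitness_values):
        supp0.append(run_simulation(SimulationParams(
            h0=0.0, fitness=f, n_cells_init=200, seed=_subseed(seed, 3, i))).suppressivity)
        supp1.append(run_simulation(SimulationParams(
            h0=1.0, fitness=f, n_cells_init=200, seed=_subseed(seed, 4, i))).suppressivity)
    return {
        "max_suppressivity_at_h0_0": float(max(supp0)),
        "min_suppressivity_at_h0_1": float(min(supp1)),
    }


def suppressivity_monotonicity(seed: int) -> dict:
    """Mean suppressivity over a reduced grid must be non-decreasing in
    fitness at each heteroplasmy and vice versa (Spearman 1 on means)."""
    grid = build_suppressivity_grid(
        [0.1, 0.3, 0.5, 0.7, 0.9],
        [0.0, 0.5, 1.0, 1.5, 2.0],
        reps=10,
        template=SimulationParams(n_cells_init=200),
        master_seed=_subseed(seed, 5),
    )
    table = grid.points.pivot(index="h0", columns="fitness", values="suppressivity_mean")
    viol_f = sum(int((np.diff(row) < 0).sum()) for _, row in table.iterrows())
    viol_h = sum(int((np.diff(col) < 0).sum()) for _, col in table.items())

    def min_spearman(series_iter):
        out = []
        for _, s in series_iter:
            rho = stats.spearmanr(np.arange(len(s)), np.argsort(np.argsort(s))).statistic
            out.append(rho)
        return float(min(out))

    return {
        "violations_in_fitness": viol_f,
        "violations_in_h0": viol_h,
        "min_spearman_fitness": min_spearman(table.iterrows()),
        "min_spearman_h0": min_spearman(table.items()),
    }


def build_inference_grid(
    seed: int,
    reps: int = 5,
    n_cells: int = 200,
    h_step: float = 0.05,
    f_step: float = 0.1,
    f_max: float = 2.0,
    h_min: float = 0.0,
    f_min: float = 0.0,
    template: SimulationParams | None = None,
) -> SuppressivityGrid:
    """Suppressivity grid at the inference resolution (h0 step 0.05,
    fitness step 0.1 over [0, 2] by default), reduced to ``n_cells``
    initial cells and ``reps`` replicates per point."""
    if template is None:
        template = SimulationParams()
    template = SimulationParams(**{
        **{k: getattr(template, k) for k in SimulationParams.__dataclass_fields__},
        "n_cells_init": n_cells,
    })
    n_h = int(round((1.0 - h_min) / h_step)) + 1
    n_f = int(round((f_max - f_min) / f_step)) + 1
    hs = [round(h_min + i * h_step, 6) for i in range(n_h)]
    fs = [round(f_min + i * f_step, 6) for i in range(n_f)]
    return build_suppressivity_grid(hs, fs, reps, template, master_seed=_subseed(seed, 6))


def make_fitness_panel(
    fitness_values,
    seed: int,
    sim_template: SimulationParams,
) -> tuple[list[StrainObservation], np.ndarray]:
    """Synthetic strain panel at the study conditions: copy numbers from
    PANEL_CN_RANGE, 100-colony assay noise, truth from the simulator."""
    fitness_values = np.asarray(fitness_values, dtype=float)
    rng = np.random.default_rng(seed)
    cn = rng.uniform(*PANEL_CN_RANGE, size=fitness_values.size)
    cfg = SynthConfig(
        seed=seed,
        assay_colonies=PANEL_COLONIES,
        panel_fitness=tuple(fitness_values),
        panel_copy_numbers=tuple(cn),
        wt_parent_copy_number=PANEL_WT_CN,
    )
    panel = gen_strain_panel(cfg, sim_template)
    obs = [
        StrainObservation(r.strain_id, r.suppressivity_pct / 100.0, r.h0)
        for r in panel.itertuples(index=False)
    ]
    return obs, fitness_values


def fitness_recovery(grid: SuppressivityGrid, seed: int) -> dict:
    """Recover known intracellular fitness for a 25-strain panel spanning
    f = 0.8..1.6; reports mean absolute error and Kendall rank correlation
    between estimates and truth."""
    truth_template = SimulationParams(n_cells_init=500)
    fitness_true = np.repeat([0.8, 1.0, 1.2, 1.4, 1.6], 5)
    obs, truth = make_fitness_panel(fitness_true, _subseed(seed, 7), truth_template)
    estimates, _ = estimate_panel(obs, grid)
    est = np.array([e.fitness_hat for e in estimates])
    return {
        "mae": float(np.abs(est - truth).mean()),
        "kendall_tau": float(stats.kendalltau(est, truth).statistic),
        "n_strains": int(truth.size),
    }


def panel_test_calibration(
    grid: SuppressivityGrid,
    seed: int,
    true_fitness: float,
    n_panels: int = 20,
    n_strains: int = 22,
    alpha: float = 0.05,
) -> dict:
    """Wilcoxon-vs-1.0 behaviour of replicate panels simulated at one true
    fitness: the fraction of panels rejecting the neutral null (and, for
    calibration at f = 1, the fraction not rejecting)."""
    truth_template = SimulationParams(n_cells_init=300)
    reject = 0
    means = []
    for rep in range(n_panels):
        obs, _ = make_fitness_panel(
            np.full(n_strains, true_fitness), _subseed(seed, 8, int(true_fitness * 100), rep),
            truth_template,
        )
        _, summary = estimate_panel(obs, grid)
        means.append(summary.mean_fitness)
        if summary.wilcoxon_p is not None and summary.wilcoxon_p < alpha:
            reject += 1
    return {
        "true_fitness": true_fitness,
        "rejection_fraction": reject / n_panels,
        "nonsignificant_fraction": 1.0 - reject / n_panels,
        "mean_estimated_fitness": float(np.mean(means)),
        "n_panels": n_panels,
    }


# deletion patterns sparing exactly one quantification region each
_SPARE_ONE_REGION = {
    "region_1": ((8154, 85779),),
    "region_2": ((1, 31221), (31306, 85779)),
    "region_3": ((1, 48194), (48297, 85779)),
}


def copy_number_round_trip(seed: int, ratios=(5.0, 20.0, 80.0), noisy_reps: int = 5) -> dict:
    """Generator/estimator round trip: noiseless profiles must return the
    true mtDNA/nDNA ratio exactly; overdispersed profiles (negative-binomial
    dispersion 0.2) within 10%.

    The noisy accuracy is the mean absolute relative error over
    ``noisy_reps`` independent profiles per ratio: with dispersion 0.2 the
    per-position coefficient of variation has a floor near 0.45 regardless
    of depth, so a single 84-bp region average carries ~5% sampling noise
    and a one-draw error is not a stable accuracy measure.
    """
    spare = list(_SPARE_ONE_REGION.items())
    max_err_noiseless = 0.0
    max_err_noisy = 0.0
    for i, r in enumerate(ratios):
        region_id, deletions = spare[i % len(spare)]
        cfg = SynthConfig(
            seed=_subseed(seed, 9, i), true_ratio=float(r), deletions=deletions,
            base_nuclear_depth=40.0, nuclear_genome_length=100_000,
        )
        mt, nuc, _ = gen_depth_profiles(cfg)
        est = mtdna_ratio(mt, nuc)
        max_err_noiseless = max(max_err_noiseless, abs(est.ratio - r) / r)
        if est.regions_retained != {region_id}:
            raise AssertionError(f"expected only {region_id} retained, got {est.regions_retained}")

        errs = []
        for j in range(noisy_reps):
            noisy_cfg = SynthConfig(
                seed=_subseed(seed, 10, i, j), true_ratio=float(r), deletions=deletions,
                base_nuclear_depth=40.0, nuclear_genome_length=100_000, noise_dispersion=0.2,
            )
            mt, nuc, _ = gen_depth_profiles(noisy_cfg)
            est = mtdna_ratio(mt, nuc)
            errs.append(abs(est.ratio - r) / r)
        max_err_noisy = max(max_err_noisy, float(np.mean(errs)))
    return {
        "max_rel_error_noiseless": float(max_err_noiseless),
        "max_rel_error_noisy": float(max_err_noisy),
        "ratios_tested": list(ratios),
        "noisy_reps": noisy_reps,
    }


def growth_rate_recovery(seed: int, n_noisy: int = 100) -> dict:
    """Exact-rate recovery on a pure exponential (5-minute sampling,
    50-point window) and noisy-logistic recovery (sigma = 0.02) across
    ``n_noisy`` seeded replicates."""
    t = np.arange(216) * 5.0
    exact = GrowthCurve(t, 0.05 * np.exp(0.006 * t))
    exp_rel_err = abs(mu_max(exact, window=50) - 0.006) / 0.006

    mu_true = 0.005
    errors = []
    for i in range(n_noisy):
        curve = gen_growth_curve(
            mu=mu_true, od0=0.05, K=2.0, noise_sd=0.02, n_points=216,
            seed=_subseed(seed, 11, i),
        )
        errors.append(abs(mu_max(curve, window=50) - mu_true) / mu_true)
    return {
        "exponential_rel_error": float(exp_rel_err),
        "logistic_max_rel_error": float(np.max(errors)),
        "logistic_mean_rel_error": float(np.mean(errors)),
        "n_noisy_curves": n_noisy,
    }


def robustness_sweep(
    seed: int,
    thresholds=(0.4, 0.5, 0.6),
    copy_numbers=(10, 20, 50),
    true_fitness: float = 1.3,
    n_strains: int = 12,
) -> dict:
    """Re-run the fitness inference under varied pathogenicity threshold and
    per-cell copy number: an f = 1.3 panel's mean recovered fitness should
    stay above the neutral value 1.0 in every condition."""
    condition_means = {}
    for tau in thresholds:
        for n in copy_numbers:
            template = SimulationParams(n_cells_init=150, threshold=tau, n_copies=n)
            grid = build_inference_grid(
                _subseed(seed, 12, int(tau * 10), n),
                reps=2, n_cells=150, h_min=0.7, f_min=0.6, f_max=2.0,
                template=template,
            )
            truth_template = SimulationParams(n_cells_init=300, threshold=tau, n_copies=n)
            obs, _ = make_fitness_panel(
                np.full(n_strains, true_fitness),
                _subseed(seed, 13, int(tau * 10), n),
                truth_template,
            )
            _, summary = estimate_panel(obs, grid, fitness_window=(0.6, 2.0))
            condition_means[f"tau={tau},n={n}"] = summary.mean_fitness
    return {
        "min_mean_fitness": float(min(condition_means.values())),
        "condition_means": condition_means,
        "true_fitness": true_fitness,
    }
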