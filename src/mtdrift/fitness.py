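"""Simulation-grid k-nearest-neighbour inference of intracellular mtDNA fitness.

The simulator maps (initial heteroplasmy ``h0``, intracellular fitness
``f``) to an expected suppressivity.  Inverting that map for a strain whose
``h0`` (from parental mtDNA copy numbers) and suppressivity were measured
gives an estimate of the intracellular fitness of its rho- mtDNA: build a
grid of simulated (h0, f) -> suppressivity points, find the k grid points
nearest to the observation in the (h0, suppressivity) plane, and average
their fitness values.  Fitness values above 2 produce near-identical
suppressivity for most heteroplasmy levels, so inference is restricted to
f in [0, 2] by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .sim import SimulationParams, run_simulation

__all__ = [
    "SuppressivityGrid",
    "StrainObservation",
    "FitnessEstimate",
    "PanelSummary",
    "zygote_heteroplasmy",
    "build_suppressivity_grid",
    "neutral_curve",
    "knn_fitness",
    "estimate_panel",
]

DEFAULT_K = 6
DEFAULT_FITNESS_WINDOW = (0.0, 2.0)


@dataclass(frozen=True)
class StrainObservation:
    """One strain's measured coordinates in the inference plane.

    ``suppressivity`` and ``h0`` are fractions in [0, 1]; ``h0`` is the
    zygote heteroplasmy computed from the parental mtDNA copy numbers.
    """

    strain_id: str
    suppressivity: float
    h0: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.suppressivity <= 1.0:
            raise ValueError("suppressivity must lie in [0, 1]")
        if not 0.0 <= self.h0 <= 1.0:
            raise ValueError("h0 must lie in [0, 1]")


@dataclass(frozen=True)
class FitnessEstimate:
    strain_id: str
    fitness_hat: float
    neighbor_ids: tuple[int, ...]
    k: int


@dataclass(frozen=True)
class PanelSummary:
    """Panel-level distribution of fitness estimates vs the neutral value 1.0."""

    mean_fitness: float
    median_fitness: float
    n_strains: int
    wilcoxon_p: float | None  # None when fewer than 2 non-tied values


@dataclass
class SuppressivityGrid:
    """Simulated suppressivity over a (h0, fitness) grid.

    ``replicates`` holds one row per simulation run (h0, fitness, rep, seed,
    suppressivity); ``points`` aggregates mean/sd per (h0, fitness) pair.
    """

    replicates: pd.DataFrame
    params_used: SimulationParams
    fitness_range_used: tuple[float, float]

    @property
    def points(self) -> pd.DataFrame:
        agg = (
            self.replicates.groupby(["h0", "fitness"], as_index=False)["suppressivity"]
            .agg(suppressivity_mean="mean", suppressivity_sd="std", n_reps="size")
        )
        agg["suppressivity_sd"] = agg["suppressivity_sd"].fillna(0.0)
        return agg


def zygote_heteroplasmy(cn_mut: float, cn_wt: float) -> float:
    """Initial zygote heteroplasmy from the parental relative copy numbers
    of mutant and wild-type mtDNA: ``cn_mut / (cn_mut + cn_wt)``."""
    if cn_mut < 0 or cn_wt < 0:
        raise ValueError("copy numbers must be non-negative")
    total = cn_mut + cn_wt
    if total <= 0:
        raise ValueError("at least one parental copy number must be positive")
    return cn_mut / total


def _point_seed(master_seed: int, h0: float, fitness: float, rep: int) -> int:
    """Per-run seed derived from (master seed, grid coordinates, replicate),
    independent of the order grid points are visited in."""
    ss = np.random.SeedSequence(
        entropy=int(master_seed) & 0x7FFFFFFF,
        spawn_key=(int(round(h0 * 1_000_000)), int(round(fitness * 1_000_000)), int(rep)),
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def build_suppressivity_grid(
    h_values,
    f_values,
    reps: int,
    template: SimulationParams,
    master_seed: int = 0,
) -> SuppressivityGrid:
    """Run ``reps`` independent seeded simulations per (h0, fitness) pair.

    Deterministic given ``master_seed``; each run's seed depends only on its
    own coordinates, so shuffling the value lists permutes rows without
    changing any simulated value.
    """
    h_values = [float(h) for h in h_values]
    f_values = [float(f) for f in f_values]
    if not h_values or not f_values:
        raise ValueError("h_values and f_values must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if any(not 0.0 <= h <= 1.0 for h in h_values):
        raise ValueError("all h values must lie in [0, 1]")
    if any(f < 0 for f in f_values):
        raise ValueError("all fitness values must be >= 0")

    rows = []
    for h in h_values:
        for f in f_values:
            for rep in range(reps):
                seed = _point_seed(master_seed, h, f, rep)
                params = replace(template, h0=h, fitness=f, seed=seed)
                result = run_simulation(params)
                rows.append((h, f, rep, seed, result.suppressivity))
    replicates = pd.DataFrame(
        rows, columns=["h0", "fitness", "rep", "seed", "suppressivity"]
    )
    return SuppressivityGrid(
        replicates=replicates,
        params_used=template,
        fitness_range_used=(min(f_values), max(f_values)),
    )


def neutral_curve(grid: SuppressivityGrid, atol: float = 1e-9) -> pd.DataFrame:
    """The no-replication-advantage slice of the grid: mean suppressivity at
    fitness = 1 as a function of h0, ordered by h0.

    Observations above this curve indicate an intracellular fitness of the
    mutant molecule greater than 1.
    """
    pts = grid.points
    sel = pts[np.isclose(pts["fitness"], 1.0, atol=atol)]
    if sel.empty:
        raise ValueError("grid contains no fitness = 1 points")
    return (
        sel.sort_values("h0")[["h0", "suppressivity_mean"]]
        .rename(columns={"suppressivity_mean": "suppressivity"})
        .reset_index(drop=True)
    )


def _neighbor_table(grid: SuppressivityGrid, use_replicates: bool) -> pd.DataFrame:
    if use_replicates:
        return grid.replicates[["h0", "fitness", "suppressivity"]].reset_index(drop=True)
    pts = grid.points
    return pts[["h0", "fitness", "suppressivity_mean"]].rename(
        columns={"suppressivity_mean": "suppressivity"}
    )


def knn_fitness(
    obs: StrainObservation,
    grid: SuppressivityGrid,
    k: int = DEFAULT_K,
    fitness_window: tuple[float, float] = DEFAULT_FITNESS_WINDOW,
    use_replicates: bool = True,
) -> FitnessEstimate:
    """Estimate a strain's intracellular fitness as the unweighted mean
    fitness of its k nearest grid points.

    Distance is plain Euclidean in the (h0, suppressivity) plane -- both
    coordinates already live on [0, 1] so no standardisation is applied.
    Ties at equal distance are broken toward lower fitness, then lower h0.
    By default individual replicate runs are the neighbour set;
    ``use_replicates=False`` searches per-point means instead.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    table = _neighbor_table(grid, use_replicates)
    lo, hi = fitness_window
    eligible = table[(table["fitness"] >= lo) & (table["fitness"] <= hi)]
    if len(eligible) < k:
        raise ValueError(
            f"grid has only {len(eligible)} points with fitness in "
            f"[{lo}, {hi}]; k={k} requested"
        )
    dh = eligible["h0"].to_numpy() - obs.h0
    ds = eligible["suppressivity"].to_numpy() - obs.suppressivity
    dist = np.hypot(dh, ds)
    order = np.lexsort(
        (eligible["h0"].to_numpy(), eligible["fitness"].to_numpy(), dist)
    )
    chosen = order[:k]
    fitness_hat = float(eligible["fitness"].to_numpy()[chosen].mean())
    neighbor_ids = tuple(int(i) for i in eligible.index.to_numpy()[chosen])
    return FitnessEstimate(
        strain_id=obs.strain_id, fitness_hat=fitness_hat, neighbor_ids=neighbor_ids, k=k
    )


def estimate_panel(
    observations,
    grid: SuppressivityGrid,
    k: int = DEFAULT_K,
    fitness_window: tuple[float, float] = DEFAULT_FITNESS_WINDOW,
    use_replicates: bool = True,
) -> tuple[list[FitnessEstimate], PanelSummary]:
    """Per-strain kNN estimates plus a panel summary testing the neutral
    hypothesis (population mean fitness equal to 1.0) with the Wilcoxon
    signed-rank test with continuity correction.

    The p-value is reported as ``None`` when fewer than two estimates differ
    from 1.0 (the test is then undefined).
    """
    observations = list(observations)
    if not observations:
        raise ValueError("panel must contain at least one observation")
    estimates = [
        knn_fitness(obs, grid, k=k, fitness_window=fitness_window, use_replicates=use_replicates)
        for obs in observations
    ]
    values = np.array([e.fitness_hat for e in estimates])
    diffs = values - 1.0
    nonzero = diffs[diffs != 0]
    if nonzero.size >= 2 and np.unique(nonzero).size >= 1:
        p = float(stats.wilcoxon(nonzero, correction=True).pvalue)
    else:
        p = None
    summary = PanelSummary(
        mean_fitness=float(values.mean()),
        median_fitness=float(np.median(values)),
        n_strains=len(values),
        wilcoxon_p=p,
    )
    return estimates, summary
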