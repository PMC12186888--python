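"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators emulate the study's raw data so every estimator can be
exercised and scored without external downloads:

* per-base depth profiles for a mitochondrial genome carrying large
  deletions (plus AT-region read dropout outside the GC-rich 14-20 kb
  window) and a nuclear reference, with overdispersed negative-binomial
  coverage noise;
* plate-reader OD550 growth curves (logistic with multiplicative
  log-normal noise, 5-minute sampling);
* strain panels with known true intracellular fitness: zygote heteroplasmy
  follows from parental copy numbers, the "true" suppressivity comes from
  the stochastic simulator at that (h0, fitness), and the observed value
  adds binomial colony-sampling noise.

Every generator is deterministic given (seed, config) and returns a truth
record sufficient to score downstream estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .copynum import GC_WINDOW, DepthProfile
from .fitness import SuppressivityGrid, zygote_heteroplasmy
from .growth import GrowthCurve
from .sim import SimulationParams, run_simulation

__all__ = [
    "SynthConfig",
    "gen_depth_profiles",
    "gen_growth_curve",
    "gen_strain_panel",
]

#: S288C mitochondrial reference length (sacCer3 chrM), bp.
MT_GENOME_LENGTH = 85779


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic data generators.

    ``deletions`` are 1-based inclusive intervals of the mitochondrial
    genome with zero coverage; ``at_dropout_factor`` divides the expected
    mitochondrial depth outside the GC-rich window, mimicking AT-rich read
    dropout; ``noise_dispersion`` is the negative-binomial dispersion
    (variance = mu + dispersion * mu^2; 0 = noiseless).
    """

    seed: int = 0
    mt_genome_length: int = MT_GENOME_LENGTH
    nuclear_genome_length: int = 100_000
    base_nuclear_depth: float = 10.0
    true_ratio: float = 20.0
    deletions: tuple[tuple[int, int], ...] = ()
    at_dropout_factor: float = 1.0
    noise_dispersion: float = 0.0
    assay_colonies: int = 100
    panel_fitness: tuple[float, ...] = ()
    panel_copy_numbers: tuple[float, ...] = ()
    wt_parent_copy_number: float = 20.0

    def __post_init__(self) -> None:
        if self.mt_genome_length < 1 or self.nuclear_genome_length < 1:
            raise ValueError("genome lengths must be positive")
        if self.base_nuclear_depth <= 0 or self.true_ratio <= 0:
            raise ValueError("base_nuclear_depth and true_ratio must be positive")
        if self.at_dropout_factor < 1:
            raise ValueError("at_dropout_factor must be >= 1")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")
        if self.assay_colonies < 1:
            raise ValueError("assay_colonies must be positive")
        for s, e in self.deletions:
            if not 1 <= s <= e <= self.mt_genome_length:
                raise ValueError(f"deletion {s}-{e} outside the mt genome")
        if len(self.panel_fitness) != len(self.panel_copy_numbers):
            raise ValueError("panel_fitness and panel_copy_numbers differ in length")
        if any(c <= 0 for c in self.panel_copy_numbers) or self.wt_parent_copy_number <= 0:
            raise ValueError("copy numbers must be positive")


def _nb_sample(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draw with the mean/dispersion parameterisation;
    dispersion 0 returns the (float) mean exactly."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return mean.copy()
    r = 1.0 / dispersion
    p = r / (r + mean)
    out = np.zeros_like(mean)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def gen_depth_profiles(cfg: SynthConfig) -> tuple[DepthProfile, DepthProfile, dict]:
    """Mitochondrial and nuclear depth profiles plus a truth record.

    Nuclear depth has mean ``base_nuclear_depth`` everywhere; mitochondrial
    depth has mean ``base * true_ratio / dropout(pos)`` with dropout equal
    to ``at_dropout_factor`` outside the GC-rich window and 1 inside, and is
    zero inside deletions.
    """
    rng = np.random.default_rng(cfg.seed)
    nuc_mean = np.full(cfg.nuclear_genome_length, cfg.base_nuclear_depth)
    nuc_depth = _nb_sample(nuc_mean, cfg.noise_dispersion, rng)

    mt_mean = np.full(cfg.mt_genome_length, cfg.base_nuclear_depth * cfg.true_ratio)
    if cfg.at_dropout_factor > 1:
        gc_lo, gc_hi = GC_WINDOW[1], GC_WINDOW[2]
        outside = np.ones(cfg.mt_genome_length, dtype=bool)
        outside[gc_lo - 1 : gc_hi] = False
        mt_mean[outside] /= cfg.at_dropout_factor
    for s, e in cfg.deletions:
        mt_mean[s - 1 : e] = 0.0
    mt_depth = _nb_sample(mt_mean, cfg.noise_dispersion, rng)

    truth = {
        "true_ratio": cfg.true_ratio,
        "base_nuclear_depth": cfg.base_nuclear_depth,
        "deletions": [list(d) for d in cfg.deletions],
        "at_dropout_factor": cfg.at_dropout_factor,
        "noise_dispersion": cfg.noise_dispersion,
        "seed": cfg.seed,
    }
    return (
        DepthProfile("chrM", mt_depth),
        DepthProfile("nuclear", nuc_depth),
        truth,
    )


def gen_growth_curve(
    mu: float,
    od0: float,
    K: float | None,
    noise_sd: float,
    n_points: int,
    dt_min: float = 5.0,
    seed: int = 0,
    well_id: str = "synthetic",
) -> GrowthCurve:
    """Logistic OD trajectory with multiplicative log-normal noise.

    ``K=None`` (or infinity) gives the pure-exponential limit.  With
    ``noise_sd=0`` the curve is exactly the deterministic trajectory.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if od0 <= 0:
        raise ValueError("od0 must be positive")
    if K is not None and np.isfinite(K) and K <= od0:
        raise ValueError("carrying capacity K must exceed od0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_points < 1:
        raise ValueError("n_points must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points, dtype=float) * dt_min
    if K is None or not np.isfinite(K):
        od = od0 * np.exp(mu * t)
    else:
        od = K / (1.0 + (K / od0 - 1.0) * np.exp(-mu * t))
    if noise_sd > 0:
        od = od * np.exp(rng.normal(0.0, noise_sd, size=n_points))
    return GrowthCurve(time_min=t, od=od, well_id=well_id)


def _true_suppressivity_from_grid(grid: SuppressivityGrid, h0: float, f: float) -> float:
    pts = grid.points
    d2 = (pts["h0"].to_numpy() - h0) ** 2 + (pts["fitness"].to_numpy() - f) ** 2
    return float(pts["suppressivity_mean"].to_numpy()[int(np.argmin(d2))])


def gen_strain_panel(
    cfg: SynthConfig,
    sim_template: SimulationParams,
    grid: SuppressivityGrid | None = None,
) -> pd.DataFrame:
    """Strain panel with known true fitness, emulating a set of rho- strains.

    For each strain the zygote heteroplasmy is derived from its mtDNA copy
    number and the wild-type parent's; the true suppressivity is simulated
    at (h0, true_fitness) -- or looked up from ``grid``'s nearest point when
    a grid is supplied -- and the observed suppressivity adds binomial
    colony-sampling noise over ``assay_colonies`` colonies.

    Returns a DataFrame with columns strain_id, true_fitness, cn_mut,
    cn_wt_parent, h0, true_suppressivity, suppressivity_pct.
    """
    if not cfg.panel_fitness:
        raise ValueError("panel_fitness is empty")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for i, (f, cn_mut) in enumerate(zip(cfg.panel_fitness, cfg.panel_copy_numbers)):
        h0 = zygote_heteroplasmy(cn_mut, cfg.wt_parent_copy_number)
        if grid is not None:
            true_supp = _true_suppressivity_from_grid(grid, h0, f)
        else:
            seed_i = int(np.random.SeedSequence(
                entropy=cfg.seed & 0x7FFFFFFF, spawn_key=(1000 + i,)
            ).generate_state(1)[0] & 0x7FFFFFFF)
            params = replace(sim_template, h0=h0, fitness=float(f), seed=seed_i)
            true_supp = run_simulation(params).suppressivity
        observed = rng.binomial(cfg.assay_colonies, true_supp) / cfg.assay_colonies
        rows.append(
            (f"strain_{i + 1:02d}", float(f), float(cn_mut), cfg.wt_parent_copy_number,
             h0, true_supp, 100.0 * observed)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "strain_id", "true_fitness", "cn_mut", "cn_wt_parent",
            "h0", "true_suppressivity", "suppressivity_pct",
        ],
    )
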