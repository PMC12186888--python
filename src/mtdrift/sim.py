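"""Agent-based stochastic simulation of mtDNA drift and two-level selection.

The model follows a growing population of heteroplasmic budding-yeast cells.
Each cell carries a fixed number ``n`` of mtDNA segregating units, split
between wild-type (rho+) and deletion-bearing (rho-) molecules.  The mutant
fraction sets the cell phenotype through a pathogenicity threshold: cells
whose rho- fraction exceeds the threshold grow with the slow *petite*
doubling time, all others with the fast *grande* doubling time.  At
division the mtDNA pool is amplified (rho+ doubled, rho- multiplied by
``2 * fitness``) and daughters sample their complement of ``n`` molecules
from the amplified ratio, so an intracellular fitness above 1 biases
transmission toward the mutant molecule while selection at the cell level
(faster grande growth) pushes the population the other way.

Populations only grow -- there is no cell death -- and homoplasmic cells
are absorbing states.  The headline readout is *suppressivity*: the
fraction of cells devoid of wild-type mtDNA at the end of the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SimulationParams",
    "PopulationState",
    "PopulationSummary",
    "SimulationResult",
    "cell_phenotype",
    "daughter_counts",
    "init_population",
    "step",
    "summarize",
    "run_simulation",
]

DivisionMode = Literal["independent_binomial", "partition_hypergeometric"]
InitMode = Literal["deterministic", "binomial"]

GRANDE = "grande"
PETITE = "petite"


@dataclass(frozen=True)
class SimulationParams:
    """All constants of one simulation run.

    Parameters
    ----------
    n_copies:
        mtDNA segregating units per cell (constant between divisions).
    fitness:
        Intracellular fitness ``f`` of the rho- molecule: its relative
        increase in frequency per cell division (1.0 = neutral).
    threshold:
        Pathogenicity threshold: a cell is petite iff its mutant fraction
        strictly exceeds this value.
    t_grande_min, t_petite_min:
        Doubling times (minutes) of the two phenotypes.
    n_cells_init:
        Initial population size.
    t_total_min:
        Simulated horizon in minutes.
    dt_min:
        Scheduler tick; divisions fire on the first tick where a cell's
        age reaches its phenotype's doubling time.
    h0:
        Initial heteroplasmy: fraction of rho- molecules per cell.
    seed:
        RNG seed recorded in the result.
    division_mode:
        ``independent_binomial`` (default): each daughter's mutant count is
        an independent Binomial(n, p) draw with p the amplified mutant
        fraction.  ``partition_hypergeometric``: daughters partition one
        amplified pool without replacement.
    init_mode:
        ``deterministic`` (default): every initial cell gets
        round(h0 * n) mutant molecules.  ``binomial``: per-cell
        Binomial(n, h0) draw.
    """

    n_copies: int = 20
    fitness: float = 1.0
    threshold: float = 0.5
    t_grande_min: float = 140.0
    t_petite_min: float = 210.0
    n_cells_init: int = 1000
    t_total_min: float = 1440.0
    dt_min: float = 1.0
    h0: float = 0.5
    seed: int = 0
    division_mode: DivisionMode = "independent_binomial"
    init_mode: InitMode = "deterministic"

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError("n_copies must be a positive integer")
        if self.fitness < 0:
            raise ValueError("fitness must be >= 0")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.t_grande_min <= 0 or self.t_petite_min <= 0:
            raise ValueError("doubling times must be positive")
        if self.n_cells_init < 1:
            raise ValueError("n_cells_init must be positive")
        if self.t_total_min < self.t_grande_min:
            raise ValueError("t_total_min must allow at least one division")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be positive")
        if not 0.0 <= self.h0 <= 1.0:
            raise ValueError("h0 must lie in [0, 1]")
        if self.division_mode not in ("independent_binomial", "partition_hypergeometric"):
            raise ValueError(f"unknown division_mode {self.division_mode!r}")
        if self.init_mode not in ("deterministic", "binomial"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


@dataclass
class PopulationState:
    """Population of cells as parallel arrays (no per-cell objects).

    ``wt`` holds each cell's wild-type molecule count; the mutant count is
    ``n_copies - wt``.  ``birth_min`` is the (possibly negative) time of the
    cell's last division, so ``age = t_now_min - birth_min``.
    """

    wt: np.ndarray
    birth_min: np.ndarray
    t_now_min: float
    n_copies: int

    @property
    def n_cells(self) -> int:
        return self.wt.shape[0]

    @property
    def mut(self) -> np.ndarray:
        return self.n_copies - self.wt

    @property
    def ages_min(self) -> np.ndarray:
        return self.t_now_min - self.birth_min


@dataclass(frozen=True)
class PopulationSummary:
    suppressivity: float
    wt_fixed_fraction: float
    het_fraction: float
    mean_mut_freq: float


@dataclass
class SimulationResult:
    """Endpoint of one run plus the three population fractions.

    ``suppressivity`` is the fraction of cells devoid of wild-type mtDNA;
    together with the wild-type-fixed and heteroplasmic fractions it sums
    to 1.
    """

    final_state: PopulationState
    suppressivity: float
    wt_fixed_fraction: float
    het_fraction: float
    mean_mut_freq: float
    seed: int
    trajectory: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        """JSON-serialisable record (raw cells omitted)."""
        return {
            "suppressivity": self.suppressivity,
            "wt_fixed_fraction": self.wt_fixed_fraction,
            "het_fraction": self.het_fraction,
            "mean_mut_freq": self.mean_mut_freq,
            "n_cells_final": self.final_state.n_cells,
            "t_final_min": self.final_state.t_now_min,
            "seed": self.seed,
        }


def cell_phenotype(wt_count: int, mut_count: int, threshold: float = 0.5) -> str:
    """Phenotype of a single cell: ``"petite"`` iff the mutant fraction
    strictly exceeds ``threshold``, else ``"grande"``.

    A tie at exactly the threshold is grande.  A cell with no mtDNA at all
    (rho0) is outside the model and raises ``ValueError``.
    """
    total = wt_count + mut_count
    if total <= 0:
        raise ValueError("cell has no mtDNA molecules (rho0 is outside the model)")
    if wt_count < 0 or mut_count < 0:
        raise ValueError("molecule counts must be non-negative")
    return PETITE if mut_count / total > threshold else GRANDE


def _petite_mask(wt: np.ndarray, n: int, threshold: float) -> np.ndarray:
    # strict inequality: mut/n > tau  <=>  mut > tau*n
    return (n - wt) > threshold * n


def _amplified_mut_fraction(w: np.ndarray, m: np.ndarray, f: float) -> np.ndarray:
    """p = f*m / (f*m + w), with the f=0 homoplasmic-mutant corner defined
    as p=1 when m>0 and p=0 when m==0."""
    fm = f * np.asarray(m, dtype=float)
    denom = fm + w
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, fm / np.where(denom > 0, denom, 1.0), (np.asarray(m) > 0).astype(float))
    return p


def _stochastic_round(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    lo = np.floor(x)
    out = lo + (rng.random(x.shape) < (x - lo))
    return out.astype(np.int64)


def _divide_binomial(
    w: np.ndarray, m: np.ndarray, f: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    p = _amplified_mut_fraction(w, m, f)
    d1 = rng.binomial(n, p)
    d2 = rng.binomial(n, p)
    return d1, d2


def _divide_hypergeometric(
    w: np.ndarray, m: np.ndarray, f: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Partition an amplified pool W=2w, M=round_stochastic(2*f*m) into two
    daughters of n molecules each, without replacement.

    If the (depleted) pool holds fewer than n molecules the draw falls back
    to an independent sample at the amplified mutant fraction, which keeps
    the amplified ratio while staying well defined for any f >= 0.
    """
    w = np.asarray(w, dtype=np.int64)
    m = np.asarray(m, dtype=np.int64)
    d1 = np.empty_like(w)
    d2 = np.empty_like(w)

    homo = (m == 0) | (w == 0)
    d1[homo] = m[homo]
    d2[homo] = m[homo]

    het = ~homo
    if het.any():
        wh, mh = w[het], m[het]
        W = 2 * wh
        M = _stochastic_round(2.0 * f * mh.astype(float), rng)
        pool = W + M
        p = _amplified_mut_fraction(wh, mh, f)

        a = np.empty_like(wh)
        b = np.empty_like(wh)
        ok1 = pool >= n
        if ok1.any():
            a[ok1] = rng.hypergeometric(M[ok1], W[ok1], n)
        if (~ok1).any():
            a[~ok1] = rng.binomial(n, p[~ok1])
        # daughter 2 from the depleted pool where it still holds n molecules
        M2 = M - a
        W2 = W - (n - a)
        ok2 = ok1 & ((pool - n) >= n)
        if ok2.any():
            b[ok2] = rng.hypergeometric(M2[ok2], W2[ok2], n)
        rest = ~ok2
        if rest.any():
            fresh = rest & ok1  # fresh amplified pool, independent draw
            if fresh.any():
                b[fresh] = rng.hypergeometric(M[fresh], W[fresh], n)
            if (rest & ~ok1).any():
                b[rest & ~ok1] = rng.binomial(n, p[rest & ~ok1])
        d1[het] = a
        d2[het] = b
    return d1, d2


def daughter_counts(
    w: int,
    m: int,
    f: float,
    n: int,
    mode: DivisionMode = "independent_binomial",
    rng: np.random.Generator | None = None,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Divide one cell with ``w`` wild-type and ``m`` mutant molecules.

    Before sampling, the pool is amplified: wild-type counts are doubled and
    mutant counts multiplied by ``2 * f``.  Returns ``((wt1, mut1),
    (wt2, mut2))`` with each daughter holding exactly ``n`` molecules.
    """
    if w < 0 or m < 0:
        raise ValueError("molecule counts must be non-negative")
    if w + m != n:
        raise ValueError(f"parent holds {w + m} molecules, expected n={n}")
    if f < 0:
        raise ValueError("fitness must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    wa = np.array([w], dtype=np.int64)
    ma = np.array([m], dtype=np.int64)
    if mode == "independent_binomial":
        d1, d2 = _divide_binomial(wa, ma, f, n, rng)
    elif mode == "partition_hypergeometric":
        d1, d2 = _divide_hypergeometric(wa, ma, f, n, rng)
    else:
        raise ValueError(f"unknown division mode {mode!r}")
    m1, m2 = int(d1[0]), int(d2[0])
    return (n - m1, m1), (n - m2, m2)


def init_population(params: SimulationParams, rng: np.random.Generator) -> PopulationState:
    """Initial population: identical composition ``round(h0 * n)`` mutant
    molecules per cell (or per-cell binomial draws), with the time since the
    last division assigned uniformly at random to desynchronise divisions."""
    n = params.n_copies
    size = params.n_cells_init
    if params.init_mode == "deterministic":
        m0 = int(round(params.h0 * n))
        mut = np.full(size, m0, dtype=np.int64)
    else:
        mut = rng.binomial(n, params.h0, size=size).astype(np.int64)
    wt = n - mut
    petite = _petite_mask(wt, n, params.threshold)
    t_double = np.where(petite, params.t_petite_min, params.t_grande_min)
    ages = rng.uniform(0.0, t_double)
    return PopulationState(wt=wt, birth_min=-ages, t_now_min=0.0, n_copies=n)


def step(
    state: PopulationState, params: SimulationParams, rng: np.random.Generator
) -> PopulationState:
    """Advance the population by one tick of ``dt_min`` minutes.

    Every cell ages by ``dt_min``; each cell whose age has reached its
    phenotype's doubling time is replaced by two daughters with age 0 and
    freshly sampled molecule counts.
    """
    n = state.n_copies
    t_new = state.t_now_min + params.dt_min
    petite = _petite_mask(state.wt, n, params.threshold)
    t_double = np.where(petite, params.t_petite_min, params.t_grande_min)
    div = (t_new - state.birth_min) >= t_double
    if not div.any():
        return PopulationState(state.wt, state.birth_min, t_new, n)

    w = state.wt[div]
    m = n - w
    if params.division_mode == "independent_binomial":
        d1, d2 = _divide_binomial(w, m, params.fitness, n, rng)
    else:
        d1, d2 = _divide_hypergeometric(w, m, params.fitness, n, rng)

    keep_wt = state.wt[~div]
    keep_birth = state.birth_min[~div]
    n_div = w.shape[0]
    wt_new = np.concatenate([keep_wt, n - d1, n - d2])
    birth_new = np.concatenate([keep_birth, np.full(2 * n_div, t_new)])
    return PopulationState(wt_new, birth_new, t_new, n)


def summarize(state: PopulationState) -> PopulationSummary:
    """Population fractions: suppressivity (no wild-type mtDNA left),
    wild-type fixation, residual heteroplasmy, and the mean per-cell mutant
    molecule frequency."""
    if state.n_cells == 0:
        raise ValueError("cannot summarise an empty population")
    n = state.n_copies
    wt = state.wt
    supp = float(np.mean(wt == 0))
    fixed = float(np.mean(wt == n))
    return PopulationSummary(
        suppressivity=supp,
        wt_fixed_fraction=fixed,
        het_fraction=1.0 - supp - fixed,
        mean_mut_freq=float(np.mean((n - wt) / n)),
    )


def run_simulation(
    params: SimulationParams, record_every_min: float | None = None
) -> SimulationResult:
    """Run the model for ``t_total_min`` minutes and report final fractions.

    Deterministic for a fixed ``params.seed``.  If ``record_every_min`` is
    given, a trajectory DataFrame (time_min, suppressivity,
    wt_fixed_fraction, het_fraction, mean_mut_freq) is attached.

    The scheduler is event-driven: since molecule counts (and hence the
    phenotype and doubling time) are fixed between divisions, every cell's
    division tick is known at its birth, so cells are bucketed by that tick
    and the work per tick is proportional to the number of divisions.  This
    is equivalent to ticking every cell with :func:`step` but supports
    populations of millions of cells.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_copies
    dt = params.dt_min
    n_steps = int(round(params.t_total_min / dt))

    init = init_population(params, rng)
    size = init.n_cells
    cap = max(4 * size, 1024)
    wt = np.empty(cap, dtype=np.int64)
    birth = np.empty(cap, dtype=np.float64)
    wt[:size] = init.wt
    birth[:size] = init.birth_min

    # first tick k with k*dt - birth >= T, i.e. k = ceil((T + birth) / dt)
    petite = _petite_mask(init.wt, n, params.threshold)
    t_double = np.where(petite, params.t_petite_min, params.t_grande_min)
    fire = np.ceil((t_double + init.birth_min) / dt - 1e-9).astype(np.int64)
    fire = np.maximum(fire, 1)

    buckets: dict[int, list[np.ndarray]] = {}
    order = np.argsort(fire, kind="stable")
    ticks_sorted = fire[order]
    uniq, starts = np.unique(ticks_sorted, return_index=True)
    bounds = np.append(starts[1:], order.shape[0])
    for u, s, e in zip(uniq, starts, bounds):
        if u <= n_steps:
            buckets[int(u)] = [order[s:e]]

    # daughters born on a tick divide a fixed number of ticks later
    off_grande = int(np.ceil(params.t_grande_min / dt - 1e-9))
    off_petite = int(np.ceil(params.t_petite_min / dt - 1e-9))

    records: list[tuple[float, PopulationSummary]] = []

    def record(t: float) -> None:
        records.append((t, summarize(PopulationState(wt[:size], birth[:size], t, n))))

    if record_every_min is not None:
        record(0.0)
        next_record = record_every_min

    for k in range(1, n_steps + 1):
        t_now = k * dt
        chunks = buckets.pop(k, None)
        if chunks is not None:
            idx = chunks[0] if len(chunks) == 1 else np.concatenate(chunks)
            w = wt[idx]
            m = n - w
            if params.division_mode == "independent_binomial":
                d1, d2 = _divide_binomial(w, m, params.fitness, n, rng)
            else:
                d1, d2 = _divide_hypergeometric(w, m, params.fitness, n, rng)

            n_div = idx.shape[0]
            if size + n_div > cap:
                while size + n_div > cap:
                    cap *= 2
                wt_big = np.empty(cap, dtype=np.int64)
                birth_big = np.empty(cap, dtype=np.float64)
                wt_big[:size] = wt[:size]
                birth_big[:size] = birth[:size]
                wt, birth = wt_big, birth_big

            # daughter 1 replaces the parent in place, daughter 2 is appended
            wt[idx] = n - d1
            birth[idx] = t_now
            idx2 = np.arange(size, size + n_div)
            wt[idx2] = n - d2
            birth[idx2] = t_now
            size += n_div

            for ii in (idx, idx2):
                pet = _petite_mask(wt[ii], n, params.threshold)
                for mask, off in ((~pet, off_grande), (pet, off_petite)):
                    key = k + off
                    if key <= n_steps and mask.any():
                        buckets.setdefault(key, []).append(ii[mask])

        if record_every_min is not None and t_now >= next_record - 1e-9:
            record(t_now)
            next_record += record_every_min

    state = PopulationState(wt[:size], birth[:size], n_steps * dt, n)
    final = summarize(state)
    trajectory = None
    if record_every_min is not None:
        trajectory = pd.DataFrame(
            {
                "time_min": [t for t, _ in records],
                "suppressivity": [s.suppressivity for _, s in records],
                "wt_fixed_fraction": [s.wt_fixed_fraction for _, s in records],
                "het_fraction": [s.het_fraction for _, s in records],
                "mean_mut_freq": [s.mean_mut_freq for _, s in records],
            }
        )
    return SimulationResult(
        final_state=state,
        suppressivity=final.suppressivity,
        wt_fixed_fraction=final.wt_fixed_fraction,
        het_fraction=final.het_fraction,
        mean_mut_freq=final.mean_mut_freq,
        seed=params.seed,
        trajectory=trajectory,
    )
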