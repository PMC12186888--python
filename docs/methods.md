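# Methods

## The model

`mtdrift` simulates the vegetative segregation of two mitochondrial DNA
variants — a functional wild-type genome (rho+) and a deletion-bearing
variant (rho−) — in a growing population of budding-yeast cells, and uses
that simulator to infer the *intracellular fitness* of rho− mtDNA from two
measurable quantities: a strain's suppressivity (the fraction of petite
diploid progeny from a rho− × rho+ cross) and its zygote heteroplasmy
(derived from the parental mtDNA/nDNA copy-number ratios).

Each cell carries a fixed number `n` of segregating mtDNA units
(default 20), split into `w` wild-type and `m = n − w` mutant molecules.
Selection acts on two levels:

* **Intracellular.** At division, the pool is amplified — wild-type counts
  are doubled, mutant counts multiplied by `2f`, where `f` is the
  intracellular fitness (the relative per-division increase in frequency of
  the mutant molecule; `f = 1` is neutral) — and each daughter receives
  `n` molecules sampled from the amplified ratio.
* **Cell-level.** A cell whose mutant fraction strictly exceeds the
  pathogenicity threshold `τ` (default 0.5) expresses the slow-growing
  petite phenotype (doubling time 210 min) while all other cells are grande
  (140 min). Ties at exactly `τ` are grande.

Cells never die; homoplasmic compositions (`m = 0` or `w = 0`) are
absorbing. A run starts from 1000 cells of identical composition
`round(h0·n)` mutant molecules (a per-cell binomial initialisation is
available), with cell ages drawn uniformly below the phenotype's doubling
time to desynchronise divisions, and advances in 1-minute ticks for
1440 minutes. The headline readout is suppressivity: the final fraction of
cells devoid of wild-type mtDNA.

### Division sampling

The amplified ratio is the only identifiable part of the division rule, so
two sampling schemes are provided:

* `independent_binomial` (default): each daughter's mutant count is an
  independent draw from Binomial(n, p) with `p = f·m / (f·m + w)`. This is
  well defined for every real `f ≥ 0` and makes the per-cell mutant
  frequency a martingale when `f = 1`.
* `partition_hypergeometric`: the amplified pool (`W = 2w`,
  `M = 2·f·m` stochastically rounded to an integer) is partitioned without
  replacement; the second daughter draws from the depleted pool, or from an
  independent fresh pool when fewer than `n` molecules remain. If even the
  full amplified pool holds fewer than `n` molecules (possible for a
  heteroplasmic parent at very small `f`), the draw falls back to an
  independent Binomial(n, p) at the amplified fraction, which preserves the
  amplified ratio.

### Scheduler

Because molecule counts — and therefore the phenotype and doubling time —
are constant between divisions, every cell's division tick is known at its
birth. `run_simulation` exploits this: cells are bucketed by division tick
and the per-tick work is proportional to the number of divisions, which
supports populations of millions of cells as flat integer arrays. The
public `step` function implements the same dynamics as a literal per-tick
update and defines the semantics; the two agree because a division fires on
the first tick at which a cell's age reaches its doubling time in either
formulation. Results are insensitive to halving the tick to 0.5 min within
Monte-Carlo error.

A note on the petite doubling time: the reference value used throughout is
210 min, but 190 min also circulates for the same strain background; the
parameter (`t_petite_min`) is exposed rather than silently fixed.

## Fitness inference

A suppressivity grid is built by running the simulator over a lattice of
(h0, f) values with independent seeded replicates; each run's seed is
derived from its own coordinates, so the grid is reproducible and
independent of evaluation order. Inference restricts to `f ∈ [0, 2]`:
above 2, suppressivity saturates and different fitness values are not
distinguishable for most heteroplasmy levels.

A strain is a point `(h0, suppressivity)` with both coordinates in [0, 1];
its fitness estimate is the unweighted mean fitness of its `k = 6` nearest
grid points by plain Euclidean distance (no standardisation — both axes are
already unit-scaled; a flag selects per-point means instead of individual
replicate runs as the neighbour set). Distance ties break toward lower
fitness, then lower h0. Panel summaries report the mean and median estimate
and a two-sided Wilcoxon signed-rank test (continuity correction) of the
estimates against the neutral value 1.0; the test is reported as
unavailable with fewer than two estimates differing from 1.0.

**Identifiability caveat.** The map f → suppressivity is flat wherever
suppressivity pins to 0 or 1. For zygote heteroplasmy below ~0.7 the
neutral curve is nearly 0, so any `f ≲ 1.2` produces indistinguishable
observations and the kNN estimate there reflects the tie-break and grid
layout, not the data. Inference is meaningful for strains whose observed
suppressivity falls in the informative band (roughly 10–95%), which is
where real suppressive strains lie.

The inversion is also convex (the suppressivity–fitness curve flattens
toward the plateaus), so noise in the neighbour set biases estimates
slightly upward; the bias shrinks with grid density and replicate count.
At the validation resolution (h0 step 0.05, f step 0.1, 5 replicates per
point) the residual bias of a neutral panel is below 0.01.

## Copy number from read depth

The mtDNA/nDNA ratio is the mean mitochondrial read depth divided by the
mean nuclear read depth, with two adjustments. The nuclear mean discards
positions outside the (0.025, 0.975) empirical depth quantiles, which
suppresses rRNA-repeat and telomeric pile-ups; the trim bounds are
configurable, and on overdispersed coverage the symmetric trim of a
right-skewed distribution biases the nuclear mean low by ~2%. The
mitochondrial mean is computed separately over three short quantification
regions (8002–8153, 31222–31305, 48195–48296; 1-based inclusive), chosen
so that every deletion strain retains at least one, and the reported ratio
is the **maximum** of the per-region ratios. AT-rich mitochondrial
sequence suffers read dropout, so these regions understate copy number
relative to the GC-rich 14,000–20,000 window by severalfold; the GC window
is available as an alternative region set when a strain retains it.
Regions with a nuclear-normalised ratio above 0.5 are flagged retained; an
estimate with no retained region is rho0-like. Retained-segment detection
reports maximal runs of positions at ≥ 0.5× the nuclear mean, merging gaps
shorter than 100 bp.

## Growth rate

The maximum specific growth rate is the largest ordinary-least-squares
slope of ln(OD550) against time over a sliding window of 50 consecutive
points (5-minute sampling, one-point slide). On a pure exponential this is
exact for any window length; on saturating curves it underestimates the
intrinsic rate by a few percent because every window overlaps some
curvature, and no OD-linearisation correction is applied. Doubling time is
`ln 2 / µ`. CFU-based relative growth is a plain fold change between the
start and end of a crossing experiment.

## Suppressivity assays and drift

Suppressivity is `100 · petite / (petite + grande)` from colony counts.
The drift analysis pairs each strain's first assessment with the mean of
its subsequent ones and applies the Wilcoxon signed-rank test with
continuity correction to the paired differences; when every difference is
zero the p-value is 1 by definition (nothing to rank), and with a single
non-zero difference the test is reported unavailable.

## Synthetic data

The generators produce inputs with the statistical structure the
estimators assume, plus a truth record for scoring:

* **Depth profiles.** Nuclear and mitochondrial per-base depths are
  negative-binomial with mean/dispersion parameterisation
  (variance = µ + d·µ²; dispersion 0 returns the exact mean). The
  mitochondrial mean is `base · true_ratio`, divided by an AT-dropout
  factor outside the GC window and zeroed inside declared deletions. The
  mitochondrial genome length is 85,779 bp (the S288C reference). With
  dispersion 0.2 the per-position CV has a floor near 0.45 regardless of
  depth, so region-mean accuracy is limited by region length, not
  coverage.
* **Growth curves.** Logistic trajectories (exponential in the K → ∞
  limit) with multiplicative log-normal noise at 5-minute sampling.
* **Strain panels.** Each strain has a true fitness and an mtDNA copy
  number; zygote heteroplasmy follows from the copy number against a
  wild-type parental value of 20, the true suppressivity is simulated at
  (h0, f), and the observed value adds binomial sampling noise over 100
  colonies. The validation panels draw copy numbers uniformly from
  60–380 (heteroplasmy 0.75–0.95), emulating the severalfold mtDNA excess
  of deletion strains and keeping observations in the informative band.

What the generators deliberately do not model: read-level artefacts
(mapping bias beyond the single-step AT dropout, GC-content gradients),
mating efficiency and plating variation beyond binomial colony sampling,
mtDNA concatemers (so "copy number" means segregating units throughout),
cell death, recombination, and zygote-formation dynamics. Passing the
round-trip tests therefore shows the estimators are correct under the
stated noise structure, not that real libraries or platings meet it.

## Validation experiment sizes

The self-validation experiments (`mtdrift.validation`, reported by
`scripts/acceptance.py`) run at reduced scale, chosen as the package's own
trade-off between Monte-Carlo error and desk-scale runtime:

* neutral martingale: 10 runs at the reference scale (1000 cells,
  1440 min);
* monotonicity: 5 × 5 grid, 10 replicates, 200 initial cells;
* inference grid: h0 step 0.05 × f step 0.1 over [0, 2], 5 replicates,
  200 initial cells (the full-scale analogue uses 10 replicates at 1000
  cells);
* recovery/calibration panels: 22–25 strains, truth simulated at 300–500
  cells, 20 replicate panels for the test-calibration rates;
* robustness sweep: τ ∈ {0.4, 0.5, 0.6} × n ∈ {10, 20, 50}, each with a
  0.7–1.0 × 0.6–2.0 grid at 2 replicates and a 12-strain f = 1.3 panel;
* copy-number noisy accuracy: mean absolute relative error over 5
  independent profiles per ratio (single draws on an 84-bp region carry
  ~5% sampling noise by construction, see above).

All randomness flows from a single seed through named
`numpy.random.SeedSequence` spawn keys, so every quantity is reproducible
and independent of execution order.
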