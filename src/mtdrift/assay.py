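"""Suppressivity assay arithmetic and the first-vs-subsequent drift test.

Suppressivity is the percentage of petite colonies among the diploid
progeny of a rho- x rho+ cross.  Repeated assessments of the same strain
tend to drift upward after the initial post-bottleneck measurement; the
drift test pairs each strain's first assessment with the mean of its later
ones and applies the Wilcoxon signed-rank test with continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AssayCount",
    "DriftRecord",
    "DriftSummary",
    "suppressivity_from_counts",
    "drift_comparison",
]


@dataclass(frozen=True)
class AssayCount:
    """Colony counts from one suppressivity assessment."""

    strain_id: str
    petite: int
    grande: int

    def __post_init__(self) -> None:
        if self.petite < 0 or self.grande < 0:
            raise ValueError("colony counts must be non-negative")


@dataclass(frozen=True)
class DriftRecord:
    """A strain's first suppressivity assessment (%) and all later ones."""

    strain_id: str
    first: float
    subsequent: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.subsequent:
            raise ValueError("need at least one subsequent assessment")
        for v in (self.first, *self.subsequent):
            if not 0.0 <= v <= 100.0:
                raise ValueError("suppressivity percentages must lie in [0, 100]")


@dataclass(frozen=True)
class DriftSummary:
    mean_shift: float  # mean over strains of mean(subsequent) - first, in %
    sd_shift: float
    n_strains: int
    wilcoxon_p: float | None  # None when the test is unavailable


def suppressivity_from_counts(count: AssayCount) -> float:
    """Suppressivity in percent: 100 * petite / (petite + grande)."""
    total = count.petite + count.grande
    if total == 0:
        raise ValueError(f"strain {count.strain_id}: no colonies counted")
    return 100.0 * count.petite / total


def drift_comparison(records) -> DriftSummary:
    """Compare first vs subsequent suppressivity assessments across strains.

    Per strain the paired difference is mean(subsequent) - first (percentage
    points).  The two-sided Wilcoxon signed-rank test with continuity
    correction is applied to the differences; with fewer than two non-zero
    differences the p-value is reported as None (all-zero differences give
    p = 1: nothing to reject).
    """
    records = list(records)
    if not records:
        raise ValueError("no drift records supplied")
    diffs = np.array([float(np.mean(r.subsequent)) - r.first for r in records])
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        p: float | None = 1.0
    elif nonzero.size < 2:
        p = None
    else:
        p = float(stats.wilcoxon(nonzero, correction=True).pvalue)
    return DriftSummary(
        mean_shift=float(diffs.mean()),
        sd_shift=float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0,
        n_strains=len(records),
        wilcoxon_p=p,
    )
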