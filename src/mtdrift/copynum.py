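"""mtDNA/nDNA copy-number estimation from per-base read depth.

The mitochondrial copy number per nuclear genome is estimated as the ratio
of mitochondrial to nuclear mean read depth.  Two quirks of rho- yeast
genomes shape the procedure:

* the nuclear mean is taken after discarding positions with extreme depth
  quantiles (rRNA repeats and telomeres attract excess reads);
* rho- strains retain only fragments of the mitochondrial genome, so the
  mitochondrial mean is computed separately over three short quantification
  regions chosen so that every strain retains at least one of them, and the
  final ratio is the maximum of the per-region ratios.

Coordinates are 1-based inclusive throughout, matching the reference
mitochondrial genome annotation; BED conversion happens only at I/O
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DepthProfile",
    "RegionSpec",
    "CopyNumberEstimate",
    "QPCR_REGIONS",
    "GC_WINDOW",
    "nuclear_mean_depth",
    "region_mean_depth",
    "mtdna_ratio",
    "detect_retained_segments",
]

#: The three short mtDNA quantification regions (1-based inclusive), chosen
#: so every rho- strain retains at least one; same loci as the qPCR primers.
QPCR_REGIONS = (
    ("region_1", 8002, 8153),
    ("region_2", 31222, 31305),
    ("region_3", 48195, 48296),
)

#: GC-rich mtDNA window with uniform coverage, the conventional single-window
#: alternative; absent from some rho- strains.
GC_WINDOW = ("gc_window", 14000, 20000)


@dataclass
class DepthProfile:
    """Per-position read depth over one reference, positions 1..len(depth)."""

    ref_name: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D array")
        if self.depth.size and self.depth.min() < 0:
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return int(self.depth.size)


@dataclass(frozen=True)
class RegionSpec:
    """1-based inclusive interval on a reference."""

    region_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid region {self.region_id}: {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Per-region and final (max-rule) mtDNA/nDNA depth ratios."""

    per_region_ratio: dict[str, float]
    ratio: float
    nuclear_mean: float
    regions_retained: frozenset[str]

    @property
    def is_rho0_like(self) -> bool:
        """True when no quantification region shows appreciable coverage."""
        return len(self.regions_retained) == 0

    def to_dict(self) -> dict:
        return {
            "ratio": self.ratio,
            "per_region_ratio": dict(self.per_region_ratio),
            "nuclear_mean": self.nuclear_mean,
            "regions_retained": sorted(self.regions_retained),
            "rho0_like": self.is_rho0_like,
        }


def nuclear_mean_depth(
    profile: DepthProfile, lo_q: float = 0.025, hi_q: float = 0.975
) -> float:
    """Mean nuclear depth after discarding positions outside the
    [lo_q, hi_q] empirical depth quantiles (rRNA repeats, telomeres)."""
    if not 0.0 <= lo_q < hi_q <= 1.0:
        raise ValueError("require 0 <= lo_q < hi_q <= 1")
    if len(profile) == 0:
        raise ValueError("empty depth profile")
    lo, hi = np.quantile(profile.depth, [lo_q, hi_q])
    kept = profile.depth[(profile.depth >= lo) & (profile.depth <= hi)]
    if kept.size == 0:
        raise ValueError("quantile trimming removed every position")
    return float(kept.mean())


def region_mean_depth(profile: DepthProfile, region: RegionSpec) -> float:
    """Arithmetic mean depth over region.start..region.end (inclusive)."""
    if region.start > len(profile):
        raise ValueError(
            f"region {region.region_id} ({region.start}-{region.end}) lies "
            f"outside the profile (length {len(profile)})"
        )
    if region.end > len(profile):
        raise ValueError(
            f"region {region.region_id} extends past the profile end "
            f"({region.end} > {len(profile)})"
        )
    return float(profile.depth[region.start - 1 : region.end].mean())


def mtdna_ratio(
    mt_profile: DepthProfile,
    nuc_profile: DepthProfile,
    regions=None,
    trim: tuple[float, float] = (0.025, 0.975),
    retention_floor: float = 0.5,
) -> CopyNumberEstimate:
    """mtDNA/nDNA ratio via per-region means and the max rule.

    Each region's mean mitochondrial depth is divided by the trimmed nuclear
    mean; the reported ratio is the maximum over regions, so a strain is
    scored by whichever quantification region it retains.  Regions whose
    ratio exceeds ``retention_floor`` are flagged as retained; an estimate
    with no retained region is rho0-like.
    """
    if regions is None:
        regions = [RegionSpec(*r) for r in QPCR_REGIONS]
    regions = list(regions)
    if not regions:
        raise ValueError("need at least one quantification region")
    nuc_mean = nuclear_mean_depth(nuc_profile, *trim)
    if nuc_mean <= 0:
        raise ValueError("trimmed nuclear mean depth is zero")
    per_region = {
        r.region_id: region_mean_depth(mt_profile, r) / nuc_mean for r in regions
    }
    retained = frozenset(rid for rid, v in per_region.items() if v > retention_floor)
    return CopyNumberEstimate(
        per_region_ratio=per_region,
        ratio=max(per_region.values()),
        nuclear_mean=nuc_mean,
        regions_retained=retained,
    )


def detect_retained_segments(
    mt_profile: DepthProfile,
    nuclear_mean: float,
    floor_frac: float = 0.5,
    merge_distance: int = 100,
) -> list[tuple[int, int]]:
    """Maximal runs of mitochondrial positions with depth >=
    ``floor_frac * nuclear_mean``, merging runs separated by gaps shorter
    than ``merge_distance`` bp.  Returns 1-based inclusive intervals."""
    if nuclear_mean <= 0:
        raise ValueError("nuclear_mean must be positive")
    covered = mt_profile.depth >= floor_frac * nuclear_mean
    if not covered.any():
        return []
    padded = np.concatenate([[False], covered, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts = edges[0::2] + 1  # 1-based
    ends = edges[1::2]  # inclusive
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] - 1 < merge_distance:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    return [(s, e) for s, e in merged]
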