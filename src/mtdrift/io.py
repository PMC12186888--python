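"""Readers and writers for the package's tabular formats.

Conventions: samtools-depth-style TSV (no header) for per-base depth;
headered TSV for strain tables and grids; CSV for plate-reader curves;
JSON for nested results; BED (0-based half-open) only at export
boundaries.  Positions absent from a depth file are depth 0, matching the
samtools-depth default of omitting zero rows.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

import numpy as np
import pandas as pd

from .assay import AssayCount, DriftRecord
from .copynum import DepthProfile, RegionSpec
from .fitness import StrainObservation, SuppressivityGrid, zygote_heteroplasmy
from .growth import GrowthCurve
from .sim import SimulationParams

__all__ = [
    "read_depth_tsv",
    "write_depth_tsv",
    "read_regions_bed",
    "write_segments_bed",
    "read_strain_table",
    "read_assay_table",
    "drift_records_from_assays",
    "read_growth_csv",
    "read_grid_tsv",
    "write_grid_tsv",
    "params_from_toml",
    "provenance_record",
]


def read_depth_tsv(path, declared_lengths: dict[str, int] | None = None) -> dict[str, DepthProfile]:
    """Parse a 3-column samtools-depth TSV (ref, 1-based pos, depth).

    Returns one :class:`DepthProfile` per reference name.  Positions missing
    from the file get depth 0, up to the maximum observed position or the
    declared length for that reference.
    """
    path = Path(path)
    per_ref: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
                )
            ref, pos_s, depth_s = fields
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer position {pos_s!r}") from None
            try:
                depth = float(depth_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric depth {depth_s!r}") from None
            if pos < 1:
                raise ValueError(f"{path}:{lineno}: positions are 1-based, got {pos}")
            if depth < 0:
                raise ValueError(f"{path}:{lineno}: negative depth {depth}")
            per_ref.setdefault(ref, []).append((pos, depth))
    if not per_ref:
        raise ValueError(f"{path}: no depth rows found")
    profiles = {}
    for ref, rows in per_ref.items():
        max_pos = max(p for p, _ in rows)
        if declared_lengths and ref in declared_lengths:
            max_pos = max(max_pos, declared_lengths[ref])
        depth = np.zeros(max_pos)
        for p, d in rows:
            depth[p - 1] = d
        profiles[ref] = DepthProfile(ref, depth)
    return profiles


def write_depth_tsv(path, profiles, omit_zero: bool = True) -> None:
    """Write profiles as samtools-depth TSV; zero-depth rows omitted by
    default (round-tripping through :func:`read_depth_tsv` restores them)."""
    with open(path, "w") as fh:
        for profile in profiles:
            for pos, d in enumerate(profile.depth, start=1):
                if omit_zero and d == 0:
                    continue
                fh.write(f"{profile.ref_name}\t{pos}\t{int(round(d))}\n")


def read_regions_bed(path) -> list[RegionSpec]:
    """BED (0-based half-open) -> 1-based inclusive :class:`RegionSpec`."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            name = fields[3] if len(fields) > 3 else f"region_{lineno}"
            start0, end0 = int(fields[1]), int(fields[2])
            regions.append(RegionSpec(name, start0 + 1, end0))
    if not regions:
        raise ValueError(f"{path}: no regions found")
    return regions


def write_segments_bed(path, ref_name: str, segments) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, (start, end) in enumerate(segments, start=1):
            fh.write(f"{ref_name}\t{start - 1}\t{end}\tsegment_{i}\n")


def read_strain_table(path) -> list[StrainObservation]:
    """Headered TSV (strain_id, suppressivity_pct, cn_mut, cn_wt_parent) ->
    strain observations with h0 derived from the parental copy numbers.
    Suppressivity is accepted as a percentage and stored as a fraction."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain_id", "suppressivity_pct", "cn_mut", "cn_wt_parent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: empty strain table")
    obs = []
    for row in df.itertuples(index=False):
        pct = float(row.suppressivity_pct)
        if not 0.0 <= pct <= 100.0:
            raise ValueError(
                f"{path}: strain {row.strain_id}: suppressivity {pct} outside [0, 100]"
            )
        if float(row.cn_mut) < 0 or float(row.cn_wt_parent) < 0:
            raise ValueError(f"{path}: strain {row.strain_id}: negative copy number")
        obs.append(
            StrainObservation(
                strain_id=str(row.strain_id),
                suppressivity=pct / 100.0,
                h0=zygote_heteroplasmy(float(row.cn_mut), float(row.cn_wt_parent)),
            )
        )
    return obs


def read_assay_table(path) -> list[AssayCount]:
    """Headered TSV (strain_id, assessment_index, petite, grande) ->
    per-assessment colony counts, ordered by assessment_index."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain_id", "assessment_index", "petite", "grande"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: empty assay table")
    df = df.sort_values(["strain_id", "assessment_index"])
    return [
        AssayCount(str(r.strain_id), int(r.petite), int(r.grande))
        for r in df.itertuples(index=False)
    ]


def drift_records_from_assays(path) -> list[DriftRecord]:
    """Group an assay table into drift records: the assessment with the
    lowest index is 'first', all later ones are 'subsequent'.  Strains with
    a single assessment are skipped (no pair to compare)."""
    from .assay import suppressivity_from_counts

    df = pd.read_csv(path, sep="\t")
    required = {"strain_id", "assessment_index"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if "suppressivity_pct" in df.columns:
        df = df.assign(pct=df["suppressivity_pct"].astype(float))
    elif {"petite", "grande"} <= set(df.columns):
        df = df.assign(
            pct=[
                suppressivity_from_counts(AssayCount(str(r.strain_id), int(r.petite), int(r.grande)))
                for r in df.itertuples(index=False)
            ]
        )
    else:
        raise ValueError(f"{path}: need either suppressivity_pct or petite/grande columns")
    records = []
    for strain, sub in df.sort_values("assessment_index").groupby("strain_id"):
        vals = sub["pct"].tolist()
        if len(vals) < 2:
            continue
        records.append(DriftRecord(str(strain), vals[0], tuple(vals[1:])))
    if not records:
        raise ValueError(f"{path}: no strain has both a first and a subsequent assessment")
    return records


def read_growth_csv(path) -> list[GrowthCurve]:
    """Long-format CSV (well_id, time_min, od) -> one curve per well."""
    df = pd.read_csv(path)
    required = {"well_id", "time_min", "od"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    for well, sub in df.groupby("well_id", sort=False):
        sub = sub.sort_values("time_min")
        curves.append(
            GrowthCurve(
                time_min=sub["time_min"].to_numpy(float),
                od=sub["od"].to_numpy(float),
                well_id=str(well),
            )
        )
    if not curves:
        raise ValueError(f"{path}: no growth curves found")
    return curves


GRID_COLUMNS = ["h0", "fitness", "rep", "seed", "suppressivity"]


def write_grid_tsv(path, grid: SuppressivityGrid) -> None:
    grid.replicates[GRID_COLUMNS].to_csv(path, sep="\t", index=False)


def read_grid_tsv(path, template: SimulationParams | None = None) -> SuppressivityGrid:
    df = pd.read_csv(path, sep="\t")
    missing = set(GRID_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if template is None:
        template = SimulationParams()
    f = df["fitness"]
    return SuppressivityGrid(
        replicates=df[GRID_COLUMNS].copy(),
        params_used=template,
        fitness_range_used=(float(f.min()), float(f.max())),
    )


_PARAM_KEYS = set(SimulationParams.__dataclass_fields__)


def params_from_toml(path) -> SimulationParams:
    """TOML key/value config -> :class:`SimulationParams`; keys map 1:1 to
    the dataclass fields (optionally under a [simulation] table) and unknown
    keys are rejected."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    if "simulation" in data and isinstance(data["simulation"], dict):
        data = data["simulation"]
    unknown = set(data) - _PARAM_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown simulation keys {sorted(unknown)}")
    return SimulationParams(**data)


def provenance_record(config: dict, seed: int | None = None) -> dict:
    """Record written next to every CLI output: config, seed, version."""
    from . import __version__

    rec = {"package": "mtdrift", "version": __version__, "config": config}
    if seed is not None:
        rec["seed"] = seed
    return rec


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
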