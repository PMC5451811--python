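"""Species durations and palaeogeographic range sizes.

A species' stratigraphic range runs from the oldest to the youngest stage it
occurs in. Duration is measured two ways: in stages (index span, so a species
known from a single stage has duration 1 stage) and in million years (distance
between the midpoints of the first and last stage, rounded to whole My — a
single-stage species therefore has a 0 My duration and is a *single-interval*
species, or singleton). Range size is occupancy: the number of distinct cells
of a 2 x 2 decimal-degree grid projected on the palaeocoordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .habitat import HabitatAssignment, HabitatMap, species_habitat_sets
from .occurrence_io import GeologicalStage, OccurrenceTable, Timescale

__all__ = [
    "stage_midpoint",
    "round_ma",
    "species_duration",
    "grid_cells",
    "SpeciesSummary",
    "build_species_summaries",
    "summaries_frame",
    "stratify_by_range",
]


def stage_midpoint(stage: GeologicalStage) -> float:
    """Arithmetic midpoint age of a stage in Ma."""
    return (stage.base_ma + stage.top_ma) / 2.0


def round_ma(x: float, mode: str = "nearest") -> int:
    """Round a duration in My to an integer.

    ``nearest`` rounds half away from zero (2.5 -> 3); ``ceiling`` always
    rounds up. Python's built-in banker's rounding is deliberately avoided:
    midpoint distances ending in .5 are common on real timescales and should
    not round down half the time.
    """
    if mode == "nearest":
        return int(math.floor(x + 0.5))
    if mode == "ceiling":
        return int(math.ceil(x))
    raise ValueError(f"unknown rounding mode {mode!r}")


def species_duration(
    occs: pd.DataFrame, stages: Timescale, rounding: str = "nearest"
) -> tuple[int, int]:
    """Duration of one species in (stages, whole My).

    First occurrence resolves through the *early* stage of each record and
    last occurrence through the *late* stage, giving the outer bound of the
    range for records dated to a stage interval rather than a single stage.
    """
    try:
        first_idx = min(stages.by_name(s).index for s in occs["early_stage"])
        last_idx = max(stages.by_name(s).index for s in occs["late_stage"])
    except KeyError as exc:
        sp = occs["species_name"].iloc[0] if len(occs) else "?"
        raise KeyError(f"species {sp!r}: {exc.args[0]}") from None
    duration_stages = last_idx - first_idx + 1
    dist = abs(stage_midpoint(stages[first_idx]) - stage_midpoint(stages[last_idx]))
    return duration_stages, round_ma(dist, rounding)


def grid_cells(occs: pd.DataFrame) -> set[tuple[int, int]]:
    """Distinct 2-degree grid cells occupied by a set of occurrences.

    Cells are half-open intervals [2k, 2k+2) on both axes anchored at 0;
    the id is (floor(lng/2), floor(lat/2)). Occurrences without coordinates
    are skipped.
    """
    cells = set()
    for lng, lat in zip(occs["paleo_lng"], occs["paleo_lat"]):
        if pd.isna(lng) or pd.isna(lat):
            continue
        cells.add((int(math.floor(lng / 2.0)), int(math.floor(lat / 2.0))))
    return cells


@dataclass
class SpeciesSummary:
    """All per-species quantities the comparisons consume."""

    species_name: str
    taxon_group: str
    first_stage_index: int
    last_stage_index: int
    duration_stages: int
    duration_ma: int
    is_single_interval: bool
    n_occurrences: int
    grid_cell_count: int
    occupied_stages: frozenset  # stage indices with a dated occurrence
    in_lagerstatte: bool
    habitat: HabitatAssignment | None = None


def build_species_summaries(
    table: OccurrenceTable,
    stages: Timescale,
    habitat_map: HabitatMap | None = None,
    rounding: str = "nearest",
) -> list[SpeciesSummary]:
    """Aggregate an occurrence table into one summary per species.

    Occupied stages collect the early- and late-stage index of every record
    (interior stages of a two-stage record are not presumed sampled). Habitat
    sets are attached where the species has at least one assignable
    lithology; species without one keep ``habitat=None`` and still enter the
    taxon-level and quality analyses.
    """
    assignments, _ = species_habitat_sets(table, habitat_map)
    by_name = {a.species_name: a for a in assignments}
    out: list[SpeciesSummary] = []
    for sp, occs in table.df.groupby("species_name", sort=True):
        dur_stages, dur_ma = species_duration(occs, stages, rounding)
        occupied = frozenset(
            stages.by_name(s).index for s in occs["early_stage"]
        ) | frozenset(stages.by_name(s).index for s in occs["late_stage"])
        groups = occs["taxon_group"].mode()
        out.append(
            SpeciesSummary(
                species_name=sp,
                taxon_group=str(groups.iloc[0]),
                first_stage_index=min(occupied),
                last_stage_index=max(occupied),
                duration_stages=dur_stages,
                duration_ma=dur_ma,
                is_single_interval=dur_stages == 1,
                n_occurrences=len(occs),
                grid_cell_count=len(grid_cells(occs)),
                occupied_stages=occupied,
                in_lagerstatte=bool(occs["is_lagerstatte"].any()),
                habitat=by_name.get(sp),
            )
        )
    return out


def summaries_frame(summaries: list[SpeciesSummary]) -> pd.DataFrame:
    """Flatten summaries for TSV export (habitat sets ';'-joined)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "species_name": s.species_name,
                "taxon_group": s.taxon_group,
                "first_stage_index": s.first_stage_index,
                "last_stage_index": s.last_stage_index,
                "duration_stages": s.duration_stages,
                "duration_ma": s.duration_ma,
                "is_single_interval": s.is_single_interval,
                "n_occurrences": s.n_occurrences,
                "grid_cell_count": s.grid_cell_count,
                "in_lagerstatte": s.in_lagerstatte,
                "level1": ";".join(sorted(s.habitat.level1)) if s.habitat else "",
                "level2": ";".join(sorted(s.habitat.level2)) if s.habitat else "",
                "level3": ";".join(sorted(s.habitat.level3)) if s.habitat else "",
            }
        )
    return pd.DataFrame(rows)


def stratify_by_range(
    summaries: list[SpeciesSummary], rule: str = "single_cell"
) -> dict[str, list[SpeciesSummary]]:
    """Partition species into small- and large-range strata.

    ``single_cell``: small = exactly one occupied grid cell, large = two or
    more. ``median``: split at the median cell count (ties to small).
    """
    counts = np.array([s.grid_cell_count for s in summaries])
    if rule == "single_cell":
        cut = 1
    elif rule == "median":
        cut = float(np.median(counts))
    else:
        raise ValueError(f"unknown range rule {rule!r}")
    small = [s for s in summaries if s.grid_cell_count <= cut]
    large = [s for s in summaries if s.grid_cell_count > cut]
    if not large:
        warnings.warn("large-range stratum is empty", stacklevel=2)
    return {"small": small, "large": large}
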