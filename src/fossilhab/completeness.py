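"""Fossil-record quality and completeness metrics.

Three preservation/completeness views of an occurrence dataset:

* **FreqRat** — the Foote-Raup frequency-ratio estimator of per-stage
  preservation probability, ``f2^2 / (f1 * f3)``, where f1, f2, f3 count
  taxa with stratigraphic ranges of one, two and three stages. Under the
  model of exponentially distributed true durations and independent
  per-stage sampling, the ratio estimates the per-stage sampling
  probability; low values mean many short observed ranges and a poorly
  sampled record.
* **SCM** (simple completeness metric) — per taxon, the share of stages
  within its observed first-to-last range that actually yield a fossil:
  known record / assumed record. 1 means a gapless record. An
  endpoint-excluded variant scores only the interior stages, removing the
  guaranteed hits at the range ends that make singleton-rich datasets look
  artificially complete.
* **Proportion of living taxa with a fossil record** — how much of the
  extant fauna has been found as a fossil at all.

Specimen condition (the ordinal 1-5 completeness score: isolated bones up to
multiple skeletons) is compared between habitats or taxa with the same
trimmed-mean / Kruskal-Wallis / pairwise-Wilcoxon machinery used for
durations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occurrence_io import OccurrenceTable
from .stats import GroupComparisonResult, compare_groups

__all__ = [
    "FreqRatResult",
    "SCMResult",
    "freqrat",
    "scm",
    "genus_of",
    "aggregate_scm",
    "aggregate_freqrat",
    "proportion_with_fossil",
    "specimen_completeness_compare",
    "quality_report",
]


@dataclass
class FreqRatResult:
    f1: int
    f2: int
    f3: int
    value: float  # nan when undefined
    undefined: bool

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.f1, self.f2, self.f3)


def freqrat(durations_stages, denominator_factor: float = 1.0) -> FreqRatResult:
    """FreqRat preservation probability from a multiset of stage durations.

    ``denominator_factor`` scales the denominator (value =
    f2^2 / (factor * f1 * f3)); the default 1 is the Foote-Raup ratio.
    The result is flagged undefined when any of f1, f2, f3 is zero.
    """
    durations = list(durations_stages)
    if not durations:
        raise ValueError("empty duration multiset")
    tally = Counter(int(d) for d in durations)
    f1, f2, f3 = tally.get(1, 0), tally.get(2, 0), tally.get(3, 0)
    if f1 == 0 or f2 == 0 or f3 == 0:
        return FreqRatResult(f1, f2, f3, float("nan"), True)
    return FreqRatResult(f1, f2, f3, f2**2 / (denominator_factor * f1 * f3), False)


@dataclass
class SCMResult:
    known: int
    assumed: int
    value: float  # nan when undefined
    endpoints_excluded: bool
    undefined: bool = False


def scm(occupied_stage_indices, exclude_endpoints: bool = False) -> SCMResult:
    """Simple completeness metric of one taxon's occupied-stage set.

    known = number of occupied stages, assumed = full span max-min+1.
    With ``exclude_endpoints`` both counts are restricted to stages strictly
    inside the range; taxa spanning fewer than three stages then have no
    interior and yield a flagged undefined result.
    """
    occ = set(int(i) for i in occupied_stage_indices)
    if not occ:
        raise ValueError("empty occupancy set")
    lo, hi = min(occ), max(occ)
    if exclude_endpoints:
        interior = set(range(lo + 1, hi))
        if not interior:
            return SCMResult(0, 0, float("nan"), True, undefined=True)
        known = len(occ & interior)
        assumed = len(interior)
    else:
        known = len(occ)
        assumed = hi - lo + 1
    return SCMResult(known, assumed, known / assumed, exclude_endpoints)


def genus_of(species_name: str) -> str:
    """Genus = first whitespace-separated token of a binomial."""
    return str(species_name).split()[0]


def _occupancy_by_taxon(
    summaries, level: str, family_lookup: dict[str, str] | None
) -> dict[str, set]:
    occ: dict[str, set] = {}
    for s in summaries:
        if level == "species":
            key = s.species_name
        elif level == "genus":
            key = genus_of(s.species_name)
        elif level == "family":
            if family_lookup is None:
                raise ValueError("family-level aggregation requires a family lookup")
            key = family_lookup.get(s.species_name)
            if key is None:
                continue
        else:
            raise ValueError(f"unknown taxon level {level!r}")
        occ.setdefault(key, set()).update(s.occupied_stages)
    return occ


def aggregate_scm(
    summaries,
    level: str = "species",
    mode: str = "pooled",
    exclude_endpoints: bool = False,
    family_lookup: dict[str, str] | None = None,
) -> float:
    """SCM aggregated over taxa at species, genus or family level.

    ``pooled`` divides total known by total assumed record (taxa with long
    ranges weigh more); ``mean`` averages per-taxon ratios. Taxa whose SCM
    is undefined under endpoint exclusion are dropped from either mode.
    """
    occ = _occupancy_by_taxon(summaries, level, family_lookup)
    results = [scm(v, exclude_endpoints) for v in occ.values()]
    results = [r for r in results if not r.undefined]
    if not results:
        return float("nan")
    if mode == "pooled":
        assumed = sum(r.assumed for r in results)
        return sum(r.known for r in results) / assumed if assumed else float("nan")
    if mode == "mean":
        return float(np.mean([r.value for r in results]))
    raise ValueError(f"unknown mode {mode!r}")


def aggregate_freqrat(
    summaries,
    level: str = "species",
    family_lookup: dict[str, str] | None = None,
    denominator_factor: float = 1.0,
) -> FreqRatResult:
    """FreqRat at species/genus/family rank from per-taxon pooled ranges.

    Above the species rank a taxon's range spans the union of its species'
    occupied stages (max minus min index, plus one).
    """
    occ = _occupancy_by_taxon(summaries, level, family_lookup)
    durations = [max(v) - min(v) + 1 for v in occ.values()]
    return freqrat(durations, denominator_factor)


def proportion_with_fossil(extant_taxa, fossil_taxa) -> float:
    """Share of the living taxa already known from the fossil record."""
    extant = set(extant_taxa)
    if not extant:
        raise ValueError("empty extant-taxon set")
    return len(extant & set(fossil_taxa)) / len(extant)


def specimen_completeness_compare(
    table: OccurrenceTable,
    grouping: str = "habitat",
    habitat_map=None,
    level: int = 1,
    trim: float = 0.1,
) -> GroupComparisonResult:
    """Compare specimen-condition scores between habitats or taxon groups.

    Operates on the occurrences that carry a score (condition was typically
    scored for a sample, not the full dataset). ``grouping='habitat'`` bins
    each scored occurrence by its own lithology's level-1 category (an
    occurrence is a single collection event, so no species-level dedup
    applies here); ``grouping='taxon'`` bins by taxon_group.
    """
    from .habitat import EXCLUDED, default_habitat_map, rollup_level2, rollup_level3

    df = table.df[table.df["specimen_score"].notna()]
    groups: dict[str, list[float]] = {}
    if grouping == "habitat":
        habitat_map = habitat_map or default_habitat_map()
        for lith, score in zip(df["lithology"], df["specimen_score"]):
            cat = habitat_map.match(lith)
            if cat == EXCLUDED:
                continue
            if level == 2:
                cat = rollup_level2(cat)
            elif level == 3:
                cat = rollup_level3(cat)
            groups.setdefault(cat, []).append(float(score))
    elif grouping == "taxon":
        for g, score in zip(df["taxon_group"], df["specimen_score"]):
            groups.setdefault(g, []).append(float(score))
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    groups = dict(sorted(groups.items()))
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups with specimen scores")
    return compare_groups(groups, grouping=f"specimen:{grouping}", trim=trim)


def quality_report(
    summaries,
    family_lookup: dict[str, str] | None = None,
    denominator_factor: float = 1.0,
) -> pd.DataFrame:
    """One-row-per-metric quality table (metric, rank, value, detail)."""
    rows = []
    levels = ["species", "genus"] + (["family"] if family_lookup else [])
    for level in levels:
        fr = aggregate_freqrat(summaries, level, family_lookup, denominator_factor)
        rows.append(
            {
                "metric": "freqrat",
                "rank": level,
                "value": fr.value,
                "detail": f"f1={fr.f1},f2={fr.f2},f3={fr.f3}",
            }
        )
        for excl in (False, True):
            for mode in ("pooled", "mean"):
                rows.append(
                    {
                        "metric": "scm_no_endpoints" if excl else "scm",
                        "rank": level,
                        "value": aggregate_scm(
                            summaries, level, mode, excl, family_lookup
                        ),
                        "detail": mode,
                    }
                )
    return pd.DataFrame(rows)
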