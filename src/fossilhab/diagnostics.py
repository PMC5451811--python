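"""Reliability diagnostics for single-interval species.

Species known from one geological stage (singletons) dominate many fossil
datasets; their nominally zero durations are only trustworthy if they are
not artefacts of how the record was sampled. Four checks probe that:

* stage-length correlations — if singletons were produced by coarse temporal
  binning, longer stages should hold more (and a larger share of) them;
* lagerstätten test — deposits of exceptional preservation find rare species
  that ordinary sampling misses, so singleton proportions are compared
  between species with and without a lagerstätte occurrence;
* monographic effect — intensively worked-up publications (many occurrences)
  likewise sweep up rare species; the singleton share among species covered
  by such publications is compared with the overall share;
* singleton-by-habitat tests — whether the singleton proportion differs
  between habitat categories (it should, if short durations are ecology
  rather than artefact, given preservation is *better* in quiet water).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .occurrence_io import OccurrenceTable, Timescale
from .stats import ChiSquareResult, chi_square_test

__all__ = [
    "SpearmanResult",
    "spearman",
    "stage_occupancy_table",
    "stage_singleton_correlations",
    "lagerstatten_test",
    "monographic_effect",
    "singleton_habitat_test",
    "singleton_occurrence_proportion",
]


@dataclass
class SpearmanResult:
    rho: float
    pvalue: float
    n: int
    undefined: bool = False


def spearman(x, y, method: str = "t") -> SpearmanResult:
    """Spearman rank correlation with tie-corrected rho.

    ``method='t'`` uses the usual t-approximation for the p-value;
    ``method='exact'`` enumerates all rank permutations (n <= 10 only).
    A constant input vector leaves rho undefined (flagged, not an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(float("nan"), float("nan"), x.size, undefined=True)
    if method == "t":
        rho, p = sps.spearmanr(x, y)
        return SpearmanResult(float(rho), float(p), x.size)
    if method == "exact":
        n = x.size
        if n > 10:
            raise ValueError("exact permutation p only for n <= 10")
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = float(sps.spearmanr(x, y).statistic)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            if abs(r) >= abs(obs) - 1e-12:
                count += 1
            total += 1
        return SpearmanResult(obs, count / total, n)
    raise ValueError(f"unknown method {method!r}")


def stage_occupancy_table(
    stages: Timescale, summaries, membership: str = "range_through"
) -> pd.DataFrame:
    """Per-stage richness and singleton counts.

    ``range_through`` counts a species in every stage from its first to its
    last occurrence; ``occurrences`` counts only stages it actually occurs
    in. Singletons occupy exactly one stage under either convention.
    """
    n = len(stages)
    richness = np.zeros(n, dtype=int)
    singletons = np.zeros(n, dtype=int)
    for s in summaries:
        if membership == "range_through":
            member = range(s.first_stage_index, s.last_stage_index + 1)
        elif membership == "occurrences":
            member = sorted(s.occupied_stages)
        else:
            raise ValueError(f"unknown membership {membership!r}")
        for idx in member:
            richness[idx] += 1
            if s.is_single_interval:
                singletons[idx] += 1
    with np.errstate(invalid="ignore"):
        prop = np.where(richness > 0, singletons / np.maximum(richness, 1), np.nan)
    return pd.DataFrame(
        {
            "stage_index": np.arange(n),
            "stage_name": [st.name for st in stages],
            "stage_length_ma": [st.length_ma for st in stages],
            "richness": richness,
            "n_singletons": singletons,
            "prop_singletons": prop,
        }
    )


def stage_singleton_correlations(
    stages: Timescale,
    summaries,
    membership: str = "range_through",
    method: str = "t",
) -> dict[str, SpearmanResult]:
    """Spearman correlations of stage length with richness and singletons.

    Returns results keyed ``richness``, ``n_singletons``, ``prop_singletons``;
    stages with zero richness are dropped from the proportion correlation.
    """
    occ = stage_occupancy_table(stages, summaries, membership)
    if len(occ) < 3:
        raise ValueError("need >= 3 stages")
    out = {
        "richness": spearman(occ["stage_length_ma"], occ["richness"], method),
        "n_singletons": spearman(occ["stage_length_ma"], occ["n_singletons"], method),
    }
    has = occ[occ["richness"] > 0]
    if len(has) >= 3:
        out["prop_singletons"] = spearman(
            has["stage_length_ma"], has["prop_singletons"], method
        )
    else:
        out["prop_singletons"] = SpearmanResult(
            float("nan"), float("nan"), len(has), undefined=True
        )
    return out


def lagerstatten_test(summaries, yates: bool | None = None) -> ChiSquareResult:
    """2x2 chi-square: lagerstätte membership against singleton status.

    A species is in the lagerstätte stratum if any of its occurrences is
    flagged. Yates continuity correction follows the 2x2 default unless
    overridden.
    """
    counts = np.zeros((2, 2), dtype=int)
    for s in summaries:
        counts[0 if s.in_lagerstatte else 1, 0 if s.is_single_interval else 1] += 1
    obs = pd.DataFrame(
        counts,
        index=["lagerstatte", "no_lagerstatte"],
        columns=["singleton", "not_singleton"],
    )
    if (obs.sum(axis=1) == 0).any():
        raise ValueError("need both lagerstätte and non-lagerstätte species")
    return chi_square_test(obs, yates=yates)


def monographic_effect(
    table: OccurrenceTable, summaries, min_occurrences: int = 20
) -> tuple[float, float]:
    """Singleton proportions: species from large publications vs all species.

    A "large" publication covers more than ``min_occurrences`` occurrences.
    Returns (proportion among species appearing in large publications,
    proportion overall); the first is nan when no publication qualifies.
    Similar values indicate the dataset is free of monographic inflation of
    rare species.
    """
    singleton = {s.species_name: s.is_single_interval for s in summaries}
    df = table.df[table.df["reference_id"].astype(str).str.strip() != ""]
    ref_sizes = df.groupby("reference_id").size()
    big_refs = ref_sizes[ref_sizes > min_occurrences].index
    big_species = set(df[df["reference_id"].isin(big_refs)]["species_name"])
    big_species &= set(singleton)

    overall = float(np.mean([v for v in singleton.values()])) if singleton else math.nan
    if not big_species:
        return float("nan"), overall
    big = float(np.mean([singleton[sp] for sp in big_species]))
    return big, overall


def singleton_habitat_test(
    summaries, level: int = 1, yates: bool | None = None
) -> ChiSquareResult:
    """Chi-square of singleton status against habitat category.

    The contingency table counts species once per category of the requested
    habitat level (1 or 3; level 2 is also accepted). Categories with no
    species are dropped with a warning by the underlying test.
    """
    counts: dict[str, list[int]] = {}
    for s in summaries:
        if s.habitat is None:
            continue
        for cat in sorted(getattr(s.habitat, f"level{level}")):
            counts.setdefault(cat, [0, 0])
            counts[cat][0 if s.is_single_interval else 1] += 1
    if len(counts) < 2:
        raise ValueError("need >= 2 populated habitat categories")
    obs = pd.DataFrame(
        counts, index=["singleton", "not_singleton"]
    ).T.sort_index()
    return chi_square_test(obs, yates=yates)


def singleton_occurrence_proportion(table: OccurrenceTable, summaries) -> dict[str, float]:
    """Per-source-database share of occurrences belonging to singletons.

    A log statistic: comparable proportions across databases suggest neither
    source is singleton-inflated relative to the other.
    """
    singleton = {s.species_name: s.is_single_interval for s in summaries}
    out = {}
    for db, df in table.df.groupby("source_db"):
        flags = [singleton.get(sp, False) for sp in df["species_name"]]
        out[str(db)] = float(np.mean(flags)) if flags else float("nan")
    return out
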