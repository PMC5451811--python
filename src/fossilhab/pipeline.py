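"""End-to-end analysis runs.

The full sequence mirrors how the analysis must be ordered scientifically:
quality gates first (preservation probability, completeness, singleton
diagnostics), inference second (habitat assignment, durations, range sizes,
group comparisons). Every stage is also callable on its own through the
module functions or the CLI subcommands; :func:`run_all` only sequences
them and assembles their outputs — no number in the summary is recomputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import chronology, completeness, diagnostics, habitat, occurrence_io, stats

logger = logging.getLogger("fossilhab")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Paths and switches for one full analysis run."""

    occurrences: str
    timescale: str
    out_dir: str
    dialect: str = "generic"
    habitat_map: str | None = None
    extant_list: str | None = None
    synonym_map: str | None = None
    family_lookup: str | None = None
    rounding: str = "nearest"  # duration rounding: nearest | ceiling
    yates: bool | None = None  # None = Yates exactly for 2x2 tables
    freqrat_denominator_factor: float = 1.0
    scm_mode: str = "pooled"
    exclude_singletons: bool = False
    range_rule: str = "single_cell"
    min_occurrences: int = 20  # monograph threshold
    trim: float = 0.1
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _read_two_col_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="," if str(path).endswith(".csv") else "\t")
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))


def _comparison_specs(cfg: RunConfig):
    """(name, kwargs) for every duration/range comparison of a full run."""
    specs = []
    for level in (1, 2, 3):
        specs.append((f"duration_level{level}", dict(grouping=f"level{level}")))
    specs.append(("duration_taxa_lissamphibia", dict(grouping="taxon:lissamphibia")))
    specs.append(("duration_taxa_higher", dict(grouping="taxon:higher")))
    for taxon in occurrence_io.TAXON_GROUPS:
        if taxon == "other":
            continue
        for level in (1, 2, 3):
            specs.append(
                (
                    f"duration_within_{taxon}_level{level}",
                    dict(grouping=f"level{level}", taxon_restrict=taxon),
                )
            )
    for level in (1, 3):
        specs.append(
            (f"range_level{level}", dict(grouping=f"level{level}", value="grid_cell_count"))
        )
    for stratum in ("small", "large"):
        specs.append(
            (
                f"duration_level2_range_{stratum}",
                dict(grouping="level2", range_stratum=stratum, range_rule=cfg.range_rule),
            )
        )
    for level in (1, 2, 3):
        specs.append(
            (
                f"duration_level{level}_no_singletons",
                dict(grouping=f"level{level}", exclude_singletons=True),
            )
        )
    return specs


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Writes, under ``cfg.out_dir``: filtered occurrences, species summaries,
    habitat assignments, the quality report, diagnostics, one long-format
    comparisons table, a machine-readable ``summary.json`` and ``run.log``
    with all filter counts and the effective configuration. Returns the
    summary dict.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    log_lines: list[str] = [f"effective config: {asdict(cfg)}"]
    notices: list[str] = []

    # --- ingest ---------------------------------------------------------
    synonyms = _read_two_col_map(cfg.synonym_map) if cfg.synonym_map else None
    table = occurrence_io.read_occurrences(cfg.occurrences, cfg.dialect, synonyms)
    if cfg.extant_list:
        extant = set(
            pd.read_csv(cfg.extant_list, sep="\t" if cfg.extant_list.endswith(".tsv") else ",")
            .iloc[:, 0]
            .astype(str)
        )
        table = occurrence_io.drop_extant(table, extant)
    stages = occurrence_io.read_timescale(cfg.timescale)
    log_lines.append(f"filter log: {table.filter_log}")
    occurrence_io.write_table(table, out / "occurrences_filtered.tsv")

    hab_map = (
        habitat.load_habitat_map(cfg.habitat_map)
        if cfg.habitat_map
        else habitat.default_habitat_map()
    )
    family_lookup = _read_two_col_map(cfg.family_lookup) if cfg.family_lookup else None

    # --- habitat assignment & per-species summaries ---------------------
    assignments, hab_log = habitat.species_habitat_sets(table, hab_map)
    log_lines.append(f"habitat log: {hab_log}")
    occurrence_io.write_table(
        habitat.habitat_sets_frame(assignments), out / "habitat_assignments.tsv"
    )
    summaries = chronology.build_species_summaries(table, stages, hab_map, cfg.rounding)
    occurrence_io.write_table(
        chronology.summaries_frame(summaries), out / "species_summaries.tsv"
    )
    n_assigned = sum(1 for s in summaries if s.habitat is not None)
    assert len(summaries) == n_assigned + (len(summaries) - n_assigned)

    # --- quality metrics -------------------------------------------------
    quality = completeness.quality_report(
        summaries, family_lookup, cfg.freqrat_denominator_factor
    )
    occurrence_io.write_table(quality, out / "quality_report.tsv")
    specimen = {}
    if table.df["specimen_score"].notna().any():
        for grouping in ("habitat", "taxon"):
            try:
                res = completeness.specimen_completeness_compare(
                    table, grouping, hab_map, trim=cfg.trim
                )
                specimen[grouping] = res
                occurrence_io.write_table(
                    res.to_frame(), out / f"specimen_completeness_{grouping}.tsv"
                )
            except ValueError as exc:
                notices.append(f"specimen comparison ({grouping}) skipped: {exc}")
    else:
        notices.append("no specimen scores present; specimen comparisons skipped")

    # --- singleton bias diagnostics --------------------------------------
    diag: dict = {}
    try:
        corr = diagnostics.stage_singleton_correlations(stages, summaries)
        diag["stage_correlations"] = {
            k: {"rho": v.rho, "p": v.pvalue, "n": v.n, "undefined": v.undefined}
            for k, v in corr.items()
        }
    except ValueError as exc:
        notices.append(f"stage correlations skipped: {exc}")
    occurrence_io.write_table(
        diagnostics.stage_occupancy_table(stages, summaries), out / "stage_occupancy.tsv"
    )
    try:
        lager = diagnostics.lagerstatten_test(summaries, cfg.yates)
        diag["lagerstatten"] = {
            "chi2": lager.statistic,
            "df": lager.df,
            "p": lager.pvalue,
            "observed": lager.observed.to_dict(),
        }
    except ValueError as exc:
        notices.append(f"lagerstätten test skipped: {exc}")
    big, overall = diagnostics.monographic_effect(table, summaries, cfg.min_occurrences)
    diag["monographic"] = {
        "prop_singletons_large_pubs": big,
        "prop_singletons_overall": overall,
    }
    for level in (1, 3):
        try:
            res = diagnostics.singleton_habitat_test(summaries, level, cfg.yates)
            diag[f"singleton_habitat_level{level}"] = {
                "chi2": res.statistic,
                "df": res.df,
                "p": res.pvalue,
            }
        except ValueError as exc:
            notices.append(f"singleton-habitat test (level {level}) skipped: {exc}")
    diag["singleton_occurrence_proportion_by_db"] = (
        diagnostics.singleton_occurrence_proportion(table, summaries)
    )

    # --- comparisons ------------------------------------------------------
    comparison_frames = []
    comparisons: dict = {}
    for name, kwargs in _comparison_specs(cfg):
        try:
            res = stats.compare_durations(summaries, trim=cfg.trim, **kwargs)
        except ValueError as exc:
            notices.append(f"comparison {name} skipped: {exc}")
            continue
        comparisons[name] = res
        frame = res.to_frame()
        frame.insert(0, "analysis", name)
        comparison_frames.append(frame)
    if comparison_frames:
        occurrence_io.write_table(
            pd.concat(comparison_frames, ignore_index=True), out / "comparisons.tsv"
        )
    else:
        notices.append("no comparison had >= 2 populated groups; comparison stage skipped")

    preference = {}
    for scheme in ("lissamphibia", "higher"):
        try:
            res = stats.habitat_preference_test(summaries, scheme)
            preference[scheme] = {
                "chi2": res.statistic,
                "df": res.df,
                "p": res.pvalue,
            }
        except ValueError as exc:
            notices.append(f"habitat preference ({scheme}) skipped: {exc}")

    # --- assemble summary -------------------------------------------------
    summary = {
        "counts": {
            "occurrences": len(table),
            "species": len(summaries),
            "species_with_habitat": n_assigned,
            "singletons": sum(s.is_single_interval for s in summaries),
        },
        "filter_log": table.filter_log,
        "habitat_log": hab_log,
        "stage_length_median_ma": float(
            pd.Series([s.length_ma for s in stages]).median()
        ),
        "quality": quality.to_dict(orient="records"),
        "specimen": {
            k: {
                "trimmed_means": v.group_trimmed_mean,
                "omnibus_p": v.pvalue,
            }
            for k, v in specimen.items()
        },
        "diagnostics": diag,
        "habitat_preference": preference,
        "comparisons": {
            name: {
                "group_n": res.group_n,
                "trimmed_means": res.group_trimmed_mean,
                "omnibus_H": res.statistic,
                "omnibus_df": res.df,
                "omnibus_p": res.pvalue,
                "pairwise_adjusted_p": {
                    f"{a}|{b}": float(res.pairwise_adjusted_p.loc[a, b])
                    for a in res.group_n
                    for b in res.group_n
                    if a < b
                },
            }
            for name, res in comparisons.items()
        },
        "notices": notices,
    }
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=float)
    with open(out / "run.log", "w", encoding="utf-8") as fh:
        fh.write("\n".join(log_lines + [f"notice: {n}" for n in notices]) + "\n")
    logger.info("run complete: %d occurrences, %d species", len(table), len(summaries))
    return summary
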