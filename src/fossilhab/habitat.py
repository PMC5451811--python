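"""Lithology-based habitat classification.

Each occurrence's lithology (free text) is mapped to one of four first-level
habitat categories ordered by water-flow energy of the depositional setting —
*stagnant*, *low-velocity*, *medium-velocity*, *high-velocity* — or excluded
when the rock type carries no energetic signal (missing entries, cave infill).
Two coarser levels are fixed rollups of level 1: level 2 contrasts *lentic*
(standing water) with *lotic* (flowing water), level 3 *low* with *high*
energy. A species is assigned at most once per category on each level, no
matter how many of its occurrences share a lithology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .occurrence_io import OccurrenceTable

__all__ = [
    "LEVEL1_CATEGORIES",
    "LEVEL2_ROLLUP",
    "LEVEL3_ROLLUP",
    "EXCLUDED",
    "HabitatRule",
    "HabitatMap",
    "HabitatAssignment",
    "default_habitat_map",
    "load_habitat_map",
    "assign_level1",
    "rollup_level2",
    "rollup_level3",
    "species_habitat_sets",
    "habitat_sets_frame",
]

LEVEL1_CATEGORIES = ("stagnant", "low-velocity", "medium-velocity", "high-velocity")
EXCLUDED = "excluded"
#: Rule categories that bypass level 1 and contribute directly to a coarser
#: level (permitted by the map format; the default map defines none).
_DIRECT_LEVEL2 = ("lentic", "lotic")
_DIRECT_LEVEL3 = ("low", "high")
_VALID_RULE_CATEGORIES = LEVEL1_CATEGORIES + (EXCLUDED,) + _DIRECT_LEVEL2 + _DIRECT_LEVEL3

LEVEL2_ROLLUP = {
    "stagnant": "lentic",
    "low-velocity": "lotic",
    "medium-velocity": "lotic",
    "high-velocity": "lotic",
}
LEVEL3_ROLLUP = {
    "stagnant": "low",
    "low-velocity": "low",
    "medium-velocity": "high",
    "high-velocity": "high",
}


@dataclass(frozen=True)
class HabitatRule:
    pattern: str  # case-insensitive substring matched on normalised lithology
    category: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.category not in _VALID_RULE_CATEGORIES:
            raise ValueError(
                f"rule {self.pattern!r}: category {self.category!r} not one of "
                f"{_VALID_RULE_CATEGORIES}"
            )


@dataclass
class HabitatMap:
    """Ordered, first-match-wins lithology classification rules."""

    rules: list[HabitatRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("habitat map needs at least one rule")

    def match(self, lithology) -> str:
        """Category of the first rule matching the normalised lithology.

        Blank/missing lithology and unmatched text both yield ``excluded``.
        """
        if lithology is None or (isinstance(lithology, float) and pd.isna(lithology)):
            return EXCLUDED
        text = " ".join(str(lithology).lower().split())
        if not text:
            return EXCLUDED
        for rule in self.rules:
            if rule.pattern in text:
                return rule.category
        return EXCLUDED


def default_habitat_map() -> HabitatMap:
    """The map shipped with the package.

    Follows the grain-size/flow-energy gradient of siliciclastic rocks:
    fine-grained quiet-water deposits (claystone through tuff) are stagnant,
    siltstone low-velocity, sandstone medium-velocity, and coarse rudites
    high-velocity. Cross-stratified variants indicate traction transport and
    are bumped one energy class up, which the rule ordering implements.
    Non-informative deposits (cave/karst/fissure infill) are excluded. The
    map is replaceable via a YAML config for datasets whose lithological
    vocabulary differs.
    """
    rows = [
        # non-informative first so nothing below can claim them
        ("cave", EXCLUDED, "no energetic signal"),
        ("karst", EXCLUDED, "no energetic signal"),
        ("fissure", EXCLUDED, "no energetic signal"),
        # cross-stratified variants outrank their plain forms
        ("cross-stratified sandstone", "high-velocity", "traction structures"),
        ("cross-bedded sandstone", "high-velocity", "traction structures"),
        ("cross-stratified siltstone", "medium-velocity", "traction structures"),
        ("cross-bedded siltstone", "medium-velocity", "traction structures"),
        # coarse rudites
        ("conglomerate", "high-velocity", "coarse clasts"),
        ("gravel", "high-velocity", "coarse clasts"),
        ("breccia", "high-velocity", "coarse clasts"),
        # arenites
        ("sandstone", "medium-velocity", "sand grade"),
        ("sand", "medium-velocity", "sand grade"),
        # silt grade
        ("siltstone", "low-velocity", "silt grade"),
        ("silt", "low-velocity", "silt grade"),
        # quiet-water fines and chemical/organic deposits
        ("claystone", "stagnant", "clay grade"),
        ("clay", "stagnant", "clay grade"),
        ("mudstone", "stagnant", "clay grade"),
        ("mud", "stagnant", "clay grade"),
        ("shale", "stagnant", "laminated fines"),
        ("lignite", "stagnant", "organic accumulation"),
        ("coal", "stagnant", "organic accumulation"),
        ("peat", "stagnant", "organic accumulation"),
        ("peal", "stagnant", "organic accumulation (archaic spelling)"),
        ("diatomite", "stagnant", "lacustrine biogenic"),
        ("dolomite", "stagnant", "carbonate"),
        ("gypsum", "stagnant", "evaporite"),
        ("gyps", "stagnant", "evaporite"),
        ("marl", "stagnant", "carbonate mud"),
        ("phosphorite", "stagnant", "condensed deposit"),
        ("tuff", "stagnant", "airfall into standing water"),
        ("limestone", "stagnant", "carbonate"),
        ("micrite", "stagnant", "carbonate mud"),
    ]
    return HabitatMap([HabitatRule(p, c, n) for p, c, n in rows])


def load_habitat_map(path) -> HabitatMap:
    """Load a habitat map from YAML/JSON: a list of {pattern, category, note}."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, list):
        raise ValueError("habitat map file must contain a list of rules")
    rules = [
        HabitatRule(
            pattern=str(item["pattern"]).lower(),
            category=str(item["category"]),
            note=str(item.get("note", "")),
        )
        for item in data
    ]
    return HabitatMap(rules)


def assign_level1(lithology, habitat_map: HabitatMap) -> str:
    """First-level category of a lithology string, or ``excluded``."""
    cat = habitat_map.match(lithology)
    # direct level-2/3 rules are not level-1 assignments
    if cat in _DIRECT_LEVEL2 or cat in _DIRECT_LEVEL3:
        return EXCLUDED
    return cat


def rollup_level2(level1_category: str) -> str:
    """stagnant -> lentic; the three flowing-water categories -> lotic."""
    try:
        return LEVEL2_ROLLUP[level1_category]
    except KeyError:
        raise ValueError(
            f"cannot roll up {level1_category!r}; excluded occurrences must be "
            "filtered before rollup"
        ) from None


def rollup_level3(level1_category: str) -> str:
    """stagnant and low-velocity -> low energy; the rest -> high energy."""
    try:
        return LEVEL3_ROLLUP[level1_category]
    except KeyError:
        raise ValueError(
            f"cannot roll up {level1_category!r}; excluded occurrences must be "
            "filtered before rollup"
        ) from None


@dataclass(frozen=True)
class HabitatAssignment:
    """Per-species deduplicated habitat sets on the three levels."""

    species_name: str
    level1: frozenset
    level2: frozenset
    level3: frozenset


def species_habitat_sets(
    table: OccurrenceTable, habitat_map: HabitatMap | None = None
) -> tuple[list[HabitatAssignment], dict]:
    """Build each species' habitat-category sets from its occurrences.

    Every assignable occurrence contributes its category to the species'
    level-1 set; levels 2 and 3 are the images of that set under the fixed
    rollups (plus any direct level-2/3 rule hits). A category enters a set
    at most once regardless of how many occurrences support it. Species
    with no assignable occurrence are omitted and counted in the log.

    Returns
    -------
    (assignments, log)
        ``assignments`` sorted by species name; ``log`` holds occurrence- and
        species-level exclusion counts.
    """
    habitat_map = habitat_map or default_habitat_map()
    l1: dict[str, set] = {}
    l2: dict[str, set] = {}
    l3: dict[str, set] = {}
    n_excluded_occ = 0
    for sp, lith in zip(table.df["species_name"], table.df["lithology"]):
        cat = habitat_map.match(lith)
        if cat == EXCLUDED:
            n_excluded_occ += 1
            continue
        l1.setdefault(sp, set())
        l2.setdefault(sp, set())
        l3.setdefault(sp, set())
        if cat in LEVEL1_CATEGORIES:
            l1[sp].add(cat)
            l2[sp].add(LEVEL2_ROLLUP[cat])
            l3[sp].add(LEVEL3_ROLLUP[cat])
        elif cat in _DIRECT_LEVEL2:
            l2[sp].add(cat)
        else:  # direct level-3 rule
            l3[sp].add(cat)

    assignments = [
        HabitatAssignment(sp, frozenset(l1[sp]), frozenset(l2[sp]), frozenset(l3[sp]))
        for sp in sorted(l1)
    ]
    all_species = set(table.df["species_name"])
    log = {
        "occurrences without assignable lithology": n_excluded_occ,
        "species without any assignable occurrence": len(all_species) - len(assignments),
    }
    return assignments, log


def habitat_sets_frame(assignments: list[HabitatAssignment]) -> pd.DataFrame:
    """Serialise assignments to a frame (sets as sorted ';'-joined strings)."""
    return pd.DataFrame(
        {
            "species_name": [a.species_name for a in assignments],
            "level1": [";".join(sorted(a.level1)) for a in assignments],
            "level2": [";".join(sorted(a.level2)) for a in assignments],
            "level3": [";".join(sorted(a.level3)) for a in assignments],
        }
    )
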