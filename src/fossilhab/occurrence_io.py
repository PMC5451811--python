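"""Reading, validation, filtering and writing of fossil occurrence tables.

The canonical in-memory containers are a :class:`pandas.DataFrame` with a
fixed column set (wrapped in :class:`OccurrenceTable` together with a filter
log) and an ordered sequence of :class:`GeologicalStage` bins.

Occurrence tables arrive as CSV/TSV exports from occurrence databases.
Column names differ between sources, so each supported *dialect* maps its
native headers onto the canonical schema; unknown extra columns are carried
through untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "GeologicalStage",
    "Timescale",
    "OccurrenceTable",
    "CANONICAL_COLUMNS",
    "TAXON_GROUPS",
    "QUALIFIER_TOKENS",
    "read_occurrences",
    "read_timescale",
    "drop_extant",
    "write_table",
    "read_table",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """Row-level content violates an invariant (bad coordinate, score...)."""


#: Canonical occurrence columns, in output order.
CANONICAL_COLUMNS = [
    "occurrence_id",
    "species_name",
    "taxon_group",
    "early_stage",
    "late_stage",
    "lithology",
    "paleo_lng",
    "paleo_lat",
    "reference_id",
    "is_lagerstatte",
    "specimen_score",
    "source_db",
]

#: Recognised taxonomic groups (amphibian orders, their stem groups, and the
#: two candidate stem clades of modern amphibians).
TAXON_GROUPS = [
    "Allocaudata",
    "Urodela",
    "Parabatrachia",
    "Salientia",
    "Gymnophiona",
    "Lepospondyli",
    "Temnospondyli",
    "other",
]

#: Open-nomenclature qualifiers whose presence anywhere in a name excludes
#: the record (case-insensitive literal match).
QUALIFIER_TOKENS = ("aff.", "cf.", "?")

# Per-dialect column aliases: native header -> canonical name.
_DIALECTS: dict[str, dict[str, str]] = {
    "generic": {},
    "pbdb": {
        "occurrence_no": "occurrence_id",
        "accepted_name": "species_name",
        "early_interval": "early_stage",
        "late_interval": "late_stage",
        "lithology1": "lithology",
        "paleolng": "paleo_lng",
        "paleolat": "paleo_lat",
        "reference_no": "reference_id",
    },
    "fosfar": {
        "id": "occurrence_id",
        "species": "species_name",
        "group": "taxon_group",
        "earliest_age": "early_stage",
        "latest_age": "late_stage",
        "rock_type": "lithology",
        "paleolongitude": "paleo_lng",
        "paleolatitude": "paleo_lat",
        "reference": "reference_id",
    },
}

_REQUIRED = ("species_name", "early_stage")

#: Columns that jointly identify a record; exact duplicates on this key are
#: collapsed to one row.
_DEDUP_KEY = [
    "species_name",
    "early_stage",
    "late_stage",
    "lithology",
    "reference_id",
    "paleo_lng",
    "paleo_lat",
]


@dataclass(frozen=True)
class GeologicalStage:
    """One chronostratigraphic time bin.

    ``base_ma`` is the age of the older boundary, ``top_ma`` of the younger
    one (Ma = million years before present); ``index`` runs from 0 at the
    oldest stage and increases towards the present.
    """

    name: str
    index: int
    base_ma: float
    top_ma: float

    def __post_init__(self) -> None:
        if not self.base_ma > self.top_ma >= 0:
            raise ValidationError(
                f"stage {self.name!r}: need base_ma > top_ma >= 0, "
                f"got base={self.base_ma}, top={self.top_ma}"
            )

    @property
    def midpoint_ma(self) -> float:
        return (self.base_ma + self.top_ma) / 2.0

    @property
    def length_ma(self) -> float:
        return self.base_ma - self.top_ma


class Timescale:
    """Ordered sequence of non-overlapping stages, oldest first."""

    def __init__(self, stages: list[GeologicalStage]):
        self.stages = list(stages)
        self._by_name = {s.name: s for s in self.stages}
        if len(self._by_name) != len(self.stages):
            raise ValidationError("duplicate stage names in timescale")

    def __len__(self) -> int:
        return len(self.stages)

    def __iter__(self):
        return iter(self.stages)

    def __getitem__(self, index: int) -> GeologicalStage:
        return self.stages[index]

    def by_name(self, name: str) -> GeologicalStage:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown stage name: {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [s.name for s in self.stages],
                "index": [s.index for s in self.stages],
                "base_ma": [s.base_ma for s in self.stages],
                "top_ma": [s.top_ma for s in self.stages],
            }
        )


@dataclass
class OccurrenceTable:
    """Validated occurrence rows plus provenance/filter bookkeeping.

    ``filter_log`` maps rule name -> number of rows removed by that rule;
    the conservation identity rows_in == len(df) + sum(filter_log.values())
    holds after reading.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    filter_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species(self) -> list[str]:
        return sorted(self.df["species_name"].unique())


def _has_qualifier(name: str) -> bool:
    low = str(name).lower()
    return any(tok in low for tok in QUALIFIER_TOKENS)


def _sniff_sep(path: str) -> str:
    p = str(path).lower()
    return "," if p.endswith(".csv") else "\t"


def _coerce_float(df: pd.DataFrame, col: str, lo: float, hi: float) -> pd.Series:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        rows = df.loc[bad, "occurrence_id"].tolist()
        raise ValidationError(f"unparseable {col} in rows: {rows}")
    oob = out.notna() & ((out < lo) | (out > hi))
    if oob.any():
        rows = df.loc[oob, "occurrence_id"].tolist()
        raise ValidationError(f"{col} outside [{lo}, {hi}] in rows: {rows}")
    return out


def read_occurrences(
    path,
    dialect: str = "generic",
    synonym_map: dict[str, str] | None = None,
) -> OccurrenceTable:
    """Read an occurrence CSV/TSV, validate it and apply the standard filters.

    Filters applied, in order, each logged with the count of rows removed:
    name-qualifier exclusion (``aff.``, ``cf.``, ``?``) and exact-duplicate
    collapse. ``synonym_map`` (old name -> harmonised name) is applied before
    filtering so that duplicates across synonymised names collapse too.

    Parameters
    ----------
    path : str or Path
        CSV (comma) or TSV (tab) file; delimiter chosen from the extension.
    dialect : {"generic", "pbdb", "fosfar"}
        Column-name alias set of the source database.
    synonym_map : dict, optional
        Taxonomic harmonisation applied to ``species_name`` at read time.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    df = df.rename(columns=_DIALECTS[dialect])

    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(
            f"missing required column(s) for dialect {dialect!r}: {', '.join(missing)}"
        )

    # Fill optional canonical columns so downstream code sees a fixed schema.
    defaults = {
        "occurrence_id": None,
        "taxon_group": "other",
        "late_stage": None,
        "lithology": "",
        "paleo_lng": "",
        "paleo_lat": "",
        "reference_id": "",
        "is_lagerstatte": "",
        "specimen_score": "",
        "source_db": dialect if dialect != "generic" else "synthetic",
    }
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    if df["occurrence_id"].isna().all() or (df["occurrence_id"] == "").all():
        df["occurrence_id"] = [f"row{i}" for i in range(len(df))]
    blank_late = df["late_stage"].isna() | (df["late_stage"].astype(str).str.strip() == "")
    df.loc[blank_late, "late_stage"] = df.loc[blank_late, "early_stage"]

    df["paleo_lng"] = _coerce_float(df, "paleo_lng", -180.0, 180.0)
    df["paleo_lat"] = _coerce_float(df, "paleo_lat", -90.0, 90.0)

    score = pd.to_numeric(df["specimen_score"], errors="coerce")
    raw_score = df["specimen_score"].astype(str).str.strip()
    bad = (score.isna() & (raw_score != "")) | (
        score.notna() & (~score.isin([1, 2, 3, 4, 5]))
    )
    if bad.any():
        rows = df.loc[bad, "occurrence_id"].tolist()
        raise ValidationError(f"specimen_score not an integer in [1,5] in rows: {rows}")
    df["specimen_score"] = score.astype("Int64")

    flag = df["is_lagerstatte"].astype(str).str.strip().str.lower()
    df["is_lagerstatte"] = flag.isin(("1", "true", "yes", "y", "t"))

    unknown = ~df["taxon_group"].isin(TAXON_GROUPS)
    df.loc[unknown, "taxon_group"] = "other"

    if synonym_map:
        df["species_name"] = df["species_name"].map(lambda s: synonym_map.get(s, s))

    log: dict[str, int] = {}
    n_in = len(df)

    qual = df["species_name"].map(_has_qualifier).astype(bool)
    log["qualifier names removed"] = int(qual.sum())
    df = df[~qual]

    before = len(df)
    df = df.drop_duplicates(subset=_DEDUP_KEY, keep="first")
    log["duplicates removed"] = before - len(df)

    df = df.reset_index(drop=True)
    assert n_in == len(df) + sum(log.values())
    return OccurrenceTable(
        df=df[CANONICAL_COLUMNS + [c for c in df.columns if c not in CANONICAL_COLUMNS]],
        provenance={"path": str(path), "dialect": dialect, "rows_in": n_in},
        filter_log=log,
    )


def read_timescale(path) -> Timescale:
    """Read a timescale table (columns: name, base_ma, top_ma).

    Stages are sorted oldest to youngest. Overlapping stages are rejected;
    gaps between consecutive stages only raise a warning, since standard
    timescales may omit intervals a dataset never samples.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path))
    missing = [c for c in ("name", "base_ma", "top_ma") if c not in df.columns]
    if missing:
        raise FormatError(f"timescale missing column(s): {', '.join(missing)}")
    bad = ~(df["base_ma"] > df["top_ma"])
    if bad.any():
        raise ValidationError(
            f"base_ma <= top_ma for stage(s): {df.loc[bad, 'name'].tolist()}"
        )
    df = df.sort_values("base_ma", ascending=False).reset_index(drop=True)
    stages = [
        GeologicalStage(str(r["name"]), i, float(r["base_ma"]), float(r["top_ma"]))
        for i, r in df.iterrows()
    ]
    for a, b in zip(stages, stages[1:]):
        if b.base_ma > a.top_ma:
            raise ValidationError(f"stages {a.name!r} and {b.name!r} overlap")
        if b.base_ma < a.top_ma:
            warnings.warn(
                f"gap of {a.top_ma - b.base_ma:g} My between stages "
                f"{a.name!r} and {b.name!r}",
                stacklevel=2,
            )
    return Timescale(stages)


def drop_extant(table: OccurrenceTable, extant_names: set[str]) -> OccurrenceTable:
    """Remove all occurrences of species present in ``extant_names``.

    The analysis concerns extinct species only; living species that also have
    a fossil record are identified against a user-supplied extant-taxon list.
    """
    extant = set(extant_names)
    mask = table.df["species_name"].isin(extant)
    out = table.df[~mask].reset_index(drop=True)
    log = dict(table.filter_log)
    log["extant species removed"] = int(mask.sum())
    if len(out) == 0 and len(table.df) > 0:
        warnings.warn("all occurrences belonged to extant species", stacklevel=2)
    return OccurrenceTable(df=out, provenance=dict(table.provenance), filter_log=log)


def write_table(rows, path) -> None:
    """Write any tabular result as a UTF-8 TSV with header.

    Missing values are written as empty fields so the file round-trips
    through :func:`read_table`.
    """
    if isinstance(rows, OccurrenceTable):
        rows = rows.df
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(rows)
    rows.to_csv(path, sep="\t", index=False, na_rep="", encoding="utf-8")


def read_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
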