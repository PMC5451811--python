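"""Statistical engine for group comparisons.

Durations (and specimen scores, range sizes) are skewed count-like data, so
location is summarised by the 10%-trimmed mean and groups are compared
non-parametrically: a Kruskal-Wallis omnibus followed by pairwise two-sided
Wilcoxon rank-sum tests with Benjamini-Hochberg (fdr) adjustment over all
pairs of one grouping. Habitat-preference and singleton contingency tables
use Pearson's chi-square, Yates-corrected for 2x2 tables (matching the R
default the field's scripts rely on).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "trimmed_mean",
    "kruskal_wallis",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "pairwise_wilcoxon_bh",
    "chi_square_test",
    "ChiSquareResult",
    "GroupComparisonResult",
    "compare_groups",
    "compare_durations",
    "habitat_preference_test",
    "LISSAMPHIBIA_GROUPS",
    "HIGHER_GROUPS",
    "taxon_scheme_members",
    "significance_stars",
]

ALPHA = 0.05

#: Orders of modern amphibians and their stem representatives: comparisons
#: stay within one hierarchical level, so these never meet the higher groups.
LISSAMPHIBIA_GROUPS = ("Allocaudata", "Gymnophiona", "Salientia", "Urodela")
#: The two candidate stem clades and their complements.
HIGHER_GROUPS = ("Temnospondyli", "No-Temnospondyli", "Lepospondyli", "No-Lepospondyli")


def trimmed_mean(values, trim: float = 0.1) -> float:
    """Mean after dropping floor(n*trim) values from each tail.

    The same tail count R's ``mean(x, trim=)`` (and hence psych::describe)
    uses, so trim=0.1 on n=10 drops exactly one value per end.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("trimmed_mean of empty data")
    if not 0 <= trim < 0.5:
        raise ValueError(f"trim must be in [0, 0.5), got {trim}")
    return float(sps.trim_mean(values, trim))


def kruskal_wallis(groups: list) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with df = k-1 and chi-square tail p.

    Degenerate input (all values identical across groups) returns
    (0.0, k-1, 1.0) instead of raising: equal groups carry no evidence.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    df = len(groups) - 1
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 0.0, df, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), df, float(p)


def wilcoxon_rank_sum(
    x, y, method: str = "auto", continuity: bool = True
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test -> (U, p).

    ``auto`` uses the exact null distribution when both samples have n <= 8
    and the pooled data are tie-free, else the normal approximation with tie
    correction and (by default) continuity correction — the convention of
    R's ``wilcox.test``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample in rank-sum test")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    if method == "auto":
        method = "exact" if (x.size <= 8 and y.size <= 8 and not ties) else "asymptotic"
    if method == "exact" and ties:
        raise ValueError("exact method is undefined with ties")
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=continuity
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (fdr) of a p-value family."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def pairwise_wilcoxon_bh(
    groups: dict[str, np.ndarray], method: str = "auto", continuity: bool = True
) -> pd.DataFrame:
    """Symmetric matrix of BH-adjusted pairwise rank-sum p-values.

    The adjustment family is all pairs of this one call, never pooled
    across analyses.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups for pairwise comparisons")
    pairs = list(itertools.combinations(names, 2))
    raw = [
        wilcoxon_rank_sum(groups[a], groups[b], method=method, continuity=continuity)[1]
        for a, b in pairs
    ]
    adj = bh_adjust(raw)
    mat = pd.DataFrame(np.eye(len(names)) * np.nan, index=names, columns=names)
    for (a, b), p in zip(pairs, adj):
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    pvalue: float
    observed: pd.DataFrame
    expected: pd.DataFrame
    residuals: pd.DataFrame  # standardised (O-E)/sqrt(E)
    yates: bool


def chi_square_test(observed, yates: bool | None = None) -> ChiSquareResult:
    """Pearson chi-square test of independence on a contingency table.

    ``yates=None`` applies the continuity correction exactly when the table
    is 2x2; larger tables are never corrected. The statistic is computed
    directly as sum((|O-E| - c)^2 / E) with c = 0.5 (capped at |O-E|) under
    Yates and 0 otherwise.
    """
    obs = pd.DataFrame(observed).astype(float)
    if (obs.values < 0).any():
        raise ValueError("negative counts")
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    row = obs.sum(axis=1).values
    col = obs.sum(axis=0).values
    total = obs.values.sum()
    if total == 0 or (row == 0).any() or (col == 0).any():
        raise ValueError("zero row/column margin in contingency table")
    expected = np.outer(row, col) / total
    use_yates = obs.shape == (2, 2) if yates is None else yates
    diff = np.abs(obs.values - expected)
    if use_yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    resid = (obs.values - expected) / np.sqrt(expected)
    return ChiSquareResult(
        statistic=stat,
        df=df,
        pvalue=p,
        observed=obs,
        expected=pd.DataFrame(expected, index=obs.index, columns=obs.columns),
        residuals=pd.DataFrame(resid, index=obs.index, columns=obs.columns),
        yates=use_yates,
    )


@dataclass
class GroupComparisonResult:
    """One grouping's full comparison: summaries, omnibus, pairwise."""

    grouping: str
    group_n: dict[str, int]
    group_median: dict[str, float]
    group_trimmed_mean: dict[str, float]
    trim: float
    statistic: float  # Kruskal-Wallis H
    df: int
    pvalue: float
    pairwise_adjusted_p: pd.DataFrame
    trimmed_mean_diff: pd.DataFrame  # row minus column
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Long-format report: group summaries then pairwise rows."""
        rows = [
            {
                "grouping": self.grouping,
                "kind": "group",
                "a": g,
                "b": "",
                "n": self.group_n[g],
                "median": self.group_median[g],
                "trimmed_mean": self.group_trimmed_mean[g],
                "statistic": np.nan,
                "p": np.nan,
                "stars": "",
            }
            for g in self.group_n
        ]
        rows.append(
            {
                "grouping": self.grouping,
                "kind": "omnibus",
                "a": "",
                "b": "",
                "n": sum(self.group_n.values()),
                "median": np.nan,
                "trimmed_mean": np.nan,
                "statistic": self.statistic,
                "p": self.pvalue,
                "stars": significance_stars(self.pvalue),
            }
        )
        for a, b in itertools.combinations(self.group_n, 2):
            p = self.pairwise_adjusted_p.loc[a, b]
            rows.append(
                {
                    "grouping": self.grouping,
                    "kind": "pairwise",
                    "a": a,
                    "b": b,
                    "n": self.group_n[a] + self.group_n[b],
                    "median": np.nan,
                    "trimmed_mean": self.trimmed_mean_diff.loc[a, b],
                    "statistic": np.nan,
                    "p": p,
                    "stars": significance_stars(p),
                }
            )
        return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """'***' below 0.001, '**' below 0.01, '*' below 0.05, else ''."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_groups(
    groups: dict[str, np.ndarray], grouping: str = "", trim: float = 0.1
) -> GroupComparisonResult:
    """Full comparison of named numeric groups (omnibus + adjusted pairwise)."""
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    empty = [k for k, v in groups.items() if v.size == 0]
    if empty:
        raise ValueError(f"empty group(s): {empty}")
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to compare")
    h, df, p = kruskal_wallis(list(groups.values()))
    flat = np.concatenate(list(groups.values()))
    degenerate = bool(np.all(flat == flat[0]))
    pmat = pairwise_wilcoxon_bh(groups)
    names = list(groups)
    tmeans = {k: trimmed_mean(v, trim) for k, v in groups.items()}
    dmat = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for a in names:
        for b in names:
            dmat.loc[a, b] = tmeans[a] - tmeans[b]
    return GroupComparisonResult(
        grouping=grouping,
        group_n={k: int(v.size) for k, v in groups.items()},
        group_median={k: float(np.median(v)) for k, v in groups.items()},
        group_trimmed_mean=tmeans,
        trim=trim,
        statistic=h,
        df=df,
        pvalue=p,
        pairwise_adjusted_p=pmat,
        trimmed_mean_diff=dmat,
        degenerate=degenerate,
    )


def taxon_scheme_members(summary, scheme: str) -> list[str]:
    """Groups a species belongs to under a taxon comparison scheme.

    ``lissamphibia`` assigns a species to its own order (if it is one of the
    four lissamphibian groups); ``higher`` assigns every species to two of
    the four groups Temnospondyli/No-Temnospondyli/Lepospondyli/
    No-Lepospondyli, so the two candidate stem clades are each contrasted
    with the rest of the data.
    """
    g = summary.taxon_group
    if scheme == "lissamphibia":
        return [g] if g in LISSAMPHIBIA_GROUPS else []
    if scheme == "higher":
        out = []
        out.append("Temnospondyli" if g == "Temnospondyli" else "No-Temnospondyli")
        out.append("Lepospondyli" if g == "Lepospondyli" else "No-Lepospondyli")
        return out
    raise ValueError(f"unknown taxon scheme {scheme!r}")


def _habitat_members(summary, level: int) -> list[str]:
    if summary.habitat is None:
        return []
    return sorted(getattr(summary.habitat, f"level{level}"))


def compare_durations(
    summaries,
    grouping: str,
    value: str = "duration_ma",
    exclude_singletons: bool = False,
    taxon_restrict: str | None = None,
    range_stratum: str | None = None,
    range_rule: str = "single_cell",
    trim: float = 0.1,
) -> GroupComparisonResult:
    """Compare per-species durations (or range sizes) between groups.

    ``grouping`` is ``level1``/``level2``/``level3`` (habitat levels; a
    species contributes its value once per category it belongs to) or
    ``taxon:lissamphibia``/``taxon:higher``. Filters: drop singletons,
    restrict to one taxon group, or keep one geographic-range stratum.
    """
    from .chronology import stratify_by_range  # local import avoids cycle

    pool = list(summaries)
    applied = []
    if taxon_restrict is not None:
        pool = [s for s in pool if s.taxon_group == taxon_restrict]
        applied.append(f"taxon={taxon_restrict}")
    if exclude_singletons:
        pool = [s for s in pool if not s.is_single_interval]
        applied.append("exclude_singletons")
    if range_stratum is not None:
        pool = stratify_by_range(pool, rule=range_rule)[range_stratum]
        applied.append(f"range_stratum={range_stratum}")

    if grouping.startswith("level"):
        level = int(grouping[-1])
        member = lambda s: _habitat_members(s, level)
    elif grouping.startswith("taxon:"):
        scheme = grouping.split(":", 1)[1]
        member = lambda s: taxon_scheme_members(s, scheme)
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    groups: dict[str, list[float]] = {}
    for s in pool:
        for cat in member(s):
            groups.setdefault(cat, []).append(float(getattr(s, value)))
    groups = {k: v for k, v in sorted(groups.items()) if v}
    if len(groups) < 2:
        filt = ", ".join(applied) if applied else "none"
        raise ValueError(
            f"grouping {grouping!r} leaves {len(groups)} group(s) after "
            f"filters ({filt}); need >= 2"
        )
    return compare_groups(groups, grouping=grouping, trim=trim)


def habitat_preference_test(
    summaries, taxon_scheme: str = "higher", level: int = 1
) -> ChiSquareResult:
    """Chi-square test of habitat-category frequency against taxon identity.

    Counts species once per habitat category (within its taxon groups under
    the scheme); a significant result means taxa are unevenly spread over
    habitats, i.e. habitat usage is not phylogenetically independent.
    Rows or columns with zero total are dropped with a warning.
    """
    counts: dict[str, dict[str, int]] = {}
    for s in summaries:
        for taxon in taxon_scheme_members(s, taxon_scheme):
            for cat in _habitat_members(s, level):
                counts.setdefault(taxon, {}).setdefault(cat, 0)
                counts[taxon][cat] += 1
    table = pd.DataFrame(counts).T.fillna(0).astype(int)
    if table.empty:
        raise ValueError("no species with both taxon and habitat information")
    table = table.sort_index(axis=0).sort_index(axis=1)
    zero_rows = table.index[table.sum(axis=1) == 0].tolist()
    zero_cols = table.columns[table.sum(axis=0) == 0].tolist()
    if zero_rows or zero_cols:
        warnings.warn(
            f"dropping empty rows {zero_rows} / columns {zero_cols}", stacklevel=2
        )
        table = table.drop(index=zero_rows, columns=zero_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 taxa and >= 2 habitat categories")
    return chi_square_test(table)
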