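import itertools
import types

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from fossilhab import (
    bh_adjust,
    chi_square_test,
    compare_durations,
    compare_groups,
    habitat_preference_test,
    kruskal_wallis,
    pairwise_wilcoxon_bh,
    trimmed_mean,
    wilcoxon_rank_sum,
)
from fossilhab.habitat import HabitatAssignment


def make_summary(name, group, dur, habitat1=("stagnant",), cells=1, singleton=None):
    level1 = frozenset(habitat1)
    level2 = frozenset(
        {"lentic" if c == "stagnant" else "lotic" for c in habitat1}
    )
    level3 = frozenset(
        {"low" if c in ("stagnant", "low-velocity") else "high" for c in habitat1}
    )
    return types.SimpleNamespace(
        species_name=name,
        taxon_group=group,
        duration_ma=dur,
        duration_stages=1 if dur == 0 else 2,
        is_single_interval=(dur == 0) if singleton is None else singleton,
        grid_cell_count=cells,
        habitat=HabitatAssignment(name, level1, level2, level3),
    )


class TestTrimmedMean:
    def test_drops_floor_n_trim_per_tail(self):
        assert trimmed_mean(range(1, 11), 0.1) == pytest.approx(5.5)

    def test_small_n_trims_nothing(self):
        assert trimmed_mean([1, 2, 3], 0.1) == pytest.approx(2.0)

    def test_constant_data_invariant(self):
        for trim in (0.0, 0.1, 0.3):
            assert trimmed_mean([4.2] * 7, trim) == pytest.approx(4.2)

    def test_trim_half_rejected(self):
        with pytest.raises(ValueError):
            trimmed_mean([1, 2], 0.5)


class TestKruskalWallis:
    def test_identical_groups_degenerate(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert df == 1 and p > 0.9

    def test_all_constant_returns_h0_p1(self):
        h, df, p = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert (h, p) == (0.0, 1.0)

    def test_matches_rank_formula_without_ties(self):
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, no tie correction needed
        groups = [[1, 2, 3], [10, 11, 12]]
        ranks = {v: r for r, v in enumerate(sorted(sum(groups, [])), start=1)}
        n = 6
        h_hand = 12 / (n * (n + 1)) * sum(
            len(g) * (np.mean([ranks[v] for v in g]) - (n + 1) / 2) ** 2 for g in groups
        )
        h, df, p = kruskal_wallis(groups)
        assert h == pytest.approx(h_hand, abs=1e-12)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


def exact_rank_sum_p(x, y):
    """Brute-force two-sided rank-sum p by enumerating all rank splits."""
    n1, n = len(x), len(x) + len(y)
    allr = sps.rankdata(np.concatenate([x, y]))
    u_obs = allr[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * (n - n1) / 2
    us = [
        sum(i + 1 for i in idx) - n1 * (n1 + 1) / 2
        for idx in itertools.combinations(range(n), n1)
    ]
    us = np.array(us, dtype=float)
    return float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-9))


class TestWilcoxon:
    def test_fully_separated_small_samples_exact(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 4], [5, 6, 7, 8])
        assert p == pytest.approx(2 / 70)

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.permutation(np.arange(14.0))[:6]
            y = np.setdiff1d(np.arange(14.0), x)[:7]
            _, p = wilcoxon_rank_sum(x, y, method="exact")
            assert p == pytest.approx(exact_rank_sum_p(list(x), list(y)))

    def test_normal_approximation_close_to_exact_at_n8(self):
        """Exhaustive over all achievable U at n1=n2=8, tie-free."""
        vals = np.arange(1.0, 17.0)
        seen = set()
        maxd = 0.0
        for idx in itertools.combinations(range(16), 8):
            x = vals[list(idx)]
            y = np.delete(vals, list(idx))
            u, pe = wilcoxon_rank_sum(x, y, method="exact")
            if u in seen:
                continue
            seen.add(u)
            _, pa = wilcoxon_rank_sum(x, y, method="asymptotic")
            maxd = max(maxd, abs(pa - pe))
        assert maxd < 0.02

    def test_tied_data_uses_corrected_normal_approximation(self):
        x, y = [1, 1, 2, 2], [2, 3, 3, 4]
        _, p = wilcoxon_rank_sum(x, y)  # ties -> asymptotic path
        r = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(r.pvalue)

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_sum([2, 2, 2], [2, 2, 2])
        assert p == 1.0


class TestBH:
    def test_textbook_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=15)
        # direct: sort, p*m/rank, cumulative min from the largest rank
        order = np.argsort(p)
        m = len(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        stepped = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=12))
    def test_monotone_and_dominating(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_permutation_equivariance(self):
        p = [0.04, 0.2, 0.008, 0.6]
        perm = [2, 0, 3, 1]
        np.testing.assert_allclose(bh_adjust([p[i] for i in perm]),
                                   bh_adjust(p)[perm])


class TestChiSquare:
    def test_balanced_table_zero(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)

    def test_hand_computed_without_yates(self):
        res = chi_square_test([[20, 10], [10, 20]], yates=False)
        assert res.statistic == pytest.approx(20 / 3)
        assert res.df == 1

    def test_default_2x2_applies_yates(self):
        res = chi_square_test([[20, 10], [10, 20]])
        assert res.yates
        # |O-E|=5 -> (4.5)^2/15 * 4
        assert res.statistic == pytest.approx(4 * 4.5**2 / 15)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            r, c = rng.integers(2, 5, size=2)
            table = rng.integers(1, 40, size=(r, c))
            mine = chi_square_test(table, yates=False)
            stat, p, df, _ = sps.chi2_contingency(table, correction=False)
            assert mine.statistic == pytest.approx(stat, abs=1e-9)
            assert mine.pvalue == pytest.approx(p, abs=1e-9)
            assert mine.df == df
        # Yates on 2x2 where every |O-E| >= 0.5 agrees with scipy too
        for _ in range(30):
            table = rng.integers(1, 40, size=(2, 2))
            mine = chi_square_test(table, yates=True)
            if np.abs(mine.observed.values - mine.expected.values).min() < 0.5:
                continue
            stat, p, df, _ = sps.chi2_contingency(table, correction=True)
            assert mine.statistic == pytest.approx(stat, abs=1e-9)

    def test_margins_preserved_and_residuals(self):
        res = chi_square_test([[30, 10], [20, 40]], yates=False)
        np.testing.assert_allclose(res.expected.sum(axis=1), res.observed.sum(axis=1))
        np.testing.assert_allclose(
            res.residuals.values,
            (res.observed.values - res.expected.values) / np.sqrt(res.expected.values),
        )

    def test_empty_margin_is_error(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [5, 3]])


class TestCompareDurations:
    def test_species_counted_once_per_category(self):
        s = [
            make_summary("a", "Urodela", 5, ("stagnant", "medium-velocity")),
            make_summary("b", "Urodela", 3, ("stagnant",)),
            make_summary("c", "Urodela", 8, ("medium-velocity",)),
        ]
        res = compare_durations(s, "level1")
        assert res.group_n == {"medium-velocity": 2, "stagnant": 2}

    def test_identical_durations_all_p_one(self):
        s = [make_summary(f"a{i}", "Urodela", 4, ("stagnant",)) for i in range(5)]
        s += [make_summary(f"b{i}", "Urodela", 4, ("medium-velocity",)) for i in range(5)]
        res = compare_durations(s, "level2")
        assert res.degenerate
        assert res.pairwise_adjusted_p.loc["lentic", "lotic"] == 1.0

    def test_taxon_schemes_stay_within_level(self):
        s = [make_summary(f"u{i}", "Urodela", i, ("stagnant",)) for i in range(6)]
        s += [make_summary(f"s{i}", "Salientia", i + 1, ("stagnant",)) for i in range(6)]
        s += [make_summary(f"t{i}", "Temnospondyli", i + 2, ("stagnant",)) for i in range(6)]
        liss = compare_durations(s, "taxon:lissamphibia")
        assert set(liss.group_n) == {"Urodela", "Salientia"}
        higher = compare_durations(s, "taxon:higher")
        assert set(higher.group_n) == {
            "Temnospondyli", "No-Temnospondyli", "Lepospondyli", "No-Lepospondyli"
        } - {"Lepospondyli"}
        # every species lands in No-Lepospondyli when no lepospondyls exist
        assert higher.group_n["No-Lepospondyli"] == 18

    def test_filters_named_in_error(self):
        s = [make_summary("a", "Urodela", 5, ("stagnant",))]
        with pytest.raises(ValueError, match="exclude_singletons"):
            compare_durations(s, "level1", exclude_singletons=True)

    def test_singleton_exclusion_filters(self):
        s = [make_summary(f"a{i}", "Urodela", 0, ("stagnant",)) for i in range(3)]
        s += [make_summary(f"b{i}", "Urodela", 5, ("stagnant",)) for i in range(3)]
        s += [make_summary(f"c{i}", "Urodela", 7, ("medium-velocity",)) for i in range(3)]
        res = compare_durations(s, "level1", exclude_singletons=True)
        assert res.group_n == {"medium-velocity": 3, "stagnant": 3}


class TestHabitatPreference:
    def test_uniform_table_near_zero(self):
        s = []
        for gi, group in enumerate(["Allocaudata", "Urodela", "Salientia", "Gymnophiona"]):
            for hi, hab in enumerate(
                ["stagnant", "low-velocity", "medium-velocity", "high-velocity"]
            ):
                for k in range(3):
                    s.append(make_summary(f"{group}-{hab}-{k}", group, 1, (hab,)))
        res = habitat_preference_test(s, "lissamphibia")
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.df == 9

    def test_four_by_four_df_is_nine(self):
        rng = np.random.default_rng(2)
        habs = ["stagnant", "low-velocity", "medium-velocity", "high-velocity"]
        s = [
            make_summary(f"sp{i}", "Temnospondyli" if i % 3 == 0 else
                         ("Lepospondyli" if i % 3 == 1 else "Urodela"),
                         1, (habs[rng.integers(4)],))
            for i in range(120)
        ]
        res = habitat_preference_test(s, "higher")
        assert res.df == 9

    def test_single_taxon_after_scheme_is_error(self):
        s = [make_summary(f"u{i}", "Urodela", 1, ("stagnant",)) for i in range(5)]
        s += [make_summary(f"u{i}x", "Urodela", 1, ("medium-velocity",)) for i in range(5)]
        with pytest.raises(ValueError):
            habitat_preference_test(s, "lissamphibia")

    def test_two_by_two_table_uses_yates(self):
        s = [make_summary(f"u{i}", "Urodela", 1, ("stagnant",)) for i in range(20)]
        s += [make_summary(f"u{i}x", "Urodela", 1, ("medium-velocity",)) for i in range(10)]
        s += [make_summary(f"s{i}", "Salientia", 1, ("stagnant",)) for i in range(10)]
        s += [make_summary(f"s{i}x", "Salientia", 1, ("medium-velocity",)) for i in range(20)]
        res = habitat_preference_test(s, "lissamphibia")
        assert res.observed.shape == (2, 2)
        assert res.yates
        assert res.statistic == pytest.approx(4 * 4.5**2 / 15)


def test_pairwise_matrix_symmetric_with_adjusted_ge_raw():
    rng = np.random.default_rng(9)
    groups = {k: rng.normal(loc, 1, 30) for k, loc in [("a", 0), ("b", 0.5), ("c", 1)]}
    mat = pairwise_wilcoxon_bh(groups)
    for a, b in itertools.combinations(groups, 2):
        assert mat.loc[a, b] == mat.loc[b, a]
        raw = wilcoxon_rank_sum(groups[a], groups[b])[1]
        assert mat.loc[a, b] >= raw - 1e-12
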