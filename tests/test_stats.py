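"""Kruskal-Wallis, Dunn post hoc with compact letters, and census
chi-square — checked against brute-force rank oracles and closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import recruitflow as rf
from recruitflow import CensusMarginals, GroupedValues, InputError


# ---------------------------------------------------------------- oracles

def midranks(values):
    """Brute-force midranks: count-based, independent of scipy."""
    out = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def kruskal_oracle(*samples):
    """H by direct rank computation with tie correction."""
    pooled = [v for s in samples for v in s]
    ranks = midranks(pooled)
    n = len(pooled)
    idx = 0
    h = 0.0
    for s in samples:
        r = ranks[idx: idx + len(s)]
        idx += len(s)
        h += sum(r) ** 2 / len(s)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    correction = 1 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction


def dunn_two_group_oracle(x, y):
    """Two-sample Dunn z and two-sided p from explicit midranks."""
    pooled = list(x) + list(y)
    ranks = midranks(pooled)
    n = len(pooled)
    r1 = sum(ranks[: len(x)]) / len(x)
    r2 = sum(ranks[len(x):]) / len(y)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    tie_sum = sum(t**3 - t for t in ties.values())
    var = (n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))) * (
        1.0 / len(x) + 1.0 / len(y)
    )
    z = (r1 - r2) / math.sqrt(var)
    p = math.erfc(abs(z) / math.sqrt(2.0))
    return z, p


# ---------------------------------------------------------- Kruskal-Wallis

class TestKruskalWallis:
    def test_identical_groups_have_no_signal(self):
        gv = GroupedValues(values=[1, 2, 3, 1, 2, 3], groups=list("aaabbb"))
        res = rf.kruskal_wallis(gv)
        assert res.H == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        gv = GroupedValues(values=[1, 2, 3, 4], groups=list("aabb"))
        res = rf.kruskal_wallis(gv)
        assert res.H == pytest.approx(kruskal_oracle([1, 2], [3, 4]))
        assert res.H == pytest.approx(2.4)
        assert res.df == 1

    def test_matches_oracle_with_ties(self):
        x, y, z = [1, 2, 2, 5], [2, 3, 3], [1, 1, 4, 4, 6]
        gv = GroupedValues(
            values=x + y + z, groups=["a"] * 4 + ["b"] * 3 + ["c"] * 5
        )
        assert rf.kruskal_wallis(gv).H == pytest.approx(
            kruskal_oracle(x, y, z), rel=1e-12
        )

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(-50, 50), min_size=4, max_size=20),
        st.lists(st.integers(-50, 50), min_size=4, max_size=20),
    )
    def test_invariant_under_monotone_transforms(self, x, y):
        gv = GroupedValues(values=x + y, groups=["a"] * len(x) + ["b"] * len(y))
        # x -> x^3 is strictly monotone and exact on small integers, so the
        # midrank (and tie) structure is preserved exactly
        transformed = GroupedValues(
            values=[float(v) ** 3 for v in x + y], groups=gv.groups
        )
        assert rf.kruskal_wallis(transformed).H == pytest.approx(
            rf.kruskal_wallis(gv).H, abs=1e-9
        )

    def test_single_group_is_invalid(self):
        with pytest.raises(InputError):
            GroupedValues(values=[1, 2, 3], groups=["a", "a", "a"])


# --------------------------------------------------------------- Dunn test

class TestDunn:
    def test_identical_groups_share_one_letter(self):
        gv = GroupedValues(values=[1, 2, 3] * 3,
                           groups=["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        res = rf.dunn_posthoc(gv)
        assert set(res.letters.values()) == {"a"}

    def test_well_separated_groups_get_distinct_letters(self, rng):
        vals = np.concatenate(
            [rng.normal(m, 0.1, 30) for m in (0.0, 10.0, 20.0)]
        )
        groups = ["low"] * 30 + ["mid"] * 30 + ["high"] * 30
        res = rf.dunn_posthoc(GroupedValues(values=vals, groups=groups))
        letters = [res.letters[g] for g in ("low", "mid", "high")]
        assert len(set(letters)) == 3
        assert all(len(l) == 1 for l in letters)

    def test_two_group_case_equals_rank_oracle(self, rng):
        x = list(rng.normal(0, 1, 12))
        y = list(rng.normal(0.8, 1, 15))
        res = rf.dunn_posthoc(
            GroupedValues(values=x + y, groups=["a"] * 12 + ["b"] * 15),
            adjust="none",
        )
        z_oracle, p_oracle = dunn_two_group_oracle(x, y)
        row = res.pairwise.iloc[0]
        assert abs(row["z"]) == pytest.approx(abs(z_oracle), abs=1e-10)
        assert row["p_unadjusted"] == pytest.approx(p_oracle, abs=1e-10)

    def test_two_group_oracle_with_ties(self):
        x, y = [1, 2, 2, 3], [2, 3, 3, 4, 4]
        res = rf.dunn_posthoc(
            GroupedValues(values=x + y, groups=["a"] * 4 + ["b"] * 5),
            adjust="none",
        )
        _, p_oracle = dunn_two_group_oracle(x, y)
        assert res.pairwise.iloc[0]["p_unadjusted"] == pytest.approx(
            p_oracle, abs=1e-10
        )

    @pytest.mark.parametrize("adjust", ["holm", "bonferroni", "none"])
    def test_letters_are_a_clique_cover_of_nonsignificance(self, rng, adjust):
        """Groups share a letter iff their difference is not significant."""
        vals = np.concatenate(
            [rng.normal(m, 1.5, 25) for m in (0.0, 0.5, 1.2, 4.0)]
        )
        groups = np.repeat(list("wxyz"), 25)
        res = rf.dunn_posthoc(GroupedValues(values=vals, groups=groups),
                              adjust=adjust)
        for row in res.pairwise.itertuples():
            shared = set(res.letters[row.group1]) & set(res.letters[row.group2])
            assert bool(shared) == (not row.significant), (
                f"{row.group1} vs {row.group2}: letters "
                f"{res.letters[row.group1]}/{res.letters[row.group2]}, "
                f"p_adj={row.p_adjusted:.4f}"
            )

    def test_holm_is_at_least_as_conservative_as_raw(self, rng):
        vals = rng.normal(0, 1, 40)
        groups = np.repeat(list("abcd"), 10)
        res = rf.dunn_posthoc(GroupedValues(values=vals, groups=groups))
        assert (res.pairwise["p_adjusted"] >= res.pairwise["p_unadjusted"]
                - 1e-15).all()


# --------------------------------------------------------- census chi-square

def census(gender_shares=None):
    gender_shares = gender_shares or {"male": 0.5, "female": 0.5}
    age = {"20-39": 0.5, "40+": 0.5}
    cells = {(g, a): pg * pa for g, pg in gender_shares.items()
             for a, pa in age.items()}
    return CensusMarginals(city="c", cells=cells)


class TestCensusComparison:
    def test_proportional_sample_has_zero_statistic(self):
        res = rf.census_comparison({"male": 50, "female": 50}, census(), "gender")
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.effect_size == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_closed_form(self):
        # (60, 40) vs (0.5, 0.5), n = 100: chi2 = (10^2/50)*2 = 4, w = 0.2
        res = rf.census_comparison({"male": 60, "female": 40}, census(), "gender")
        assert res.chi2 == pytest.approx(4.0)
        assert res.effect_size == pytest.approx(0.2)
        assert res.df == 1

    def test_two_classes_equal_squared_proportion_z_test(self):
        # chi2 gof with k = 2 is the square of the one-sample z statistic
        obs, n, p0 = 37, 120, 0.4
        res = rf.census_comparison(
            {"male": obs, "female": n - obs},
            census({"male": p0, "female": 1 - p0}),
            "gender",
        )
        z = (obs / n - p0) / math.sqrt(p0 * (1 - p0) / n)
        assert res.chi2 == pytest.approx(z**2, abs=1e-10)

    def test_missing_census_class_is_an_error(self):
        with pytest.raises(InputError):
            rf.census_comparison({"male": 10, "other": 5}, census(), "gender")

    def test_empty_sample_is_an_error(self):
        with pytest.raises(InputError):
            rf.census_comparison({"male": 0, "female": 0}, census(), "gender")
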