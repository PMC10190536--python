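"""OEL, regression, DES calling, patterns, rank DE and Meet/Min."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from editscape import (
    Condition,
    EditingProfile,
    call_des,
    compare_oel_groups,
    compute_oel,
    find_informative_sites,
    log2_fold_change,
    meet_min,
    meet_min_matrix,
    rank_de,
    regress_oel_on_expression,
    summarize_patterns,
    wilcoxon_rank_sum,
)
from editscape.editing_core import OELResult

from conftest import wilcoxon_enumeration_oracle


def _condition(res, sen):
    return Condition("C", "D", frozenset(res), frozenset(sen))


class TestOEL:
    def test_single_site_oel_is_identity(self):
        levels = pd.DataFrame({"s1": [0.2], "s2": [0.4]}, index=["site1"])
        oel = compute_oel(EditingProfile(levels))
        assert oel.overall["s1"] == 0.2 and oel.overall["s2"] == 0.4

    def test_missing_values_excluded_from_mean(self, tiny_profile):
        # s1 sees (0.2, 0.4) -> 0.3; s2 sees only 0.6
        oel = compute_oel(tiny_profile)
        assert oel.overall["s1"] == pytest.approx(0.3)
        assert oel.overall["s2"] == pytest.approx(0.6)

    def test_all_zero_matrix_gives_zero_oels(self):
        levels = pd.DataFrame(np.zeros((5, 3)), columns=["a", "b", "c"])
        oel = compute_oel(EditingProfile(levels))
        assert (oel.overall == 0).all()

    def test_sample_with_no_observations_omitted_not_zero(self):
        levels = pd.DataFrame({"s1": [0.5], "s2": [np.nan]}, index=["x"])
        oel = compute_oel(EditingProfile(levels))
        assert "s2" not in oel.overall.index

    def test_per_region_means(self):
        levels = pd.DataFrame({"s1": [0.2, 0.8]}, index=["a", "b"])
        ann = pd.DataFrame(
            {"region": ["exonic", "intronic"], "gene_id": ["g", "g"],
             "chrom": ["c", "c"], "pos": [1, 2], "strand": ["+", "+"]},
            index=["a", "b"],
        )
        oel = compute_oel(EditingProfile(levels), ann)
        assert oel.by_region.loc["exonic", "s1"] == 0.2
        assert oel.by_region.loc["intronic", "s1"] == 0.8


class TestRegression:
    def test_perfect_fit_r2_one(self):
        x = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
        fit = regress_oel_on_expression(x, x)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_regressor_rejected(self):
        oel = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        expr = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            regress_oel_on_expression(oel, expr)

    def test_independent_expression_gives_tiny_r2(self):
        # null: expression unrelated to OEL; at n=500, R^2 < 0.02 almost surely
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(20):
            idx = [f"s{i}" for i in range(500)]
            oel = pd.Series(rng.uniform(0.1, 0.4, 500), index=idx)
            expr = pd.Series(rng.uniform(0, 100, 500), index=idx)
            if regress_oel_on_expression(oel, expr).r2 < 0.02:
                hits += 1
        assert hits >= 19


class TestGroupComparison:
    def test_extreme_separation_exact_p(self):
        # all C(6,3) = 20 rank splits: the observed one and its mirror are
        # the two most extreme, so the exact two-sided p is 2/20 = 0.1
        oel = OELResult(pd.Series(
            {"r1": 0.1, "r2": 0.2, "r3": 0.3, "s1": 0.7, "s2": 0.8, "s3": 0.9}
        ))
        cond = _condition(["r1", "r2", "r3"], ["s1", "s2", "s3"])
        assert compare_oel_groups(oel, cond, mode="exact") == pytest.approx(0.1)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.random(10), index=[f"x{i}" for i in range(10)])
        cond = _condition([f"x{i}" for i in range(5)], [f"x{i}" for i in range(5, 10)])
        p1 = compare_oel_groups(OELResult(vals), cond)
        p2 = compare_oel_groups(OELResult(vals.sample(frac=1, random_state=1)), cond)
        assert p1 == p2

    def test_wilcoxon_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n1, n2 = rng.integers(3, 8, size=2)
            x, y = rng.random(n1), rng.random(n2)
            assert wilcoxon_rank_sum(x, y, mode="exact") == pytest.approx(
                wilcoxon_enumeration_oracle(x, y), abs=1e-12
            )


class TestDESCalling:
    def _profile(self, res_vals, sen_vals, n_sites=1):
        res_cols = {f"r{i}": v for i, v in enumerate(res_vals)}
        sen_cols = {f"s{i}": v for i, v in enumerate(sen_vals)}
        levels = pd.DataFrame({**res_cols, **sen_cols}, index=[f"site{i}" for i in range(n_sites)])
        cond = _condition(res_cols, sen_cols)
        return EditingProfile(levels), cond

    def test_informative_filter_requires_three_per_group(self):
        levels = pd.DataFrame(
            {
                "r0": [0.1], "r1": [0.2], "r2": [0.3],
                "s0": [0.4], "s1": [0.5], "s2": [np.nan],
            },
            index=["siteA"],
        )
        cond = _condition(["r0", "r1", "r2"], ["s0", "s1", "s2"])
        prof = EditingProfile(levels)
        assert find_informative_sites(prof, cond) == []
        assert find_informative_sites(prof, cond, min_per_group=1) == ["siteA"]

    def test_significant_p_but_small_diff_is_not_a_des(self):
        # clear separation (p < 0.05 at 5v5 exact: p = 2/252) but |Diff| < 0.05
        prof, cond = self._profile(
            [0.100, 0.101, 0.102, 0.103, 0.104],
            [0.110, 0.111, 0.112, 0.113, 0.114],
        )
        des, full = call_des(prof, cond)
        assert full.loc["site0", "p"] < 0.05
        assert abs(full.loc["site0", "diff"]) < 0.05
        assert len(des) == 0

    def test_direction_follows_diff_sign(self):
        prof, cond = self._profile(
            [0.5, 0.52, 0.54, 0.56, 0.58], [0.1, 0.12, 0.14, 0.16, 0.18]
        )
        des, _ = call_des(prof, cond)
        assert des.loc["site0", "direction"] == "over"
        assert des.loc["site0", "diff"] == pytest.approx(0.4)

    def test_three_vs_three_exact_mode_cannot_reach_significance(self):
        # smallest achievable two-sided exact p with 3+3 untied values is
        # 2/C(6,3) = 0.1, so no site can pass p < 0.05
        rng = np.random.default_rng(1)
        levels = pd.DataFrame(
            rng.random((50, 6)),
            columns=["r0", "r1", "r2", "s0", "s1", "s2"],
            index=[f"site{i}" for i in range(50)],
        )
        cond = _condition(["r0", "r1", "r2"], ["s0", "s1", "s2"])
        des, full = call_des(EditingProfile(levels), cond, mode="exact")
        assert len(des) == 0
        assert full["p"].min() >= 0.1 - 1e-12

    def test_monotone_in_alpha_and_min_diff(self, small_sim, small_condition):
        _, profile, _, _ = small_sim
        des_strict, _ = call_des(profile, small_condition, alpha=0.01, min_diff=0.10)
        des_loose, _ = call_des(profile, small_condition, alpha=0.05, min_diff=0.05)
        assert set(des_strict.index) <= set(des_loose.index)

    def test_planted_direction_recovered(self, small_sim, small_condition):
        _, profile, _, truth = small_sim
        des, _ = call_des(profile, small_condition)
        planted = truth.sites[truth.sites["is_des"]]
        hits = des.index.intersection(planted.index)
        assert len(hits) > 0
        for site in hits:
            expected = "over" if planted.loc[site, "planted_diff"] > 0 else "under"
            assert des.loc[site, "direction"] == expected


class TestPatterns:
    def test_proportions_and_conservation(self):
        des_a = pd.DataFrame({"direction": ["over"] * 3})
        des_b = pd.DataFrame({"direction": ["over"] * 42 + ["under"] * 1200})
        summary = summarize_patterns(
            {"A": des_a, "B": des_b}, {"A": 0.5, "B": -0.5}
        )
        tab = summary.table
        assert tab.loc["A", "prop_over"] == 1.0
        assert tab.loc["B", "prop_over"] == pytest.approx(42 / 1242, abs=1e-4)
        assert (tab["n_over"] + tab["n_under"]).tolist() == [3, 1242]

    def test_zero_des_condition_excluded_from_regression(self):
        des = pd.DataFrame({"direction": ["over", "under"]})
        empty = pd.DataFrame({"direction": pd.Series(dtype=str)})
        summary = summarize_patterns(
            {"A": des, "B": empty, "C": des, "D": des},
            {"A": 1.0, "B": 2.0, "C": -1.0, "D": 0.5},
        )
        assert np.isnan(summary.table.loc["B", "prop_over"])
        assert summary.regression is None or summary.regression.n == 3

    def test_equal_group_means_give_zero_log2fc(self):
        vals = pd.Series({"r0": 2.0, "r1": 4.0, "s0": 3.0, "s1": 3.0})
        cond = _condition(["r0", "r1"], ["s0", "s1"])
        assert log2_fold_change(vals, cond) == 0.0

    def test_zero_denominator_requires_explicit_pseudocount(self):
        vals = pd.Series({"r0": 2.0, "r1": 4.0, "s0": 0.0, "s1": 0.0})
        cond = _condition(["r0", "r1"], ["s0", "s1"])
        with pytest.raises(ValueError, match="pseudocount"):
            log2_fold_change(vals, cond)
        assert log2_fold_change(vals, cond, pseudocount=1.0) == pytest.approx(2.0)


class TestRankDE:
    def _cond(self):
        return _condition(["r0", "r1", "r2"], ["s0", "s1", "s2"])

    def test_identical_groups_give_p_one_and_zero_fc(self):
        expr = pd.DataFrame(
            {"r0": [5.0], "r1": [5.0], "r2": [5.0], "s0": [5.0], "s1": [5.0], "s2": [5.0]},
            index=["g1"],
        )
        out = rank_de(expr, self._cond())
        assert out.loc["g1", "p"] == 1.0
        assert out.loc["g1", "log2fc"] == 0.0

    def test_eightfold_change_recovered(self):
        rng = np.random.default_rng(0)
        jitter = rng.normal(0, 1e-3, 6)
        vals = np.array([8.0, 8.0, 8.0, 1.0, 1.0, 1.0]) + jitter
        expr = pd.DataFrame([vals], columns=["r0", "r1", "r2", "s0", "s1", "s2"], index=["g1"])
        out = rank_de(expr, self._cond())
        assert out.loc["g1", "log2fc"] == pytest.approx(3.0, abs=0.01)

    def test_within_group_permutation_invariance(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(
            rng.random((4, 6)) * 10,
            columns=["r0", "r1", "r2", "s0", "s1", "s2"],
            index=[f"g{i}" for i in range(4)],
        )
        shuffled = expr[["r2", "r0", "r1", "s1", "s2", "s0"]]
        pd.testing.assert_frame_equal(
            rank_de(expr, self._cond()), rank_de(shuffled, self._cond())
        )


class TestMeetMin:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"a", "b", "c"}, {"b", "c"}, 1.0),
            ({"a", "b"}, {"c", "d"}, 0.0),
            ({"a", "b", "c", "d"}, {"c", "d", "e"}, 2 / 3),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert meet_min(a, b) == pytest.approx(expected)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            meet_min(set(), {"a"})

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.sets(st.integers(0, 30), min_size=1, max_size=12),
        b=st.sets(st.integers(0, 30), min_size=1, max_size=12),
        offset=st.integers(100, 200),
    )
    def test_symmetry_identity_and_relabeling(self, a, b, offset):
        assert meet_min(a, b) == meet_min(b, a)
        assert meet_min(a, a) == 1.0
        relabel = lambda s: {x + offset for x in s}
        assert meet_min(relabel(a), relabel(b)) == meet_min(a, b)

    def test_matrix_builder_diagonal_and_symmetry(self):
        mat = meet_min_matrix({"A": {1, 2}, "B": {2, 3}, "C": {4}})
        assert (np.diag(mat.values) == 1.0).all()
        assert mat.loc["A", "B"] == mat.loc["B", "A"] == 0.5
        assert mat.loc["A", "C"] == 0.0
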