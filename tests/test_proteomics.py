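"""Fold changes, t-tests, the DEP filter rule and cross-contrast set logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from melanet import proteomics
from melanet.proteomics import AbundanceTable
from melanet.synthetic_data import ProteomicsSimSpec, simulate_proteomics


def _table(rows: dict, reps: int = 2) -> AbundanceTable:
    """rows: protein -> {condition: mean}; replicates identical (noiseless)."""
    data = {}
    conditions = sorted({c for v in rows.values() for c in v})
    for cond in conditions:
        for r in range(1, reps + 1):
            data[f"{cond}_rep{r}"] = [rows[p][cond] for p in rows]
    return AbundanceTable.from_wide(pd.DataFrame(data, index=list(rows)))


class TestFoldChange:
    def test_ratio_of_means(self):
        table = _table({"P1": {"0h": 1.0, "24h": 2.86}})
        fc = proteomics.fold_change(table, ("24h", "0h"))
        assert fc.loc["P1"] == pytest.approx(2.86)

    def test_identity_contrast(self):
        table = _table({"P1": {"0h": 5.0, "24h": 5.0}})
        assert proteomics.fold_change(table, ("24h", "0h")).loc["P1"] == 1.0

    def test_chained_consistency_on_noiseless_means(self):
        table = _table({"P1": {"0h": 2.0, "24h": 5.0, "48h": 8.0}})
        fc_24_0 = proteomics.fold_change(table, ("24h", "0h")).loc["P1"]
        fc_48_24 = proteomics.fold_change(table, ("48h", "24h")).loc["P1"]
        fc_48_0 = proteomics.fold_change(table, ("48h", "0h")).loc["P1"]
        assert fc_48_0 == pytest.approx(fc_48_24 * fc_24_0)

    def test_zero_denominator_flagged_nan(self):
        table = _table({"P1": {"0h": 0.0, "24h": 3.0}})
        assert np.isnan(proteomics.fold_change(table, ("24h", "0h")).loc["P1"])


class TestTTest:
    def test_identical_groups_p_one(self):
        assert proteomics.t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_textbook_pair_matches_closed_form(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        # pooled-variance t with 4 df, closed form via the t CDF
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        expected = 2 * stats.t.sf(abs(t), df=4)
        assert proteomics.t_test(a, b) == pytest.approx(expected, abs=1e-6)

    def test_symmetric_in_group_order(self):
        a, b = [1.0, 2.0, 5.0], [2.0, 2.5, 3.0]
        assert proteomics.t_test(a, b) == proteomics.t_test(b, a)

    def test_degenerate_zero_variance(self):
        assert proteomics.t_test([2.0, 2.0], [2.0, 2.0]) == 1.0
        assert proteomics.t_test([2.0, 2.0], [3.0, 3.0]) == 0.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            proteomics.t_test([1.0], [2.0, 3.0])


EPS = 1e-9


class TestDepFilter:
    @pytest.mark.parametrize(
        "fc, p, expected",
        [
            (2.86, 0.01, "up"),
            (1.0, 0.001, "none"),
            (0.5, 0.2, "none"),
            (0.5, 0.01, "down"),
        ],
    )
    def test_reference_calls(self, fc, p, expected):
        assert proteomics.dep_filter(fc, p) == expected

    @pytest.mark.parametrize("fc", [2 / 3 - EPS, 2 / 3, 1.0, 1.5, 1.5 + EPS])
    @pytest.mark.parametrize("p", [0.049, 0.05])
    def test_boundary_grid_matches_printed_rule(self, fc, p):
        expected = "none"
        if p < 0.05 and fc >= 1.5:
            expected = "up"
        elif p < 0.05 and fc <= 2 / 3:
            expected = "down"
        assert proteomics.dep_filter(fc, p) == expected

    @given(st.floats(0.01, 10.0), st.floats(0.0, 1.0))
    def test_pure_function_consistent_with_rule(self, fc, p):
        call = proteomics.dep_filter(fc, p)
        assert call == ("up" if (p < 0.05 and fc >= 1.5)
                        else "down" if (p < 0.05 and fc <= 2 / 3) else "none")


class TestContrastSetOps:
    def test_union_and_intersection(self):
        union, inter, overlaps = proteomics.contrast_set_ops(
            {"c1": {"A", "B"}, "c2": {"B", "C"}, "c3": {"B"}}
        )
        assert union == {"A", "B", "C"}
        assert inter == {"B"}
        assert overlaps[("c1", "c2")] == 1

    def test_set_size_bounds(self):
        sets = {"c1": {"A", "B", "C"}, "c2": {"B", "C"}, "c3": {"C", "D"}}
        union, inter, _ = proteomics.contrast_set_ops(sets)
        sizes = sorted(len(s) for s in sets.values())
        assert len(inter) <= sizes[0] and sizes[-1] <= len(union)

    def test_single_contrast_rejected(self):
        with pytest.raises(ValueError):
            proteomics.contrast_set_ops({"c1": {"A"}})


class TestPlantedTruth:
    def test_noiseless_calls_equal_planted_truth(self):
        sim = simulate_proteomics(
            ProteomicsSimSpec(n_proteins=60, n_dep_up=8, n_dep_down=8,
                              noise_cv=0.0, seed=2)
        )
        frame = proteomics.dep_table(sim.table, [("24h", "0h"), ("48h", "0h")])
        for contrast, calls in frame.groupby("contrast"):
            observed = calls.set_index("protein")["call"]
            assert (observed.loc[sim.truth.index] == sim.truth).all()

    def test_union_intersection_equal_ground_truth(self):
        sim = simulate_proteomics(
            ProteomicsSimSpec(n_proteins=60, n_dep_up=8, n_dep_down=8,
                              noise_cv=0.0, seed=3)
        )
        frame = proteomics.dep_table(
            sim.table, [("24h", "0h"), ("48h", "0h"), ("48h", "24h")]
        )
        truth_set = set(sim.truth.index[sim.truth != "none"])
        dep_sets = proteomics.deps_per_contrast(frame)
        union, inter, _ = proteomics.contrast_set_ops(dep_sets)
        # the geometric time course makes every pairwise contrast planted
        assert dep_sets["24h_vs_0h"] == truth_set
        assert dep_sets["48h_vs_0h"] == truth_set
        assert dep_sets["48h_vs_24h"] == truth_set
        assert union == truth_set and inter == truth_set


class TestIntersectWithTargets:
    def test_overlap_carries_calls_and_layer(self):
        frame = pd.DataFrame(
            [
                {"protein": "A", "contrast": "24h_vs_0h", "fold_change": 2.0,
                 "p": 0.01, "call": "up"},
                {"protein": "B", "contrast": "24h_vs_0h", "fold_change": 0.5,
                 "p": 0.01, "call": "down"},
            ]
        )
        result = proteomics.intersect_with_targets(
            frame, {"A", "B"}, {"A": 1, "C": 2}
        )
        assert list(result["protein"]) == ["A"]
        assert result.loc[0, "ap_layer"] == 1
        assert result.loc[0, "call_24h_vs_0h"] == "up"
        assert result.loc[0, "fc_24h_vs_0h"] == 2.0

    def test_empty_ap_set_gives_empty_overlap(self):
        frame = pd.DataFrame(
            [{"protein": "A", "contrast": "c", "fold_change": 2.0,
              "p": 0.01, "call": "up"}]
        )
        assert proteomics.intersect_with_targets(frame, {"A"}, {}).empty


class TestAssayFormulas:
    @pytest.mark.parametrize("gsh, gssg, expected", [(1, 2, 5), (0, 0, 0), (7, 0, 7)])
    def test_total_gsh(self, gsh, gssg, expected):
        assert proteomics.total_gsh(gsh, gssg) == expected

    def test_total_gsh_rejects_negative(self):
        with pytest.raises(ValueError):
            proteomics.total_gsh(-1.0, 0.0)

    @pytest.mark.parametrize("ddct, expected", [(0, 1.0), (1, 0.5), (-2, 4.0)])
    def test_ddct_expression(self, ddct, expected):
        assert proteomics.ddct_expression(ddct) == pytest.approx(expected)
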