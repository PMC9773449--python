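"""Discovery-phase operations against hand values and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from chemosig import discovery
from chemosig.matrix import ProteinMatrix


def _matrix(values: dict, groups: dict) -> ProteinMatrix:
    df = pd.DataFrame(values).T
    return ProteinMatrix(values=df, groups=pd.Series(groups))


class TestTop3Summarize:
    def test_mean_of_three_largest(self):
        table = pd.DataFrame(
            {
                "protein": ["A"] * 4,
                "peptide": [f"A.p{i}" for i in range(4)],
                "sample": ["s1"] * 4,
                "area": [10.0, 8.0, 6.0, 1.0],
            }
        )
        m = discovery.top3_summarize(table)
        assert m.values.loc["A", "s1"] == pytest.approx(np.log2(8.0))

    def test_single_peptide_fallback(self):
        table = pd.DataFrame(
            {"protein": ["A"], "peptide": ["A.p1"], "sample": ["s1"],
             "area": [4.0]}
        )
        m = discovery.top3_summarize(table)
        assert m.values.loc["A", "s1"] == pytest.approx(2.0)

    def test_negative_area_rejected(self):
        table = pd.DataFrame(
            {"protein": ["A"], "peptide": ["p"], "sample": ["s"], "area": [-1.0]}
        )
        with pytest.raises(ValueError, match="negative"):
            discovery.top3_summarize(table)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_sort_and_average_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for prot in "AB":
            for samp in ("s1", "s2"):
                for k in range(rng.integers(1, 20)):
                    rows.append((prot, f"{prot}.p{k}", samp,
                                 float(rng.uniform(1, 1e6))))
        table = pd.DataFrame(rows, columns=["protein", "peptide", "sample", "area"])
        m = discovery.top3_summarize(table)
        for (prot, samp), sub in table.groupby(["protein", "sample"]):
            expect = np.log2(np.mean(sorted(sub.area, reverse=True)[:3]))
            assert m.values.loc[prot, samp] == pytest.approx(expect, abs=1e-12)


class TestEqualizeMedianNormalize:
    def test_two_columns_meet_at_common_median(self):
        m = _matrix(
            {"p1": {"s1": 9.0, "s2": 11.0}, "p2": {"s1": 10.0, "s2": 12.0},
             "p3": {"s1": 11.0, "s2": 13.0}},
            {"s1": "g", "s2": "g"},
        )
        out = discovery.equalize_median_normalize(m)
        assert out.values["s1"].median() == pytest.approx(11.0)
        assert out.values["s2"].median() == pytest.approx(11.0)
        assert (out.values["s1"] - m.values["s1"]).iloc[0] == pytest.approx(1.0)
        assert (out.values["s2"] - m.values["s2"]).iloc[0] == pytest.approx(-1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.normal(20, 2, (30, 5)),
                            index=[f"p{i}" for i in range(30)],
                            columns=[f"s{j}" for j in range(5)])
        vals.iloc[rng.random((30, 5)) < 0.2] = np.nan
        m = ProteinMatrix(values=vals)
        once = discovery.equalize_median_normalize(m)
        twice = discovery.equalize_median_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        meds = once.values.median()
        assert (meds - meds.iloc[0]).abs().max() < 1e-9

    def test_all_missing_column_rejected(self):
        m = ProteinMatrix(values=pd.DataFrame({"s1": [1.0], "s2": [np.nan]},
                                              index=["p"]))
        with pytest.raises(ValueError, match="no present values"):
            discovery.equalize_median_normalize(m)


class TestPresenceFilter:
    def _seven_by_three(self, counts):
        # counts: present values per group for one protein, groups of 7
        groups = {}
        values = {}
        row = {}
        for gi, c in enumerate(counts):
            for si in range(7):
                name = f"g{gi}s{si}"
                groups[name] = f"g{gi}"
                row[name] = 20.0 if si < c else np.nan
        values["p1"] = row
        return _matrix(values, groups)

    def test_three_of_seven_removed(self):
        m = self._seven_by_three([3, 7, 7])
        kept, removed = discovery.presence_filter(m, 4)
        assert removed == ["p1"] and kept.values.empty

    def test_four_of_seven_everywhere_retained(self):
        m = self._seven_by_three([4, 4, 4])
        kept, removed = discovery.presence_filter(m, 4)
        assert removed == [] and list(kept.proteins) == ["p1"]

    def test_min_present_larger_than_group_rejected(self):
        m = self._seven_by_three([7, 7, 7])
        with pytest.raises(ValueError, match="exceeds"):
            discovery.presence_filter(m, 8)


class TestDifferentialTest:
    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_identical_groups_give_t0_p1(self):
        m = _matrix(
            {"p1": {"a1": 5.0, "a2": 5.0, "b1": 5.0, "b2": 5.0}},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        res = discovery.differential_test(m, ("A", "B"))
        assert res.table.loc[0, "t"] == 0.0
        assert res.table.loc[0, "p"] == 1.0

    def test_matches_welch_formula_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        m = _matrix(
            {"p1": dict(zip("abcdef", np.r_[a, b]))},
            dict(zip("abcdef", ["A"] * 3 + ["B"] * 3)),
        )
        res = discovery.differential_test(m, ("A", "B"))
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_or = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_or = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        p_or = 2 * stats.t.sf(abs(t_or), df_or)
        assert res.table.loc[0, "t"] == pytest.approx(t_or, abs=1e-12)
        assert res.table.loc[0, "p"] == pytest.approx(p_or, abs=1e-12)
        assert res.table.loc[0, "log2_fc"] == pytest.approx(-1.0)

    def test_underpowered_protein_skipped_with_reason(self):
        m = _matrix(
            {"p1": {"a1": 1.0, "a2": np.nan, "b1": 2.0, "b2": 3.0}},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        res = discovery.differential_test(m, ("A", "B"))
        assert res.table.empty
        assert res.skipped[0][0] == "p1"

    def test_q_values_are_benjamini_hochberg(self):
        rng = np.random.default_rng(1)
        vals = pd.DataFrame(rng.normal(0, 1, (50, 10)),
                            index=[f"p{i}" for i in range(50)],
                            columns=[f"s{j}" for j in range(10)])
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=vals.columns)
        res = discovery.differential_test(ProteinMatrix(vals, groups), ("A", "B"))
        from statsmodels.stats.multitest import multipletests

        expect = multipletests(res.table["p"], method="fdr_bh")[1]
        assert np.allclose(res.table["q"], expect)


class TestSelectCandidates:
    def _matrix_with_groups(self):
        groups = {}
        values = {"pa": {}, "pb": {}, "dull": {}}
        for gi, g in enumerate(["chemoresistant", "g1", "g2"]):
            for si in range(7):
                s = f"{g}{si}"
                groups[s] = g
                # pa: present in 4 of chemoresistant, absent in g1
                values["pa"][s] = 20.0 if (g == "chemoresistant" and si < 4) or g == "g2" else np.nan
                # pb: fully present in chemoresistant, mixed elsewhere
                values["pb"][s] = 20.0 if g == "chemoresistant" or si < 3 else np.nan
                values["dull"][s] = 20.0 if si < 5 else np.nan
        return _matrix(values, groups)

    def test_criterion_a_and_b_tagging(self):
        m = self._matrix_with_groups()
        diff = discovery.DiffTestResult(
            ("chemoresistant", "g1"),
            pd.DataFrame(columns=["protein", "q"]), [],
        )
        cand = discovery.select_candidates(diff, m, [])
        assert "criterion_a" in cand.reasons["pa"]
        assert "criterion_b" in cand.reasons["pb"]
        assert "dull" not in cand.reasons

    def test_literature_outside_panel_kept_with_warning(self):
        m = self._matrix_with_groups()
        diff = discovery.DiffTestResult(
            ("chemoresistant", "g1"), pd.DataFrame(columns=["protein", "q"]), []
        )
        cand = discovery.select_candidates(diff, m, ["CT45"])
        assert cand.reasons["CT45"] == ("literature",)
        assert "CT45" in cand.warnings

    def test_empty_inputs_give_empty_set(self):
        groups = {"a": "chemoresistant", "b": "g1"}
        m = _matrix({"p": {"a": 1.0, "b": np.nan}}, groups)
        diff = discovery.DiffTestResult(
            ("chemoresistant", "g1"), pd.DataFrame(columns=["protein", "q"]), []
        )
        cand = discovery.select_candidates(diff, m, [], min_present=4)
        # p is all-present in the (single-sample) resistant group: criterion b
        assert cand.reasons.get("p") == ("criterion_b",)
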