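"""Targeted-quantification operations: QC, LOD handling, normalization, rollup."""

import numpy as np
import pandas as pd
import pytest

from chemosig import prm
from chemosig.matrix import ProteinMatrix


def _trans_rows(run, pep, frag_areas_endo, frag_areas_std, rt_endo=None,
                rt_std=None, protein="PR1", patient=None):
    rows = []
    n = len(frag_areas_std)
    rt_endo = rt_endo or [50.0] * n
    rt_std = rt_std or [50.0] * n
    for i in range(n):
        frag = f"y{i + 3}"
        if frag_areas_endo[i] is not None:
            rows.append((run, patient or run, protein, pep, frag, "endogenous",
                         frag_areas_endo[i], rt_endo[i]))
        rows.append((run, patient or run, protein, pep, frag, "standard",
                     frag_areas_std[i], rt_std[i]))
    return rows


def _table(rows):
    return pd.DataFrame(
        rows,
        columns=["run_id", "patient_id", "protein", "peptide", "fragment",
                 "channel", "area", "rt"],
    )


class TestQcTransitions:
    def test_matching_patterns_all_accepted(self):
        std = [100.0, 200.0, 300.0, 400.0, 500.0]
        endo = [v * 0.3 for v in std]
        t = _table(_trans_rows("r1", "pep1", endo, std))
        v = prm.qc_transitions(t)[("r1", "pep1")]
        assert v.passed and len(v.accepted) == 5 and not v.rejected

    def test_inflated_fragment_rejected_as_interference(self):
        std = [100.0, 200.0, 300.0, 400.0, 500.0]
        endo = [v * 0.3 for v in std]
        endo[1] *= 10  # contaminated trace breaks the pattern correlation
        t = _table(_trans_rows("r1", "pep1", endo, std))
        v = prm.qc_transitions(t)[("r1", "pep1")]
        assert v.rejected == {"y4": "interference"}
        assert v.passed and len(v.accepted) == 4

    def test_leave_one_out_improvement_below_margin_keeps_all(self):
        std = [100.0, 200.0, 300.0, 400.0, 500.0]
        endo = [31.0, 59.0, 92.0, 118.0, 152.0]  # noisy but coherent
        t = _table(_trans_rows("r1", "pep1", endo, std))
        v = prm.qc_transitions(t)[("r1", "pep1")]
        assert not v.rejected

    def test_too_few_traces_fails_peptide(self):
        std = [100.0, 200.0, 300.0]
        endo = [30.0, 60.0, None]
        t = _table(_trans_rows("r1", "pep1", endo, std))
        v = prm.qc_transitions(t)[("r1", "pep1")]
        assert not v.passed
        assert v.rejected["y5"] == "too_few_traces"

    def test_rt_disagreement_rejected(self):
        std = [100.0, 200.0, 300.0, 400.0]
        endo = [30.0, 60.0, 90.0, 120.0]
        t = _table(_trans_rows("r1", "pep1", endo, std,
                               rt_endo=[50.0, 50.0, 50.0, 53.0]))
        v = prm.qc_transitions(t)[("r1", "pep1")]
        assert v.rejected["y6"] == "rt_outlier"

    def test_no_standard_rows_is_error(self):
        rows = [("r1", "r1", "PR1", "pep1", "y3", "endogenous", 10.0, 50.0)]
        with pytest.raises(ValueError, match="standard"):
            prm.qc_transitions(_table(rows))


class TestSumPeptideArea:
    def test_sums_accepted_fragments(self):
        std = [100.0, 100.0, 100.0]
        endo = [5.0, 5.0, 10.0]
        t = _table(_trans_rows("r1", "pep1", endo, std))
        v = prm.qc_transitions(t)
        out = prm.sum_peptide_area(t, v)
        assert out.loc[0, "endogenous"] == pytest.approx(20.0)
        assert out.loc[0, "standard"] == pytest.approx(300.0)

    def test_failed_peptide_yields_no_value(self):
        std = [100.0, 100.0, 100.0]
        endo = [5.0, None, None]
        t = _table(_trans_rows("r1", "pep1", endo, std))
        out = prm.sum_peptide_area(t, prm.qc_transitions(t))
        assert out.empty

    def test_matches_filter_and_sum_oracle(self):
        rng = np.random.default_rng(3)
        rows = []
        for run in ("r1", "r2"):
            for pep in ("a", "b"):
                std = rng.uniform(50, 500, 5)
                endo = std * rng.uniform(0.1, 0.5)
                rows += _trans_rows(run, pep, list(endo), list(std))
        t = _table(rows)
        v = prm.qc_transitions(t)
        out = prm.sum_peptide_area(t, v).set_index(["run_id", "peptide"])
        for (run, pep), verdict in v.items():
            sub = t[(t.run_id == run) & (t.peptide == pep)
                    & t.fragment.isin(verdict.accepted)]
            for ch in ("endogenous", "standard"):
                expect = sub[sub.channel == ch].area.sum()
                assert out.loc[(run, pep), ch] == pytest.approx(expect)


class TestReplaceBelowLod:
    def _areas(self, endo):
        return pd.DataFrame(
            {"run_id": [f"r{i}" for i in range(len(endo))],
             "patient_id": [f"r{i}" for i in range(len(endo))],
             "protein": "PR1", "peptide": "pep1",
             "endogenous": endo, "standard": 100.0}
        )

    def test_below_background_replaced_and_flagged(self):
        out = prm.replace_below_lod(self._areas([3.0, 12.0]), 10.0)
        assert out.loc[0, "endogenous"] == 10.0 and out.loc[0, "below_lod"]
        assert out.loc[1, "endogenous"] == 12.0 and not out.loc[1, "below_lod"]

    def test_all_above_background_is_identity(self):
        areas = self._areas([20.0, 30.0])
        out = prm.replace_below_lod(areas, 10.0)
        assert (out["endogenous"] == areas["endogenous"]).all()
        assert not out["below_lod"].any()

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            prm.replace_below_lod(self._areas([5.0]), 0.0)


class TestNormalizeByStandards:
    def _areas(self, runs_endo, runs_std):
        rows = []
        for run, (endo, std) in enumerate(zip(runs_endo, runs_std)):
            for pep, (e, s) in enumerate(zip(endo, std)):
                rows.append((f"r{run}", f"r{run}", "PR1", f"pep{pep}", e, s))
        return pd.DataFrame(rows, columns=["run_id", "patient_id", "protein",
                                           "peptide", "endogenous", "standard"])

    def test_recovers_injected_run_biases(self):
        base = np.array([100.0, 200.0, 400.0])
        areas = self._areas(
            [base * 2.0, base * 0.5],  # +1 / -1 log2 biases on both channels
            [base * 10 * 2.0, base * 10 * 0.5],
        )
        pq = prm.normalize_by_standards(areas)
        assert pq.shifts["r0"] - pq.shifts["r1"] == pytest.approx(-2.0, abs=1e-9)
        meds = pq.standard.median(axis=0)
        assert meds.max() - meds.min() < 1e-9
        # endogenous values equal across the two (biologically identical) runs
        assert np.allclose(pq.endogenous["r0"], pq.endogenous["r1"], atol=1e-9)

    def test_equal_median_runs_get_zero_relative_shift(self):
        base = np.array([100.0, 200.0, 400.0])
        areas = self._areas([base, base], [base * 10, base * 10])
        pq = prm.normalize_by_standards(areas)
        assert pq.shifts["r0"] == pytest.approx(pq.shifts["r1"], abs=1e-12)

    def test_endo_std_ratio_invariant(self):
        rng = np.random.default_rng(5)
        endo = [rng.uniform(10, 100, 4) for _ in range(3)]
        std = [rng.uniform(100, 1000, 4) for _ in range(3)]
        areas = self._areas(endo, std)
        pq = prm.normalize_by_standards(areas)
        raw_ratio = np.log2(np.array(endo)) - np.log2(np.array(std))
        norm_ratio = (pq.endogenous - pq.standard).T.to_numpy()
        assert np.allclose(norm_ratio, raw_ratio, atol=1e-9)

    def test_run_without_standards_rejected(self):
        areas = self._areas([[100.0]], [[np.nan]])
        with pytest.raises(ValueError, match="no standard"):
            prm.normalize_by_standards(areas)


class TestComputeCv:
    def _df(self, areas, patient="p1"):
        return pd.DataFrame(
            {"peptide": "pep1", "patient_id": patient,
             "run_id": [f"r{i}" for i in range(len(areas))],
             "endogenous": areas}
        )

    def test_constant_replicates_give_zero(self):
        cv = prm.compute_cv(self._df([100.0, 100.0, 100.0]))
        assert cv["pep1"] == pytest.approx(0.0)

    def test_two_replicates_formula(self):
        cv = prm.compute_cv(self._df([90.0, 110.0]))
        assert cv["pep1"] == pytest.approx(100 * np.sqrt(200) / 100, abs=1e-9)

    def test_scale_invariant(self):
        a = prm.compute_cv(self._df([90.0, 110.0, 95.0]))
        b = prm.compute_cv(self._df([900.0, 1100.0, 950.0]))
        assert a["pep1"] == pytest.approx(b["pep1"])

    def test_single_replicate_undefined(self):
        cv = prm.compute_cv(self._df([100.0]))
        assert np.isnan(cv["pep1"])


class TestDropFailedAndRollup:
    def _pq(self, endo):
        df = pd.DataFrame(endo).T
        df.index.name = "peptide"
        return prm.PeptideQuantMatrix(
            endogenous=df, standard=df * 0 + 10.0,
            shifts=pd.Series(0.0, index=df.columns),
        )

    def test_often_failing_peptide_dropped(self):
        pq = self._pq({"pepA": {"r1": 1.0, "r2": 2.0}, "pepB": {"r1": 1.0, "r2": 2.0}})
        verdicts = {
            ("r1", "pepA"): prm.QcVerdict("r1", "pepA", (), {}, False),
            ("r2", "pepA"): prm.QcVerdict("r2", "pepA", (), {}, False),
            ("r1", "pepB"): prm.QcVerdict("r1", "pepB", ("y3",) * 3, {}, True),
            ("r2", "pepB"): prm.QcVerdict("r2", "pepB", ("y3",) * 3, {}, True),
        }
        out, dropped_peps, dropped_runs = prm.drop_failed(pq, verdicts)
        assert dropped_peps == ["pepA"] and not dropped_runs

    def test_mostly_missing_sample_dropped(self):
        endo = {f"pep{i}": {"r1": 1.0, "r2": (np.nan if i else 1.0)}
                for i in range(10)}
        pq = self._pq(endo)
        verdicts = {
            (r, p): prm.QcVerdict(r, p, ("y3",) * 3, {},
                                  not np.isnan(pq.endogenous.loc[p, r]))
            for p in pq.endogenous.index for r in ("r1", "r2")
        }
        out, _, dropped_runs = prm.drop_failed(pq, verdicts)
        assert dropped_runs == ["r2"]

    def test_no_failures_leaves_matrix_unchanged(self):
        pq = self._pq({"pepA": {"r1": 1.0, "r2": 2.0}})
        verdicts = {(r, "pepA"): prm.QcVerdict(r, "pepA", ("y3",) * 3, {}, True)
                    for r in ("r1", "r2")}
        out, dp, dr = prm.drop_failed(pq, verdicts)
        assert not dp and not dr
        pd.testing.assert_frame_equal(out.endogenous, pq.endogenous)

    def test_rollup_forced_single_peptide_and_lowest_cv(self):
        pq = self._pq({
            "A.p1": {"r1": 8.0, "r2": 9.0},
            "B.p1": {"r1": 5.0, "r2": 6.0},
            "B.p2": {"r1": 7.0, "r2": 7.5},
        })
        pep2prot = pd.Series({"A.p1": "A", "B.p1": "B", "B.p2": "B"})
        cvs = pd.Series({"A.p1": 4.0, "B.p1": 8.0, "B.p2": 3.0})
        pm, chosen, excluded = prm.best_peptide_rollup(pq, pep2prot, cvs=cvs)
        assert chosen == {"A": "A.p1", "B": "B.p2"}
        assert not excluded
        assert (pm.values.loc["B"] == pq.endogenous.loc["B.p2"]).all()


class TestImputeMin:
    def test_missing_replaced_with_row_minimum(self):
        vals = pd.DataFrame({"s1": [8.0], "s2": [10.0], "s3": [np.nan]},
                            index=["p"])
        out = prm.impute_min(ProteinMatrix(values=vals))
        assert out.values.loc["p"].tolist() == [8.0, 10.0, 8.0]
        assert out.flags["imputed"].loc["p"].tolist() == [False, False, True]

    def test_complete_matrix_identity(self):
        vals = pd.DataFrame({"s1": [8.0], "s2": [10.0]}, index=["p"])
        out = prm.impute_min(ProteinMatrix(values=vals))
        pd.testing.assert_frame_equal(out.values, vals)
        assert not out.flags["imputed"].any().any()

    def test_imputation_never_lowers_the_minimum(self):
        rng = np.random.default_rng(8)
        vals = pd.DataFrame(rng.normal(10, 2, (20, 8)))
        vals[rng.random((20, 8)) < 0.3] = np.nan
        vals.iloc[:, 0] = 5.0  # guarantee one observed value per row
        m = ProteinMatrix(values=vals)
        out = prm.impute_min(m)
        assert not out.values.isna().any().any()
        assert (out.values.min(axis=1) == m.values.min(axis=1)).all()

    def test_fully_missing_protein_rejected(self):
        vals = pd.DataFrame({"s1": [np.nan], "s2": [np.nan]}, index=["p"])
        with pytest.raises(ValueError, match="no observed"):
            prm.impute_min(ProteinMatrix(values=vals))
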