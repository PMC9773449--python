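"""Splitting, logistic fitting, forward selection, consensus, clinical models."""

import numpy as np
import pandas as pd
import pytest

from chemosig import roc, selection
from chemosig.logistic import fit_logistic
from conftest import make_planted_features


def _labels(n_pos, n_neg):
    ids = [f"s{i}" for i in range(n_pos + n_neg)]
    return pd.Series([True] * n_pos + [False] * n_neg, index=ids)


class TestSplitCohort:
    def test_eighteen_samples_split_eight_ten(self):
        cfg = selection.SelectionConfig(seed=0, stratified=False)
        tr, va = selection.split_cohort(_labels(9, 9), cfg,
                                        np.random.default_rng(0))
        assert len(tr) == 8 and len(va) == 10

    def test_eighty_samples_split_thirtysix_fortyfour(self):
        cfg = selection.SelectionConfig(seed=0)
        tr, va = selection.split_cohort(_labels(25, 55), cfg,
                                        np.random.default_rng(1))
        assert len(tr) == 36 and len(va) == 44

    def test_stratified_keeps_both_classes_everywhere(self):
        labels = _labels(25, 63)
        cfg = selection.SelectionConfig(seed=0)
        for k in range(100):
            tr, va = selection.split_cohort(labels, cfg,
                                            np.random.default_rng(k))
            assert labels[tr].nunique() == 2 and labels[va].nunique() == 2
            assert set(tr).isdisjoint(va)
            assert len(tr) + len(va) == 88 and len(tr) == 39

    def test_ten_eight_switch(self):
        cfg = selection.SelectionConfig(seed=0, split_ratio=(10, 8))
        tr, va = selection.split_cohort(_labels(9, 9), cfg,
                                        np.random.default_rng(0))
        assert len(tr) == 10 and len(va) == 8


class TestFitLogistic:
    def test_matches_statsmodels_mle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        for trial in range(15):
            n = 60
            X = rng.normal(0, 1, (n, 3))
            eta = 0.4 * X[:, 0] - 0.6 * X[:, 1] + 0.2
            y = rng.random(n) < 1 / (1 + np.exp(-eta))
            if y.all() or not y.any():
                continue
            ours = fit_logistic(X, y)
            ref = sm.Logit(y.astype(float), sm.add_constant(X)).fit(disp=0)
            assert ours.intercept == pytest.approx(ref.params[0], abs=1e-6)
            assert np.allclose(ours.coef, ref.params[1:], atol=1e-6)

    def test_separable_data_flags_ridge_and_scores_auc_one(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        model = fit_logistic(X, y)
        assert model.ridge_used > 0
        assert roc.auc(model.scores, y) == 1.0

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = rng.random(30) < 0.5
        y[0], y[1] = True, False
        with pytest.warns(UserWarning, match="constant"):
            model = fit_logistic(X, y, feature_names=("const", "z"))
        assert model.dropped == ("const",)
        assert model.coef[0] == 0.0

    def test_null_features_give_chance_auc(self):
        rng = np.random.default_rng(2)
        n = 4000
        X = rng.normal(size=(n, 2))
        y = rng.random(n) < 0.4
        model = fit_logistic(X, y)
        assert abs(roc.auc(model.scores, y) - 0.5) < 0.03


class TestForwardSelect:
    def _features(self, X):
        return pd.DataFrame(X, index=[f"s{i}" for i in range(len(X))],
                            columns=[f"F{j}" for j in range(X.shape[1])])

    def test_stops_when_gain_at_most_delta(self):
        # F0 separates strongly; F1 is a slightly noisy copy adding < 0.02
        rng = np.random.default_rng(3)
        y = np.r_[np.ones(30), np.zeros(30)].astype(bool)
        f0 = np.where(y, rng.normal(2.0, 1, 60), rng.normal(0, 1, 60))
        f1 = f0 + rng.normal(0, 0.05, 60)
        F = self._features(np.column_stack([f0, f1]))
        labels = pd.Series(y, index=F.index)
        path = selection.forward_select(F, labels,
                                        selection.SelectionConfig(seed=0))
        assert path.features == ("F0",) or len(path.features) == 1

    def test_accepted_steps_respect_gain_rule(self):
        X, y = make_planted_features(42, n_features=8, n_planted=2, effect=1.0)
        path = selection.forward_select(X, y, selection.SelectionConfig(seed=0))
        aucs = path.train_aucs
        assert len(aucs) == len(path.features) >= 1
        for prev, nxt in zip(aucs, aucs[1:]):
            assert nxt - prev > 0.02

    def test_max_features_cap(self):
        X, y = make_planted_features(1, n_features=10, n_planted=5, effect=2.0)
        cfg = selection.SelectionConfig(seed=0, max_features=2)
        path = selection.forward_select(X, y, cfg)
        assert len(path.features) <= 2


class TestRunRepeatsAndConsensus:
    def test_repeats_reproducible_and_disjoint(self):
        X, y = make_planted_features(5, n_resistant=12, n_sensitive=24,
                                     n_features=10)
        cfg = selection.SelectionConfig(seed=9, n_repeats=20)
        a = selection.run_repeats(X, y, cfg)
        b = selection.run_repeats(X, y, cfg)
        assert len(a) == 20
        for ra, rb in zip(a, b):
            assert ra.combination == rb.combination
            assert ra.val_auc == rb.val_auc
            assert set(ra.train_ids).isdisjoint(ra.val_ids)

    def test_consensus_argmax_and_tie_breaks(self):
        def rep(i, combo):
            return selection.RepeatResult(i, ("a",), ("b",), combo, (0.8,), 0.7)

        reps = [rep(i, ("A", "B", "C")) for i in range(3)]
        reps += [rep(i, ("A", "B", "D")) for i in range(3, 5)]
        reps += [rep(5, ("A", "B"))]
        table = selection.tally_combinations(reps)
        assert table.iloc[0]["combination"] == "A+B+C"
        # tie: smaller set wins, then lexicographic
        reps = [rep(0, ("A", "B", "C")), rep(1, ("A", "B", "C")),
                rep(2, ("D", "E")), rep(3, ("D", "E")),
                rep(4, ("A", "C")), rep(5, ("A", "C"))]
        table = selection.tally_combinations(reps)
        assert table.iloc[0]["combination"] == "A+C"

    def test_consensus_refit_on_whole_cohort(self):
        X, y = make_planted_features(7, n_resistant=15, n_sensitive=30,
                                     n_features=6, n_planted=2, effect=2.0)
        cfg = selection.SelectionConfig(seed=3, n_repeats=30)
        reps = selection.run_repeats(X, y, cfg)
        cons = selection.consensus(reps, X, y)
        assert cons.frequency <= cons.n_repeats == 30
        assert cons.roc_summary.auc > 0.8
        assert set(cons.features) <= set(X.columns)


class TestClinical:
    def _clinical(self, n, rng, missing_ca125=0):
        df = pd.DataFrame(
            {
                "age": rng.normal(60, 8, n).round(1),
                "menopausal_status": rng.choice(["pre", "post"], n),
                "ca125": rng.lognormal(6.5, 1.0, n).round(1),
                "treatment": rng.choice(["surgery", "neoadjuvant"], n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        if missing_ca125:
            df.iloc[:missing_ca125, df.columns.get_loc("ca125")] = np.nan
        return df

    def test_encoding_and_exclusion(self):
        rng = np.random.default_rng(0)
        clin = self._clinical(10, rng, missing_ca125=2)
        design, excluded = selection.encode_clinical(clin)
        assert list(design.columns) == list(selection.CLINICAL_COVARIATES)
        assert len(excluded) == 2 and len(design) == 8
        assert set(design["postmenopausal"].unique()) <= {0.0, 1.0}

    def test_null_covariates_leave_auc_roughly_unchanged(self):
        rng = np.random.default_rng(1)
        X, y = make_planted_features(2, n_resistant=100, n_sensitive=150,
                                     n_features=3, n_planted=3, effect=1.0)
        clin = self._clinical(250, rng)
        clin.index = X.index
        ev = selection.evaluate_with_clinical(X, clin, y)
        assert abs(ev.combined.auc - ev.proteins.auc) < 0.03
        assert abs(ev.clinical.auc - 0.5) < 0.08
        assert ev.p_proteins_vs_combined > 0.01

    def test_partial_sensitivity_window(self):
        clin = pd.DataFrame(
            {
                "group": ["chemoresistant"] * 2 + ["chemosensitive"] * 3,
                "tfip_months": [3.0, 5.0, 8.0, 11.0, 20.0],
            },
            index=list("abcde"),
        )
        ids = selection.partial_sensitivity_subset(clin)
        assert ids == ["a", "b", "c", "d"]

    def test_boundary_month_twelve_retained(self):
        clin = pd.DataFrame(
            {"group": ["chemoresistant", "chemosensitive"],
             "tfip_months": [3.0, 12.0]},
            index=["a", "b"],
        )
        assert selection.partial_sensitivity_subset(clin) == ["a", "b"]

    def test_empty_partial_group_is_error(self):
        clin = pd.DataFrame(
            {"group": ["chemoresistant", "chemosensitive"],
             "tfip_months": [3.0, 30.0]},
            index=["a", "b"],
        )
        with pytest.raises(ValueError, match="no chemosensitive"):
            selection.partial_sensitivity_subset(clin)
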