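"""Rebalancing, cross-validation, wrapper selection and the cascade."""

import numpy as np
import pandas as pd
import pytest

from ppgscreen.errors import BalanceError, FoldError, SchemaError
from ppgscreen.mlpipe import (
    ALGORITHMS,
    ClassifierSpec,
    PartRuleClassifier,
    RipperRuleClassifier,
    audit_leakage,
    balance_classes,
    cv_accuracy,
    evaluate,
    fit_stage1,
    fit_stage2,
    greedy_stepwise_select,
    predict_two_stage,
    stage1_matrix,
    stage2_matrix,
)

from conftest import make_subject_table


def planted_dataset(n=100, n_noise=10, effect=2.0, seed=0):
    """Two balanced classes; one feature carries an `effect`-sd separation."""
    rng = np.random.default_rng(seed)
    y = pd.Series(["A"] * (n // 2) + ["B"] * (n // 2))
    X = pd.DataFrame(
        rng.standard_normal((n, n_noise)),
        columns=[f"noise_{i}" for i in range(n_noise)],
    )
    X.insert(
        min(3, n_noise), "informative",
        rng.standard_normal(n) + effect * (y == "B"),
    )
    return X, y


class TestBalance:
    def test_minority_replicated_to_majority_size(self):
        X = pd.DataFrame({"f": np.arange(60.0)})
        y = pd.Series(["A"] * 50 + ["B"] * 10)
        sid = pd.Series([f"s{i}" for i in range(60)])
        Xb, yb, sb = balance_classes(X, y, sid)
        assert yb.value_counts().to_dict() == {"A": 50, "B": 50}
        b_ids = sb[yb == "B"].value_counts()
        assert set(b_ids.values) == {5}  # each B subject appears 5x

    def test_already_balanced_unchanged(self):
        X = pd.DataFrame({"f": np.arange(20.0)})
        y = pd.Series(["A"] * 10 + ["B"] * 10)
        Xb, yb, _ = balance_classes(X, y)
        assert len(Xb) == 20
        assert sorted(Xb["f"]) == sorted(X["f"])

    def test_ceiling_replication_then_truncation(self):
        X = pd.DataFrame({"f": np.arange(10.0)})
        y = pd.Series(["A"] * 7 + ["B"] * 3)
        _, yb, _ = balance_classes(X, y)
        assert yb.value_counts().to_dict() == {"A": 7, "B": 7}

    def test_single_class_rejected(self):
        with pytest.raises(BalanceError):
            balance_classes(pd.DataFrame({"f": [1.0, 2.0]}), pd.Series(["A", "A"]))


class TestCVAccuracy:
    def test_separable_data_is_perfectly_classified(self):
        X, y = planted_dataset(effect=50.0)
        acc = cv_accuracy(X[["informative"]], y, ClassifierSpec("nb"), k=10)
        assert acc == 100.0

    def test_null_features_score_at_chance(self):
        X, y = planted_dataset(effect=0.0, seed=1)
        acc = cv_accuracy(
            X, y, ClassifierSpec("knn"), k=10, seed=1
        )
        # 3 sigma binomial band around 50% at n=100
        assert 35.0 <= acc <= 65.0

    def test_deterministic_given_seed(self):
        X, y = planted_dataset(effect=1.0)
        spec = ClassifierSpec("rf", seed=3)
        a1 = cv_accuracy(X, y, spec, k=5, seed=7)
        a2 = cv_accuracy(X, y, spec, k=5, seed=7)
        assert a1 == a2

    def test_small_class_raises_fold_error(self):
        X = pd.DataFrame({"f": np.arange(15.0)})
        y = pd.Series(["A"] * 12 + ["B"] * 3)
        with pytest.raises(FoldError):
            cv_accuracy(X, y, ClassifierSpec("nb"), k=10)

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_every_classifier_family_beats_chance_on_easy_data(self, algorithm):
        X, y = planted_dataset(effect=4.0, n_noise=3, seed=2)
        acc = cv_accuracy(X, y, ClassifierSpec(algorithm, seed=0), k=5, seed=2)
        assert acc >= 80.0


class TestRuleLearners:
    def test_ripper_learns_a_threshold_rule(self):
        X, y = planted_dataset(effect=6.0, n_noise=2, seed=4)
        clf = RipperRuleClassifier().fit(X.to_numpy(), y.to_numpy())
        assert len(clf.rules_) >= 1
        assert (clf.predict(X.to_numpy()) == y.to_numpy()).mean() >= 0.95

    def test_part_rules_cover_and_default(self):
        X, y = planted_dataset(effect=6.0, n_noise=2, seed=4)
        clf = PartRuleClassifier(random_state=0).fit(X.to_numpy(), y.to_numpy())
        assert len(clf.rules_) >= 1
        assert (clf.predict(X.to_numpy()) == y.to_numpy()).mean() >= 0.95


class TestGreedySelection:
    def test_planted_feature_selected_first(self):
        X, y = planted_dataset(effect=50.0)
        sel = greedy_stepwise_select(X, y, ClassifierSpec("nb"), k=10, seed=0)
        assert sel.selected_features[0] == "informative"
        assert sel.accuracy_trajectory[0] == 100.0

    def test_pure_noise_yields_empty_selection(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            rng.standard_normal((80, 6)), columns=[f"n{i}" for i in range(6)]
        )
        y = pd.Series(["A"] * 50 + ["B"] * 30)
        sel = greedy_stepwise_select(X, y, ClassifierSpec("nb"), k=10, seed=0)
        majority = 100.0 * 50 / 80
        if not sel.selected_features:
            assert sel.final_cv_accuracy == pytest.approx(majority)

    def test_forward_trajectory_non_decreasing(self):
        X, y = planted_dataset(effect=2.0, seed=6)
        sel = greedy_stepwise_select(X, y, ClassifierSpec("nb"), k=5, seed=6)
        traj = sel.accuracy_trajectory
        assert all(b >= a for a, b in zip(traj, traj[1:]))

    def test_backward_direction_runs_and_keeps_subset(self):
        X, y = planted_dataset(effect=3.0, n_noise=4, seed=8)
        sel = greedy_stepwise_select(
            X, y, ClassifierSpec("nb"), direction="backward", k=5, seed=8
        )
        assert "informative" in sel.selected_features
        assert set(sel.selected_features) <= set(X.columns)


class TestTwoStage:
    def test_stage_matrices_have_expected_schema(self, two_class_table):
        X, y, sid = stage1_matrix(two_class_table)
        assert any(c.endswith("_var") for c in X.columns)
        assert set(y) == {"Healthy", "CVD"}
        X2, y2, _ = stage2_matrix(two_class_table)
        assert not any(c.endswith("_var") for c in X2.columns)
        assert set(y2) == {"ACS"}

    def test_stage2_refuses_healthy_rows(self, two_class_table):
        with pytest.raises(SchemaError):
            fit_stage2(two_class_table, ClassifierSpec("nb"))

    def test_stage2_refuses_variance_features(self, two_class_table):
        cvd = two_class_table[two_class_table["label"] != "Healthy"]
        with pytest.raises(SchemaError):
            fit_stage2(cvd, ClassifierSpec("nb"), features=("SA_mean", "SA_var"))

    def test_cascade_routes_through_both_stages(self):
        table = make_subject_table(
            {"Healthy": 30, "ACS": 15, "CVA": 15}, seed=9, shift=6.0
        )
        m1 = fit_stage1(table, ClassifierSpec("nb"))
        cvd = table[table["label"] != "Healthy"]
        m2 = fit_stage2(cvd, ClassifierSpec("nb"))
        pred = predict_two_stage(table, m1, m2)
        assert set(pred) <= {"Healthy", "ACS", "CVA"}
        # strong separation: the cascade recovers most labels
        assert (pred == table["label"].to_numpy()).mean() >= 0.9

    def test_healthy_stage1_verdict_is_final(self):
        table = make_subject_table(
            {"Healthy": 30, "ACS": 15, "DVT": 10}, seed=9, shift=6.0
        )
        m1 = fit_stage1(table, ClassifierSpec("nb"))
        m2 = fit_stage2(
            table[table["label"] != "Healthy"], ClassifierSpec("nb")
        )
        pred = predict_two_stage(table, m1, m2)
        stage1_says_healthy = m1.predict(table) == "Healthy"
        assert np.all(pred[stage1_says_healthy] == "Healthy")

    def test_predict_missing_columns_raises(self, two_class_table):
        m1 = fit_stage1(two_class_table, ClassifierSpec("nb"))
        with pytest.raises(SchemaError):
            m1.predict(two_class_table[["SA_mean", "label"]])


class TestEvaluate:
    def test_perfect_classifier_report(self):
        X, y = planted_dataset(effect=50.0)
        rep = evaluate(X[["informative"]], y, ClassifierSpec("nb"), k=10)
        assert rep.accuracy == 100.0
        assert all(v == 1.0 for v in rep.per_class_recall.values())
        assert rep.macro_recall == 1.0

    def test_confusion_trace_equals_accuracy(self):
        X, y = planted_dataset(effect=1.5, seed=3)
        rep = evaluate(X, y, ClassifierSpec("j48", seed=0), k=5, seed=3)
        trace = float(np.trace(rep.confusion.to_numpy()))
        assert rep.accuracy == pytest.approx(100.0 * trace / len(y))
        assert rep.confusion.sum(axis=1).to_dict() == y.value_counts().to_dict()

    def test_no_leakage_in_replicate_train_only_mode(self):
        X, y = planted_dataset(n=60, effect=1.0, seed=5)
        y = pd.Series(["A"] * 40 + ["B"] * 20)  # imbalanced
        sid = pd.Series([f"s{i}" for i in range(60)])
        rep = evaluate(
            X, y, ClassifierSpec("nb"), k=5, seed=5,
            mode="replicate-train-only", subject_ids=sid,
        )
        assert audit_leakage(rep) == set()

    def test_global_replication_leaks_duplicates_across_folds(self):
        """The audit exposes why balancing before CV inflates accuracy."""
        X, y = planted_dataset(n=60, effect=1.0, seed=5)
        y = pd.Series(["A"] * 45 + ["B"] * 15)
        sid = pd.Series([f"s{i}" for i in range(60)])
        rep = evaluate(
            X, y, ClassifierSpec("nb"), k=5, seed=5,
            mode="replicate-global", subject_ids=sid,
        )
        assert len(audit_leakage(rep)) > 0
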