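"""OVA binarization, confusion-matrix metrics and cross-validation."""

import numpy as np
import pandas as pd
import pytest

from eeglgs import (
    ClassifierConfig,
    ConfusionCounts,
    compute_metrics,
    crossval_evaluate,
    evaluate_all,
    ova_binarize,
)
from eeglgs.classify import summary_percent
from eeglgs.exceptions import ContractError, StratificationError
from oracles import metric_formulas


def make_table(rng, n_per_class=30, n_features=6, classes=("a", "b", "c"), sep=8.0):
    """Synthetic feature table with class means separated by ``sep`` sds."""
    rows = []
    for ci, cls in enumerate(classes):
        X = rng.standard_normal((n_per_class, n_features)) + ci * sep
        for k in range(n_per_class):
            row = {
                "subject_id": f"{cls}{k // 5}",
                "segment": k % 5,
                "band": "alpha",
                "label": cls,
            }
            row |= {f"f{j}": X[k, j] for j in range(n_features)}
            rows.append(row)
    return pd.DataFrame(rows)


class TestOvaBinarize:
    def test_basic(self):
        out = ova_binarize(np.array(["A", "B", "A", "C"]), "A")
        assert out.tolist() == [1, 0, 1, 0]

    def test_all_positive(self):
        assert ova_binarize(np.array(["A", "A"]), "A").tolist() == [1, 1]

    def test_absent_class_rejected(self):
        with pytest.raises(ContractError):
            ova_binarize(np.array(["A", "B"]), "X")


class TestMetrics:
    def test_balanced_counts_give_090(self):
        ms = compute_metrics(ConfusionCounts(tp=9, tn=9, fp=1, fn=1))
        assert ms.accuracy == pytest.approx(0.90)
        assert ms.precision == pytest.approx(0.90)
        assert ms.sensitivity == pytest.approx(0.90)
        assert ms.f1 == pytest.approx(0.90)

    def test_degenerate_no_positive_predictions(self):
        ms = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=5))
        assert ms.precision == 0.0
        assert "precision" in ms.zero_division_flags
        assert ms.sensitivity == 0.0
        assert ms.accuracy == pytest.approx(0.5)

    def test_matches_formula_oracle(self, rng):
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 40, size=4)
            if tp + tn + fp + fn == 0:
                continue
            ms = compute_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            ref = metric_formulas(int(tp), int(tn), int(fp), int(fn))
            for name in ("accuracy", "precision", "sensitivity", "f1"):
                assert getattr(ms, name) == pytest.approx(ref[name], abs=1e-12)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ContractError):
            compute_metrics(ConfusionCounts())


class TestCrossVal:
    def test_separable_classes_perfect_knn(self, rng):
        table = make_table(rng, sep=10.0)
        report = crossval_evaluate(table, ClassifierConfig("knn", seed=1))
        assert (report.records["accuracy"] == 1.0).all()
        assert len(report.records) == 3 * 10  # classes x folds

    def test_fold_partition_covers_each_sample_once(self, rng):
        from sklearn.model_selection import StratifiedKFold

        table = make_table(rng)
        y = table["label"].to_numpy()
        splitter = StratifiedKFold(n_splits=10, shuffle=True, random_state=3)
        seen = np.zeros(len(table), dtype=int)
        for _, test in splitter.split(np.zeros((len(table), 1)), y):
            seen[test] += 1
        assert (seen == 1).all()

    def test_metrics_consistent_with_counts(self, rng):
        table = make_table(rng, sep=1.0)
        report = crossval_evaluate(table, ClassifierConfig("naive_bayes", seed=2))
        for _, r in report.records.iterrows():
            ref = metric_formulas(r.tp, r.tn, r.fp, r.fn)
            for name in ("accuracy", "precision", "sensitivity", "f1"):
                assert r[name] == pytest.approx(ref[name], abs=1e-12)

    def test_summary_recomputable_from_folds(self, rng):
        table = make_table(rng, sep=1.0)
        report = crossval_evaluate(table, ClassifierConfig("knn", seed=4))
        by_hand = report.records.groupby("class")["accuracy"].mean()
        for _, row in report.summary.iterrows():
            assert row["accuracy_mean"] == pytest.approx(
                by_hand[row["class"]], abs=1e-12
            )

    def test_deterministic_given_seed(self, rng):
        table = make_table(rng, sep=2.0)
        cfg = ClassifierConfig("adaboost", seed=5)
        a = crossval_evaluate(table, cfg)
        b = crossval_evaluate(table, cfg)
        assert a.records.equals(b.records)

    def test_permuted_labels_fall_to_majority_baseline(self, rng):
        """With labels shuffled, OVA accuracy reverts to the negative-class
        proportion (permutation baseline over 20 replicates)."""
        table = make_table(rng, n_per_class=40, sep=6.0, classes=("a", "b"))
        baseline = 0.5
        accs = []
        for rep in range(20):
            shuffled = table.copy()
            shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
            rep_report = crossval_evaluate(shuffled, ClassifierConfig("knn", seed=rep))
            accs.append(
                rep_report.records.query("`class` == 'a'")["accuracy"].mean()
            )
        accs = np.asarray(accs)
        assert abs(accs.mean() - baseline) <= 3 * accs.std(ddof=1)

    def test_subject_grouping_never_splits_a_subject(self, rng):
        from sklearn.model_selection import StratifiedGroupKFold

        table = make_table(rng, n_per_class=40)
        report = crossval_evaluate(
            table, ClassifierConfig("knn", seed=6), grouping="subject"
        )
        assert report.config["grouping"] == "subject"
        y = table["label"].to_numpy()
        groups = table["subject_id"].to_numpy()
        splitter = StratifiedGroupKFold(n_splits=10, shuffle=True, random_state=6)
        for train, test in splitter.split(np.zeros((len(table), 1)), y, groups):
            assert not set(groups[train]) & set(groups[test])

    def test_single_class_table_rejected(self, rng):
        table = make_table(rng, classes=("a",))
        with pytest.raises(StratificationError):
            crossval_evaluate(table, ClassifierConfig("knn"))

    def test_too_few_samples_per_class_rejected(self, rng):
        table = make_table(rng, n_per_class=5)
        with pytest.raises(StratificationError):
            crossval_evaluate(table, ClassifierConfig("knn"))

    def test_evaluate_all_runs_four_algorithms(self, rng):
        table = make_table(rng, n_per_class=20, sep=5.0)
        report = evaluate_all(table, ClassifierConfig(seed=7))
        assert set(report.records["algorithm"]) == {
            "knn", "naive_bayes", "svm_rbf", "adaboost",
        }
        pct = summary_percent(report)
        assert "±" in pct["accuracy"].iloc[0]
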