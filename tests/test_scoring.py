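import numpy as np
import pytest

from phagenn.scoring import (
    NOT_CLASSIFIED,
    ScoreReport,
    build_confidence_table,
    classify,
    ensemble_score,
    evaluate,
    reports_to_csv,
    score_reports,
)
from phagenn.seqio import ClassList

from .oracles import naive_metrics

CLASSES3 = ClassList(("A", "B", "C"))
CLASSES11 = ClassList()


def _random_softmax(rng, n_members, n_queries, n_classes):
    z = rng.random((n_members, n_queries, n_classes))
    return z / z.sum(axis=2, keepdims=True)


def _report(rid, scores, classes=CLASSES3):
    scores = np.asarray(scores, float)
    cls, top = classify(scores, classes)
    return ScoreReport(id=rid, scores=scores, predicted_class=cls, top_score=top)


class TestEnsembleScore:
    def test_identical_one_hot_members(self):
        m = np.zeros((10, 11))
        m[:, 3] = 1.0
        s = ensemble_score(m)
        assert s[3] == 10.0
        assert s.sum() == 10.0

    def test_uniform_members(self):
        m = np.full((10, 11), 1 / 11)
        np.testing.assert_allclose(ensemble_score(m), 10 / 11)

    def test_conservation_total_is_member_count(self):
        rng = np.random.default_rng(0)
        s = ensemble_score(_random_softmax(rng, 10, 7, 11))
        np.testing.assert_allclose(s.sum(axis=1), 10.0, atol=1e-9)
        assert (s >= 0).all() and (s <= 10).all()

    def test_non_softmax_input_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ensemble_score(np.ones((10, 11)))


class TestClassify:
    def test_unique_max(self):
        scores = np.zeros(11)
        scores[CLASSES11.index("Portal")] = 9.0
        cls, top = classify(scores, CLASSES11)
        assert cls == "Portal" and top == 9.0

    def test_abstain_below_threshold(self):
        scores = np.zeros(11)
        scores[2] = 4.9
        cls, top = classify(scores, CLASSES11, abstain_threshold=5.0)
        assert cls == NOT_CLASSIFIED and top == 4.9
        cls5, _ = classify(scores * (5.0 / 4.9), CLASSES11, abstain_threshold=5.0)
        assert cls5 != NOT_CLASSIFIED

    def test_tie_broken_by_class_order(self):
        cls, _ = classify(np.array([4.0, 4.0, 2.0]), CLASSES3)
        assert cls == "A"

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            classify(np.zeros(5), CLASSES3)


class TestConfidenceTable:
    def test_all_correct_gives_confidence_one(self):
        reports = [_report(f"q{i}", [8 - i * 0.5, 1, 1]) for i in range(4)]
        truth = {r.id: "A" for r in reports}
        table = build_confidence_table(reports, truth, CLASSES3)
        assert table.lookup("A", 6.0) == 1.0
        assert table.lookup("A", 0.0) == 1.0

    def test_lowest_threshold_equals_class_precision(self):
        # 3 predicted A (2 correct), 2 predicted B (1 correct)
        reports = [
            _report("a1", [7, 2, 1]), _report("a2", [6, 2, 2]), _report("a3", [5, 3, 2]),
            _report("b1", [2, 7, 1]), _report("b2", [1, 6, 3]),
        ]
        truth = {"a1": "A", "a2": "A", "a3": "B", "b1": "B", "b2": "C"}
        table = build_confidence_table(reports, truth, CLASSES3)
        assert table.lookup("A", 0.0) == pytest.approx(2 / 3)
        assert table.lookup("B", 0.0) == pytest.approx(1 / 2)

    def test_six_item_hand_enumeration(self):
        """Six test queries of class A at distinct scores; two errors.

        scores (desc): 9(correct), 8(correct), 7(WRONG), 6(correct),
                       5(WRONG), 4(correct)
        confidence(A, >=s): s<=4: 4/6; s in (4,5]: 3/5; (5,6]: 3/4;
                            (6,7]: 2/3; (7,8]: 2/2; (8,9]: 1/1
        """
        scores = [9, 8, 7, 6, 5, 4]
        correct = [True, True, False, True, False, True]
        reports = [_report(f"q{i}", [s, 0.5, 0.5]) for i, s in enumerate(scores)]
        truth = {f"q{i}": ("A" if ok else "B") for i, ok in enumerate(correct)}
        table = build_confidence_table(reports, truth, CLASSES3)
        assert table.lookup("A", 4.0) == pytest.approx(4 / 6)
        assert table.lookup("A", 5.0) == pytest.approx(3 / 5)
        assert table.lookup("A", 6.0) == pytest.approx(3 / 4)
        assert table.lookup("A", 7.0) == pytest.approx(2 / 3)
        assert table.lookup("A", 8.0) == pytest.approx(1.0)
        assert table.lookup("A", 9.0) == pytest.approx(1.0)
        # 6.5 falls on a grid point: scores >= 6.5 are {9, 8, 7}, 2 correct
        assert table.lookup("A", 6.5) == pytest.approx(2 / 3)

    def test_never_predicted_class_flagged(self):
        reports = [_report("a1", [7, 2, 1])]
        table = build_confidence_table(reports, {"a1": "A"}, CLASSES3)
        assert "C" in table.never_predicted
        assert table.lookup("C", 5.0) is None

    def test_corruption_never_raises_confidence(self):
        """Metamorphic: turning one correct high-score prediction into an
        error can only lower (or keep) confidence at thresholds at or
        below its score."""
        rng = np.random.default_rng(3)
        reports = [_report(f"q{i}", s)
                   for i, s in enumerate(rng.dirichlet([1, 1, 1], size=12) * 10)]
        truth = {r.id: r.predicted_class for r in reports}  # all correct
        table = build_confidence_table(reports, truth, CLASSES3)
        victim = max((r for r in reports if r.predicted_class == "A"),
                     key=lambda r: r.top_score)
        corrupted = dict(truth)
        corrupted[victim.id] = "B"
        table2 = build_confidence_table(reports, corrupted, CLASSES3)
        grid = np.arange(0, victim.top_score + 1e-9, 0.1)
        for s in grid:
            assert table2.lookup("A", s) <= table.lookup("A", s) + 1e-12

    def test_csv_roundtrip(self, tmp_path):
        reports = [_report("a1", [7, 2, 1]), _report("b1", [1, 8, 1])]
        truth = {"a1": "A", "b1": "B"}
        table = build_confidence_table(reports, truth, CLASSES3)
        table.to_csv(tmp_path / "conf.csv")
        from phagenn.scoring import ConfidenceTable
        back = ConfidenceTable.from_csv(tmp_path / "conf.csv", CLASSES3)
        for s in (0.0, 3.3, 7.0, 9.9):
            assert back.lookup("A", s) == pytest.approx(table.lookup("A", s))


def _toy_confusion_reports():
    """Reports realizing the confusion matrix [[5,0,0],[1,4,0],[0,2,3]]
    (rows = truth A,B,C; columns = prediction)."""
    matrix = {("A", "A"): 5, ("B", "A"): 1, ("B", "B"): 4,
              ("C", "B"): 2, ("C", "C"): 3}
    reports, truth = [], {}
    i = 0
    for (true_cls, pred_cls), n in matrix.items():
        for _ in range(n):
            scores = np.full(3, 0.5)
            scores[CLASSES3.index(pred_cls)] = 9.0
            reports.append(_report(f"q{i}", scores))
            truth[f"q{i}"] = true_cls
            i += 1
    return reports, truth


class TestEvaluate:
    def test_perfect_predictions(self):
        reports = [_report(f"q{i}", np.eye(3)[i % 3] * 10) for i in range(9)]
        truth = {r.id: r.predicted_class for r in reports}
        m = evaluate(reports, truth, CLASSES3)[0]
        assert m.accuracy == 1.0
        assert (m.per_class[["precision", "recall", "f1"]] == 1.0).all().all()

    def test_toy_confusion_hand_arithmetic(self):
        reports, truth = _toy_confusion_reports()
        m = evaluate(reports, truth, CLASSES3)[0]
        np.testing.assert_array_equal(m.confusion, [[5, 0, 0], [1, 4, 0], [0, 2, 3]])
        np.testing.assert_allclose(m.per_class["precision"], [5 / 6, 4 / 6, 1.0])
        np.testing.assert_allclose(m.per_class["recall"], [1.0, 0.8, 0.6])
        assert m.accuracy == pytest.approx(12 / 15)

    def test_accuracy_equals_weighted_recall(self):
        reports, truth = _toy_confusion_reports()
        m = evaluate(reports, truth, CLASSES3)[0]
        assert m.accuracy == pytest.approx(m.weighted["recall"])

    def test_row_normalized_confusion_rows_sum_to_one(self):
        reports, truth = _toy_confusion_reports()
        m = evaluate(reports, truth, CLASSES3)[0]
        np.testing.assert_allclose(m.confusion_normalized().sum(axis=1), 1.0)

    def test_f1_is_harmonic_mean(self):
        reports, truth = _toy_confusion_reports()
        m = evaluate(reports, truth, CLASSES3)[0]
        for _, row in m.per_class.iterrows():
            p, r = row["precision"], row["recall"]
            expected = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert row["f1"] == pytest.approx(expected)

    def test_cutoff_monotone_retention(self):
        rng = np.random.default_rng(4)
        reports = [_report(f"q{i}", s)
                   for i, s in enumerate(rng.dirichlet([1, 1, 1], size=30) * 10)]
        truth = {r.id: "A" for r in reports}
        cutoffs = [0.0, 3.0, 5.0, 7.0, 9.0]
        ms = evaluate(reports, truth, CLASSES3, score_cutoffs=cutoffs)
        fracs = [m.retained_fraction for m in ms]
        assert fracs == sorted(fracs, reverse=True)
        assert ms[0].retained_fraction == 1.0

    def test_empty_retained_set_flagged_not_fatal(self):
        reports = [_report("q0", [3, 3, 4])]
        m = evaluate(reports, {"q0": "C"}, CLASSES3, score_cutoffs=[9.9])[0]
        assert not m.defined
        assert np.isnan(m.accuracy)

    def test_agrees_with_counting_oracle_on_random_sets(self):
        rng = np.random.default_rng(7)
        labels = list(CLASSES3.names)
        for trial in range(50):
            n = int(rng.integers(5, 40))
            y_true = [labels[i] for i in rng.integers(0, 3, n)]
            y_pred = [labels[i] for i in rng.integers(0, 3, n)]
            reports = []
            truth = {}
            for i, (t, p) in enumerate(zip(y_true, y_pred)):
                scores = np.full(3, 0.1)
                scores[CLASSES3.index(p)] = 9.0
                reports.append(_report(f"q{i}", scores))
                truth[f"q{i}"] = t
            m = evaluate(reports, truth, CLASSES3)[0]
            oracle = naive_metrics(y_true, y_pred, labels)
            for cls in labels:
                row = m.per_class.loc[cls]
                assert row["precision"] == pytest.approx(oracle[cls]["precision"])
                assert row["recall"] == pytest.approx(oracle[cls]["recall"])
                assert row["f1"] == pytest.approx(oracle[cls]["f1"])
                assert row["support"] == oracle[cls]["support"]

    def test_roc_perfect_separation_has_unit_auc(self):
        reports = [_report("a", [9, 0.5, 0.5]), _report("b", [8, 1, 1]),
                   _report("c", [1, 8, 1]), _report("d", [1, 1, 8])]
        truth = {"a": "A", "b": "A", "c": "B", "d": "C"}
        m = evaluate(reports, truth, CLASSES3, compute_roc=True)[0]
        assert m.roc["A"]["auc"] == pytest.approx(1.0)


def test_score_reports_and_csv(tmp_path):
    rng = np.random.default_rng(1)
    softmax = _random_softmax(rng, 10, 3, 3)
    reports = score_reports(["x", "y", "z"], softmax, CLASSES3)
    assert [r.id for r in reports] == ["x", "y", "z"]
    for r in reports:
        assert r.scores.sum() == pytest.approx(10.0, abs=1e-5)
        assert r.predicted_class == CLASSES3.names[int(np.argmax(r.scores))]
    reports_to_csv(reports, CLASSES3, tmp_path / "pred.csv")
    import pandas as pd
    df = pd.read_csv(tmp_path / "pred.csv")
    assert list(df["id"]) == ["x", "y", "z"]
    score_cols = [f"score_{c}" for c in CLASSES3]
    np.testing.assert_allclose(df[score_cols].sum(axis=1), 10.0, atol=1e-5)
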