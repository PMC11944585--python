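"""Protocol and metric correctness, pinned by independent counting oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromoplate.classifier import (
    ClassProbabilities,
    ModelConfig,
    TrainingConfig,
)
from chromoplate.evaluation import (
    ConfusionMatrix,
    MetricsRow,
    PredictionRecord,
    confusion_from_predictions,
    make_folds,
    metrics_from_counts,
    one_vs_rest_binarize,
    reconstruct_counts,
    render_reports,
    roc_ovr,
    round_half_up,
    run_cross_validation,
    split_70_30,
    summarize_table,
)
from reference_table import BENCHMARK_AVERAGES, BENCHMARK_ROWS


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def item_level_counts(pairs, species):
    """Independent oracle: count TP/FN/FP/TN by walking (true, pred) items."""
    tp = sum(1 for t, p in pairs if t == species and p == species)
    fn = sum(1 for t, p in pairs if t == species and p != species)
    fp = sum(1 for t, p in pairs if t != species and p == species)
    tn = sum(1 for t, p in pairs if t != species and p != species)
    return tp, fn, fp, tn


def mann_whitney_auc(pos_scores, neg_scores):
    """Exhaustive pair oracle: P(pos > neg) + 0.5 P(tie)."""
    wins = ties = 0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_scores) * len(neg_scores))


def make_prediction(true_label, score_map, run=0, item_id=0):
    total = sum(score_map.values())
    return PredictionRecord(
        item_id=item_id,
        true_label=true_label,
        probabilities=ClassProbabilities(
            probabilities={k: v / total for k, v in score_map.items()}
        ),
        run=run,
    )


# ---------------------------------------------------------------------------
# splits / folds
# ---------------------------------------------------------------------------


class TestSplit7030:
    def test_balanced_120_gives_84_36_stratified(self):
        labels = [f"c{i % 4}" for i in range(120)]
        train, test = split_70_30(labels, seed=0)
        assert len(train) == 84 and len(test) == 36
        arr = np.array(labels)
        for cls in "c0 c1 c2 c3".split():
            assert (arr[train] == cls).sum() == 21
            assert (arr[test] == cls).sum() == 9

    def test_deterministic_and_disjoint(self):
        labels = ["a"] * 17 + ["b"] * 23
        t1 = split_70_30(labels, seed=5)
        t2 = split_70_30(labels, seed=5)
        assert np.array_equal(t1[0], t2[0]) and np.array_equal(t1[1], t2[1])
        assert set(t1[0]).isdisjoint(t1[1])
        assert set(t1[0]) | set(t1[1]) == set(range(40))


class TestMakeFolds:
    def test_269_items_fold_sizes(self):
        # ten roughly equal classes totalling 269, as in a ~27-per-species study
        sizes = [27, 27, 27, 27, 27, 27, 27, 27, 27, 26]
        labels = [f"s{i}" for i, n in enumerate(sizes) for _ in range(n)]
        folds = make_folds(labels, k=5, seed=0)
        fold_sizes = sorted(len(t) for t in folds.test_ids)
        assert fold_sizes == [53, 54, 54, 54, 54]

    def test_small_equal_folds(self):
        folds = make_folds(["a", "b"] * 5, k=5, seed=1)
        assert all(len(t) == 2 for t in folds.test_ids)

    def test_partition_properties(self):
        labels = [f"c{i % 3}" for i in range(31)]
        folds = make_folds(labels, k=5, seed=2)
        union = np.concatenate(folds.test_ids)
        assert sorted(union) == list(range(31))
        for tr, te in zip(folds.train_ids, folds.test_ids):
            assert set(tr).isdisjoint(te)
            assert len(tr) + len(te) == 31
        # stratified: every class appears in every fold's test set
        arr = np.array(labels)
        for te in folds.test_ids:
            assert set(arr[te]) == {"c0", "c1", "c2"}

    def test_k_larger_than_n_rejected_small_class_warns(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_folds(["a", "b"], k=5, seed=0)
        with pytest.warns(UserWarning, match="fewer than"):
            make_folds(["a"] * 3 + ["b"] * 17, k=5, seed=0)


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        pairs = [("a", "a")] * 3 + [("b", "b")] * 2
        cm = confusion_from_predictions(pairs, ["a", "b"])
        np.testing.assert_array_equal(cm.matrix, [[3, 0], [0, 2]])

    def test_direct_count_example(self):
        pairs = [("A", "A"), ("A", "B"), ("B", "B")]
        cm = confusion_from_predictions(pairs, ["A", "B"])
        # rows = predicted, columns = actual
        assert cm.matrix[0, 0] == 1  # pred A, actual A
        assert cm.matrix[1, 0] == 1  # pred B, actual A
        assert cm.matrix[1, 1] == 1  # pred B, actual B
        assert cm.matrix[0, 1] == 0

    def test_column_sums_are_per_class_truth_counts(self):
        rng = np.random.default_rng(0)
        labels = ["x", "y", "z"]
        pairs = [(labels[rng.integers(3)], labels[rng.integers(3)])
                 for _ in range(200)]
        cm = confusion_from_predictions(pairs, labels)
        for j, lab in enumerate(labels):
            assert cm.matrix[:, j].sum() == sum(1 for t, _ in pairs if t == lab)
        assert cm.total == 200

    def test_sum_of_run_matrices_equals_pooled(self):
        rng = np.random.default_rng(1)
        labels = ["x", "y"]
        runs = [
            [(labels[rng.integers(2)], labels[rng.integers(2)]) for _ in range(30)]
            for _ in range(5)
        ]
        summed = confusion_from_predictions(runs[0], labels)
        for r in runs[1:]:
            summed = summed + confusion_from_predictions(r, labels)
        pooled = confusion_from_predictions([p for r in runs for p in r], labels)
        np.testing.assert_array_equal(summed.matrix, pooled.matrix)

    def test_column_normalized_percentages(self):
        cm = ConfusionMatrix(np.array([[3, 1], [1, 4]]), ["a", "b"])
        pct = cm.column_normalized()
        np.testing.assert_allclose(pct[:, 0], [75.0, 25.0])
        np.testing.assert_allclose(pct[:, 1], [20.0, 80.0])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion_from_predictions([("a", "q")], ["a", "b"])


class TestOneVsRest:
    def test_perfect_two_class(self):
        cm = ConfusionMatrix(np.array([[5, 0], [0, 7]]), ["a", "b"])
        tp, fn, fp, tn = one_vs_rest_binarize(cm, "a")
        assert (tp, fn, fp, tn) == (5, 0, 0, 7)

    def test_hand_counted_example(self):
        # rows pred, cols actual over 10 items
        cm = ConfusionMatrix(np.array([[3, 1], [2, 4]]), ["c0", "c1"])
        assert one_vs_rest_binarize(cm, "c0") == (3, 2, 1, 4)

    def test_counts_sum_invariant_across_species(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(0, 9, (4, 4))
        cm = ConfusionMatrix(mat, list("wxyz"))
        for s in "wxyz":
            assert sum(one_vs_rest_binarize(cm, s)) == cm.total

    def test_unknown_species_rejected(self):
        cm = ConfusionMatrix(np.zeros((2, 2), dtype=int), ["a", "b"])
        with pytest.raises(ValueError, match="unknown"):
            one_vs_rest_binarize(cm, "zz")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


class TestMetricsFromCounts:
    def test_benchmark_consistent_counts(self):
        """Counts (5, 0, 1, 203) reproduce a published near-perfect row."""
        row = metrics_from_counts(5, 0, 1, 203)
        assert row.sensitivity == pytest.approx(100.0)
        assert row.specificity == pytest.approx(99.51, abs=0.005)
        assert row.accuracy == pytest.approx(99.52, abs=0.005)
        assert row.ppv == pytest.approx(83.33, abs=0.005)
        assert row.npv == pytest.approx(100.0)
        assert round_half_up(row.f1) == 0.91
        assert round_half_up(row.mcc) == 0.91

    def test_perfect_classifier(self):
        row = metrics_from_counts(10, 0, 0, 90)
        for attr in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            assert getattr(row, attr) == pytest.approx(100.0)
        assert row.f1 == pytest.approx(1.0)
        assert row.mcc == pytest.approx(1.0)

    def test_f1_from_published_ppv_and_sensitivity(self):
        # PPV 53.85%, sensitivity 20.00% -> F1 0.29 at 2 dp
        row = metrics_from_counts(20, 80, 17137, 100000)  # any counts w/ right rates
        assert row.sensitivity == pytest.approx(20.0)
        f1 = 2 * 0.5385 * 0.20 / (0.5385 + 0.20)
        assert round_half_up(f1) == 0.29

    def test_zero_denominators_flagged_undefined_not_zero(self):
        row = metrics_from_counts(0, 0, 3, 7)  # no actual positives
        assert row.sensitivity is None
        assert row.npv == pytest.approx(100.0)  # TN/(TN+FN) = 7/7
        assert row.specificity == pytest.approx(70.0)
        assert row.mcc is None
        row = metrics_from_counts(0, 5, 0, 5)  # nothing predicted positive
        assert row.ppv is None and row.f1 is None

    def test_negative_or_fractional_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_counts(-1, 0, 0, 5)
        with pytest.raises(ValueError):
            metrics_from_counts(0, 0, 0, 0)

    def test_fuzzed_matrices_match_item_counting_oracle(self):
        """1000 random confusion matrices: binarize+metrics must agree with
        an item-by-item counting oracle on every species."""
        rng = np.random.default_rng(3)
        for _ in range(1000):
            k = int(rng.integers(2, 6))
            labels = [f"s{i}" for i in range(k)]
            mat = rng.integers(0, 7, (k, k))
            if mat.sum() == 0:
                continue
            cm = ConfusionMatrix(mat, labels)
            pairs = [
                (labels[a], labels[p])
                for p in range(k)
                for a in range(k)
                for _ in range(mat[p, a])
            ]
            s = labels[int(rng.integers(k))]
            counts = one_vs_rest_binarize(cm, s)
            assert counts == item_level_counts(pairs, s)
            row = metrics_from_counts(*counts)
            tp, fn, fp, tn = counts
            if tp + fn:
                assert row.sensitivity == pytest.approx(100 * tp / (tp + fn))
            if tn + fp:
                assert row.specificity == pytest.approx(100 * tn / (tn + fp))
            assert row.accuracy == pytest.approx(100 * (tp + tn) / mat.sum())

    @given(tp=st.integers(0, 50), fn=st.integers(0, 50),
           fp=st.integers(0, 50), tn=st.integers(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_mcc_symmetric_under_tp_tn_fp_fn_swap(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        a = metrics_from_counts(tp, fn, fp, tn).mcc
        b = metrics_from_counts(tn, fp, fn, tp).mcc
        if a is None or b is None:
            assert a is None and b is None
        else:
            assert a == pytest.approx(b, abs=1e-12)

    @given(tp=st.integers(1, 50), fn=st.integers(0, 50),
           fp=st.integers(0, 50), tn1=st.integers(0, 50), tn2=st.integers(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_f1_invariant_to_tn(self, tp, fn, fp, tn1, tn2):
        a = metrics_from_counts(tp, fn, fp, tn1).f1
        b = metrics_from_counts(tp, fn, fp, tn2).f1
        assert a == pytest.approx(b, abs=1e-12)


class TestReconstructCounts:
    @pytest.mark.parametrize("species", list(BENCHMARK_ROWS))
    def test_benchmark_rows_internally_consistent(self, species):
        """Every published row is reproducible from integer counts: some
        non-negative (TP, FN, FP, TN) yields all seven printed values."""
        vals = BENCHMARK_ROWS[species]
        row = MetricsRow(species, *vals)
        counts = reconstruct_counts(row)
        assert counts is not None, f"no consistent counts for {species}"
        rec = metrics_from_counts(*counts)
        assert round_half_up(rec.mcc) == pytest.approx(vals[6], abs=0.011)
        assert round_half_up(rec.f1) == pytest.approx(vals[5], abs=0.011)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


class TestROC:
    def _preds(self, pos_scores, neg_scores):
        preds = []
        for i, s in enumerate(pos_scores):
            preds.append(make_prediction("P", {"P": s, "N": 1 - s}, item_id=i))
        for i, s in enumerate(neg_scores):
            preds.append(make_prediction("N", {"P": s, "N": 1 - s},
                                         item_id=100 + i))
        return preds

    def test_perfect_separation_auc_1(self):
        roc = roc_ovr(self._preds([0.9, 0.8], [0.4, 0.2]), "P")
        assert roc.auc == pytest.approx(1.0)

    def test_brute_force_pair_example(self):
        # pairs: (.9>.8, .9>.2, .4<.8, .4>.2) -> 3/4
        roc = roc_ovr(self._preds([0.9, 0.4], [0.8, 0.2]), "P")
        assert roc.auc == pytest.approx(0.75)

    def test_constant_scores_auc_half(self):
        roc = roc_ovr(self._preds([0.5, 0.5], [0.5, 0.5, 0.5]), "P")
        assert roc.auc == pytest.approx(0.5)

    def test_curve_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(4)
        roc = roc_ovr(
            self._preds(rng.random(20).tolist(), rng.random(30).tolist()), "P"
        )
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    def test_species_absent_flagged_undefined(self):
        roc = roc_ovr(self._preds([0.9], [0.1]), "QQ")
        assert not roc.defined and roc.auc is None

    @given(
        pos=st.lists(st.integers(0, 10).map(lambda v: v / 10), min_size=1,
                     max_size=25),
        neg=st.lists(st.integers(0, 10).map(lambda v: v / 10), min_size=1,
                     max_size=25),
    )
    @settings(max_examples=150, deadline=None)
    def test_auc_equals_mann_whitney_pair_statistic(self, pos, neg):
        """Trapezoidal AUC == exhaustive pair statistic on all inputs
        up to 50 items (ties counted one half)."""
        roc = roc_ovr(self._preds(pos, neg), "P")
        assert roc.auc == pytest.approx(mann_whitney_auc(pos, neg), abs=1e-9)


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------


class TestSummarizeTable:
    def test_benchmark_bottom_line_averages(self):
        rows = [MetricsRow(s, *v) for s, v in BENCHMARK_ROWS.items()]
        table = summarize_table(rows)
        avg = table.iloc[-1]
        assert avg["species"] == "Average results"
        printed = dict(zip(
            ["sensitivity", "specificity", "accuracy", "ppv", "npv", "f1", "mcc"],
            BENCHMARK_AVERAGES,
        ))
        for col, val in printed.items():
            assert avg[col] == pytest.approx(val, abs=0.005), col

    def test_single_row_average_is_that_row(self):
        row = MetricsRow("only", 80.0, 90.0, 85.0, 70.0, 95.0, 0.746, 0.7)
        table = summarize_table([row])
        assert table.iloc[1]["sensitivity"] == 80.0
        assert table.iloc[1]["f1"] == 0.75  # rounded half-up

    def test_undefined_entries_skipped_with_warning(self):
        rows = [
            MetricsRow("a", 80.0, 90.0, 85.0, 70.0, 95.0, 0.75, 0.7),
            MetricsRow("b", None, 90.0, 85.0, 70.0, 95.0, None, 0.7),
        ]
        with pytest.warns(UserWarning, match="undefined"):
            table = summarize_table(rows)
        assert table.iloc[-1]["sensitivity"] == 80.0

    def test_rounding_is_half_up(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(65.285, 2) == 65.29
        assert round_half_up(-0.125, 2) == -0.13


# ---------------------------------------------------------------------------
# cross-validation (fast, tiny configuration)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def cv_results(color_arrays):
    x, y = color_arrays
    labels = [f"sp{i}" for i in range(4)]

    class ArrayDataset:
        def all_items(self):
            return [(f"img{i}", labels[yi]) for i, yi in enumerate(y)]

        def load_arrays(self):
            return x, y

    ds = ArrayDataset()
    ds.labels = labels
    folds = make_folds([labels[yi] for yi in y], k=5, seed=0)
    results = run_cross_validation(
        ds,
        ModelConfig(n_classes=4),
        TrainingConfig(epochs=4, seed=0),
        folds,
        arrays=(x, y),
    )
    return results, len(y)


class TestCrossValidation:
    def test_five_histories(self, cv_results):
        results, _ = cv_results
        assert len(results) == 5
        assert all(r.history is not None and r.error is None for r in results)

    def test_every_image_classified_exactly_once(self, cv_results):
        results, n = cv_results
        ids = [p.item_id for r in results for p in r.predictions]
        assert sorted(ids) == list(range(n))

    def test_confusion_conservation(self, cv_results):
        results, n = cv_results
        pooled = [p for r in results for p in r.predictions]
        cm = confusion_from_predictions(pooled, [f"sp{i}" for i in range(4)])
        assert cm.total == n
        for s in cm.labels:
            assert sum(one_vs_rest_binarize(cm, s)) == n

    def test_failed_run_recorded_not_raised(self, color_arrays):
        x, y = color_arrays

        class BadDataset:
            labels = ["a", "b", "c", "d"]

            def load_arrays(self):
                return x, y

        folds = make_folds([str(v) for v in y], k=2, seed=0)
        results = run_cross_validation(
            BadDataset(),
            ModelConfig(n_classes=3),  # class mismatch -> failure per run
            TrainingConfig(epochs=1, seed=0),
            folds,
        )
        assert all(r.error is not None for r in results)


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------


class TestRenderReports:
    def test_artifacts_written(self, tmp_path):
        from chromoplate.classifier import TrainingHistory

        histories = [
            TrainingHistory(
                accuracy=[0.3, 0.6], loss=[1.2, 0.8],
                val_accuracy=[0.25, 0.5], val_loss=[1.3, 0.9],
            )
            for _ in range(5)
        ]
        cm = ConfusionMatrix(np.array([[8, 2], [1, 9]]), ["a", "b"])
        rows = [
            metrics_from_counts(*one_vs_rest_binarize(cm, s), species=s)
            for s in cm.labels
        ]
        preds = (
            [make_prediction("a", {"a": 0.8, "b": 0.2}, item_id=i)
             for i in range(5)]
            + [make_prediction("b", {"a": 0.3, "b": 0.7}, item_id=10 + i)
               for i in range(5)]
        )
        rocs = [roc_ovr(preds, s) for s in cm.labels]
        paths = render_reports(histories, cm, summarize_table(rows), rocs, tmp_path)
        for key in ("curves", "heatmap", "roc", "metrics"):
            assert paths[key].exists() and paths[key].stat().st_size > 0
        table = pd.read_csv(paths["metrics"])
        assert list(table.columns) == [
            "species", "sensitivity", "specificity", "accuracy",
            "ppv", "npv", "f1", "mcc",
        ]
        assert len(table) == 3  # 2 species + average row
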