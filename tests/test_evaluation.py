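"""Metric closed forms, split discipline and the benchmark loop."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score, matthews_corrcoef, roc_auc_score

from snare_profiler import CorpusSpec, build_matrix, random_corpus
from snare_profiler.evaluation import (
    ClassifierSpec,
    ConfusionCounts,
    HOLDOUT_PRESETS,
    KFOLD_PRESETS,
    accuracy,
    confusion,
    make_split_plan,
    mcc,
    pr_auc,
    roc_auc,
    run_benchmark,
    run_grid,
    sensitivity,
    specificity,
)
from snare_profiler.sampling_balance import SamplingSpec


class TestConfusion:
    def test_perfect_prediction(self):
        labels = ["SNARE"] * 4 + ["NON_SNARE"] * 6
        counts = confusion(labels, labels, positive="SNARE")
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (4, 6, 0, 0)

    def test_all_flipped(self):
        labels = ["SNARE"] * 4 + ["NON_SNARE"] * 6
        flipped = ["NON_SNARE"] * 4 + ["SNARE"] * 6
        counts = confusion(labels, flipped, positive="SNARE")
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (0, 0, 6, 4)

    def test_mixed_hand_tally(self):
        labels = ["SNARE", "SNARE", "SNARE", "NON_SNARE", "NON_SNARE",
                  "NON_SNARE", "SNARE", "NON_SNARE", "NON_SNARE", "SNARE"]
        preds = ["SNARE", "NON_SNARE", "SNARE", "NON_SNARE", "SNARE",
                 "NON_SNARE", "SNARE", "NON_SNARE", "SNARE", "NON_SNARE"]
        counts = confusion(labels, preds, positive="SNARE")
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (3, 3, 2, 2)
        assert counts.total == 10

    def test_third_label_rejected(self):
        with pytest.raises(ValueError, match="two"):
            confusion(["SNARE", "other", "NON_SNARE"], ["SNARE"] * 3, positive="SNARE")


class TestScalarMetrics:
    def test_worked_example(self):
        c = ConfusionCounts(tp=90, tn=95, fp=5, fn=10)
        assert accuracy(c) == pytest.approx(0.925)
        assert sensitivity(c) == pytest.approx(0.90)
        assert specificity(c) == pytest.approx(0.95)

    def test_sensitivity_half_when_tp_equals_fn(self):
        assert sensitivity(ConfusionCounts(tp=7, tn=1, fp=1, fn=7)) == 0.5

    def test_specificity_boundary(self):
        assert specificity(ConfusionCounts(tp=1, tn=5, fp=0, fn=1)) == 1.0

    def test_zero_denominators_flagged_as_nan(self):
        assert math.isnan(sensitivity(ConfusionCounts(tp=0, tn=5, fp=2, fn=0)))
        assert math.isnan(specificity(ConfusionCounts(tp=3, tn=0, fp=0, fn=1)))

    def test_mcc_perfect_and_null(self):
        assert mcc(ConfusionCounts(tp=10, tn=10, fp=0, fn=0)) == 1.0
        assert mcc(ConfusionCounts(tp=25, tn=25, fp=25, fn=25)) == 0.0

    def test_mcc_worked_example(self):
        value = mcc(ConfusionCounts(tp=50, tn=40, fp=10, fn=0))
        assert value == pytest.approx(2000 / math.sqrt(60 * 50 * 50 * 40))
        assert value == pytest.approx(0.8165, abs=5e-5)

    def test_mcc_zero_marginal_convention(self):
        assert mcc(ConfusionCounts(tp=0, tn=10, fp=0, fn=5)) == 0.0

    counts = st.integers(0, 30)

    @given(tp=counts, tn=counts, fp=counts, fn=counts)
    @settings(max_examples=100, derandomize=True)
    def test_mcc_class_symmetry_range_and_sklearn_agreement(self, tp, tn, fp, fn):
        c = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        swapped = ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp)
        assert mcc(c) == pytest.approx(mcc(swapped))
        assert -1 <= mcc(c) <= 1
        if c.total and min(tp + fp, tp + fn, tn + fp, tn + fn) > 0:
            y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
            y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
            assert mcc(c) == pytest.approx(matthews_corrcoef(y_true, y_pred))

    @given(tp=counts, tn=counts, fp=counts, fn=counts)
    @settings(max_examples=60, derandomize=True)
    def test_acc_sn_sp_linkage_identity(self, tp, tn, fp, fn):
        c = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        P, N = tp + fn, tn + fp
        if P == 0 or N == 0:
            return
        assert accuracy(c) * (P + N) == pytest.approx(sensitivity(c) * P + specificity(c) * N, abs=1e-9)


class TestRankingMetrics:
    def test_perfect_separation(self):
        labels = [1, 1, 0, 0]
        assert roc_auc(labels, [0.9, 0.8, 0.2, 0.1], positive=1) == 1.0

    def test_three_of_four_concordant(self):
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1], positive=1) == 0.75

    def test_all_ties_give_half(self):
        assert roc_auc([1, 0, 1, 0], [0.5] * 4, positive=1) == 0.5

    def test_single_class_undefined(self):
        assert math.isnan(roc_auc([1, 1], [0.2, 0.3], positive=1))
        assert math.isnan(pr_auc([0, 0], [0.2, 0.3], positive=1))

    @given(
        n=st.integers(4, 20),
        seed=st.integers(0, 10_000),
        tie_grid=st.sampled_from([None, 4]),
    )
    @settings(max_examples=80, derandomize=True)
    def test_concordance_equals_trapezoidal_roc(self, n, seed, tie_grid):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, dtype=int)
        labels[: n // 2] = 1
        rng.shuffle(labels)
        scores = rng.random(n)
        if tie_grid:
            scores = np.round(scores * tie_grid) / tie_grid
        if labels.sum() in (0, n):
            return
        assert roc_auc(labels, scores, positive=1) == pytest.approx(
            roc_auc_score(labels, scores)
        )

    @given(n=st.integers(4, 20), seed=st.integers(0, 10_000))
    @settings(max_examples=60, derandomize=True)
    def test_pr_step_curve_equals_average_precision(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = (rng.random(n) < 0.5).astype(int)
        scores = np.round(rng.random(n) * 5) / 5
        if labels.sum() in (0, n):
            return
        assert pr_auc(labels, scores, positive=1) == pytest.approx(
            average_precision_score(labels, scores)
        )


class TestSplitPlans:
    def test_kfold_partitions_all_records(self):
        labels = np.array(["SNARE"] * 50 + ["NON_SNARE"] * 50)
        plan = make_split_plan(labels, "kfold", 10, seed=1)
        assert plan.n_folds == 10
        validation = np.concatenate([va for _, va in plan.folds])
        assert sorted(validation) == list(range(100))
        for tr, va in plan.folds:
            assert len(va) == 10
            assert not set(tr) & set(va)
            assert sorted(np.concatenate([tr, va])) == list(range(100))

    def test_stratification_keeps_class_ratio(self):
        labels = np.array(["SNARE"] * 30 + ["NON_SNARE"] * 90)
        plan = make_split_plan(labels, "kfold", 10, seed=0)
        for _, va in plan.folds:
            assert (labels[va] == "SNARE").sum() == 3

    def test_holdout_sizes(self):
        labels = np.array(["SNARE"] * 5 + ["NON_SNARE"] * 5)
        plan = make_split_plan(labels, "holdout", 0.2, seed=0)
        (train, val), = plan.folds
        assert len(val) == 2 and len(train) == 8

    def test_same_seed_same_plan(self):
        labels = np.array(["SNARE"] * 20 + ["NON_SNARE"] * 20)
        a = make_split_plan(labels, "kfold", 5, seed=7)
        b = make_split_plan(labels, "kfold", 5, seed=7)
        for (tra, vaa), (trb, vab) in zip(a.folds, b.folds):
            assert (tra == trb).all() and (vaa == vab).all()

    def test_presets_match_the_benchmark_grid(self):
        assert KFOLD_PRESETS == tuple(range(10, 101, 10))
        assert HOLDOUT_PRESETS == tuple(f / 100 for f in range(20, 81, 10))

    def test_invalid_parameters_rejected(self):
        labels = np.array(["SNARE"] * 5 + ["NON_SNARE"] * 5)
        with pytest.raises(ValueError):
            make_split_plan(labels, "kfold", 11)
        with pytest.raises(ValueError):
            make_split_plan(labels, "holdout", 1.2)
        with pytest.raises(ValueError):
            make_split_plan(labels, "bootstrap", 3)


class TestClassifierSpec:
    def test_defaults(self):
        assert ClassifierSpec("rf").parameters == {"n_trees": 100}
        assert ClassifierSpec("knn").parameters == {"n_neighbors": 1}
        assert ClassifierSpec("ada").parameters == {"n_iterations": 10, "weight_threshold": 100}

    def test_knn_normalizes_by_default_trees_do_not(self):
        assert ClassifierSpec("knn").normalizes_by_default
        assert not ClassifierSpec("rf").normalizes_by_default
        assert not ClassifierSpec("ada").normalizes_by_default

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            ClassifierSpec("svm")


@pytest.fixture(scope="module")
def separable_matrix():
    """Two Gaussian clouds at large separation, as a feature matrix."""
    from snare_profiler.feature_extraction import FeatureMatrix

    rng = np.random.default_rng(0)
    n = 60
    X = np.vstack([rng.normal(0, 1, (n, 4)), rng.normal(8, 1, (n, 4))])
    y = ["SNARE"] * n + ["NON_SNARE"] * n
    frame = pd.DataFrame(X, index=pd.Index([f"r{i}" for i in range(2 * n)], name="id"))
    frame.columns = [f"f{j}" for j in range(4)]
    return FeatureMatrix(X=frame, y=pd.Series(y, index=frame.index, name="label"))


class TestRunBenchmark:
    @pytest.mark.parametrize("algo", ["rf", "knn", "ada"])
    def test_separable_clouds_are_learned(self, separable_matrix, algo):
        plan = make_split_plan(separable_matrix.y.to_numpy(), "kfold", 10, seed=0)
        report = run_benchmark(separable_matrix, ClassifierSpec(algo), plan)
        assert report.means["acc"] >= 0.95
        assert report.means["auc"] >= 0.95

    def test_report_is_deterministic(self, gaac_matrix):
        plan = make_split_plan(gaac_matrix.y.to_numpy(), "kfold", 5, seed=3)
        spec = ClassifierSpec("rf")
        a = run_benchmark(gaac_matrix, spec, plan)
        b = run_benchmark(gaac_matrix, spec, plan)
        pd.testing.assert_frame_equal(a.fold_metrics, b.fold_metrics)
        assert a.means == b.means

    def test_fold_metrics_within_ranges_and_means_match(self, gaac_matrix):
        plan = make_split_plan(gaac_matrix.y.to_numpy(), "kfold", 5, seed=3)
        report = run_benchmark(gaac_matrix, ClassifierSpec("knn"), plan)
        fm = report.fold_metrics
        for name in ("acc", "sn", "sp", "auc", "auprc"):
            defined = fm[name].dropna()
            assert ((defined >= 0) & (defined <= 1)).all()
            assert report.means[name] == pytest.approx(defined.mean())
            assert report.n_defined[name] == len(defined)
        assert ((fm["mcc"].dropna() >= -1) & (fm["mcc"].dropna() <= 1)).all()

    def test_linkage_identity_per_fold(self, gaac_matrix):
        plan = make_split_plan(gaac_matrix.y.to_numpy(), "kfold", 4, seed=1)
        report = run_benchmark(gaac_matrix, ClassifierSpec("rf"), plan)
        for row in report.fold_metrics.itertuples():
            P, N = row.tp + row.fn, row.tn + row.fp
            assert row.acc * (P + N) == pytest.approx(row.sn * P + row.sp * N, abs=1e-9)

    def test_training_fold_balancing_changes_training_size_only(self, separable_matrix):
        # drop most positives to create imbalance
        keep = separable_matrix.y[separable_matrix.y == "SNARE"].index[:15].tolist()
        keep += separable_matrix.y[separable_matrix.y == "NON_SNARE"].index.tolist()
        from snare_profiler.feature_extraction import FeatureMatrix

        matrix = FeatureMatrix(
            X=separable_matrix.X.loc[keep], y=separable_matrix.y.loc[keep]
        )
        plan = make_split_plan(matrix.y.to_numpy(), "kfold", 5, seed=0)
        balanced = run_benchmark(
            matrix, ClassifierSpec("rf"), plan, sampling=SamplingSpec(mode="oversample", seed=0)
        )
        plain = run_benchmark(matrix, ClassifierSpec("rf"), plan)
        assert (balanced.fold_metrics["n_val"] == plain.fold_metrics["n_val"]).all()
        assert (balanced.fold_metrics["n_train"] > plain.fold_metrics["n_train"]).all()


class TestRunGrid:
    def test_product_size_and_naming(self, gaac_matrix, small_corpus):
        records, labels = small_corpus
        matrices = {
            "gaac": gaac_matrix,
            "gaac.ext": build_matrix(records, labels, "gaac.ext"),
        }
        table = run_grid(matrices, [ClassifierSpec("knn")], [("kfold", 4)], seed=0)
        assert table["cell"].nunique() == 2
        assert set(table["feature_class"]) == {"gaac", "gaac.ext"}
        # one row per cell per fold per metric
        assert len(table) == 2 * 4 * 6

    def test_rerun_identical(self, gaac_matrix):
        matrices = {"gaac": gaac_matrix}
        a = run_grid(matrices, [ClassifierSpec("knn")], [("kfold", 4)], seed=5)
        b = run_grid(matrices, [ClassifierSpec("knn")], [("kfold", 4)], seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_checkpoint_resume_skips_done_cells(self, gaac_matrix, tmp_path):
        matrices = {"gaac": gaac_matrix}
        path = tmp_path / "grid.csv"
        first = run_grid(matrices, [ClassifierSpec("knn")], [("kfold", 4)], seed=5, checkpoint_path=path)
        resumed = run_grid(
            matrices,
            [ClassifierSpec("knn"), ClassifierSpec("rf")],
            [("kfold", 4)],
            seed=5,
            checkpoint_path=path,
        )
        assert resumed["cell"].nunique() == 2
        knn_cell = first[first["algorithm"] == "knn"]
        resumed_knn = resumed[resumed["algorithm"] == "knn"].reset_index(drop=True)
        pd.testing.assert_frame_equal(knn_cell, resumed_knn, check_dtype=False)
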