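import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mthvr.evaluation import (
    ConfusionTable,
    ExperimentResult,
    PipelineSpec,
    confusion_table,
    cross_validate,
    deletion_scan,
    holdout_evaluate,
    macro_accuracy,
    micro_accuracy,
    render_result_tsv,
    render_scan_tsv,
    window_scan,
)
from mthvr._folds import stratified_fold_ids
from mthvr.profile_io import ProfileDataset, ValidationError
from mthvr.synthetic_data import SyntheticConfig, generate_dataset, make_biased_split
from .conftest import make_sample

FAST_SVM = dict(classifier="svm", k=5, C=10.0, gamma=0.1)


def table_from_per_class(accuracies, sizes, extra_pred=()):
    """Build label lists realizing given per-class accuracies and sizes."""
    classes = [f"c{i}" for i in range(len(sizes))]
    true_labels, pred_labels = [], []
    for i, (acc, n) in enumerate(zip(accuracies, sizes)):
        correct = round(acc * n / 100.0)
        wrong_target = classes[(i + 1) % len(classes)]
        true_labels += [classes[i]] * n
        pred_labels += [classes[i]] * correct + [wrong_target] * (n - correct)
    return confusion_table(
        true_labels, pred_labels, class_order=classes + list(extra_pred)
    )


class TestMetrics:
    def test_independent_test_micro(self):
        # printed per-class accuracies and sizes of the published-test confusion
        ct = table_from_per_class([92.59, 67.78, 87.31], [1956, 450, 134],
                                  extra_pred=["hispanic"])
        assert round(micro_accuracy(ct), 2) == 87.91

    def test_independent_test_macro(self):
        ct = table_from_per_class([92.59, 67.78, 87.31], [1956, 450, 134])
        assert round(macro_accuracy(ct), 2) == 82.56

    def test_cv_1nn_column_micro(self):
        ct = table_from_per_class(
            [93.73, 83.31, 86.59, 72.01], [1674, 761, 1305, 686]
        )
        assert round(micro_accuracy(ct), 2) == 86.47

    def test_cv_1nn_column_macro(self):
        ct = table_from_per_class(
            [93.73, 83.31, 86.59, 72.01], [1674, 761, 1305, 686]
        )
        assert round(macro_accuracy(ct), 2) == 83.91

    def test_all_correct_is_100(self):
        ct = confusion_table(["a", "b"], ["a", "b"], ["a", "b"])
        assert micro_accuracy(ct) == 100.0
        assert macro_accuracy(ct) == 100.0

    def test_balanced_classes_micro_equals_macro(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 5))
            n = int(rng.integers(3, 10))
            classes = [f"c{i}" for i in range(k)]
            true_labels, pred_labels = [], []
            for cls in classes:
                true_labels += [cls] * n
                pred_labels += rng.choice(classes, size=n).tolist()
            ct = confusion_table(true_labels, pred_labels, classes)
            assert micro_accuracy(ct) == pytest.approx(macro_accuracy(ct))

    def test_half_correct_macro(self):
        ct = table_from_per_class([100.0, 0.0], [7, 3])
        assert macro_accuracy(ct) == 50.0

    def test_empty_table_error(self):
        ct = ConfusionTable(("a",), ("a",), np.zeros((1, 1), dtype=int))
        with pytest.raises(ValueError):
            micro_accuracy(ct)

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_metrics_match_brute_force_recount(self, data):
        k = data.draw(st.integers(2, 4))
        classes = [f"c{i}" for i in range(k)]
        n = data.draw(st.integers(k, 40))
        true_labels = [classes[i % k] for i in range(n)]
        pred_labels = data.draw(
            st.lists(st.sampled_from(classes), min_size=n, max_size=n)
        )
        ct = confusion_table(true_labels, pred_labels, classes)
        correct = sum(1 for t, p in zip(true_labels, pred_labels) if t == p)
        assert micro_accuracy(ct) == pytest.approx(100.0 * correct / n)
        per_class = []
        for cls in classes:
            idx = [i for i, t in enumerate(true_labels) if t == cls]
            per_class.append(
                100.0 * sum(1 for i in idx if pred_labels[i] == cls) / len(idx)
            )
        assert macro_accuracy(ct) == pytest.approx(np.mean(per_class))


class TestConfusionTable:
    def test_perfect_predictions_diagonal(self):
        ct = confusion_table(["a", "b", "a"], ["a", "b", "a"], ["a", "b"])
        np.testing.assert_array_equal(ct.counts, [[2, 0], [0, 1]])

    def test_partial(self):
        ct = confusion_table(["a", "a"], ["a", "b"], ["a", "b"])
        assert ct.class_sizes.tolist() == [2]
        assert ct.correct_counts.tolist() == [1]

    def test_extra_predicted_class_column(self):
        ct = confusion_table(["a", "a"], ["a", "x"], ["a", "x"])
        assert ct.true_classes == ("a",)
        assert ct.pred_classes == ("a", "x")

    def test_unknown_label_error(self):
        with pytest.raises(ValueError):
            confusion_table(["a"], ["z"], ["a", "b"])

    def test_row_percentages_recount(self, rng):
        counts = rng.integers(1, 20, size=(3, 3))
        ct = ConfusionTable(("a", "b", "c"), ("a", "b", "c"), counts)
        perc = ct.row_percentages()
        for i in range(3):
            for j in range(3):
                assert perc[i, j] == pytest.approx(
                    100.0 * counts[i, j] / counts[i].sum()
                )


class TestFolds:
    def test_fold_sizes_differ_by_at_most_one(self):
        labels = ["x"] * 4426
        fold_ids = stratified_fold_ids(labels, 5, seed=0)
        sizes = sorted(np.bincount(fold_ids).tolist(), reverse=True)
        assert sizes == [886, 885, 885, 885, 885]

    def test_partition_property(self, rng):
        labels = rng.choice(["a", "b", "c"], size=101).tolist()
        fold_ids = stratified_fold_ids(labels, 5, seed=1)
        assert len(fold_ids) == 101
        assert set(fold_ids.tolist()) == set(range(5))

    def test_stratification(self):
        labels = ["a"] * 50 + ["b"] * 25
        fold_ids = stratified_fold_ids(labels, 5, seed=2)
        for fold in range(5):
            chunk = [labels[i] for i in range(75) if fold_ids[i] == fold]
            assert chunk.count("a") == 10
            assert chunk.count("b") == 5

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            stratified_fold_ids(["a", "b"], 5, seed=0)


class TestCrossValidate:
    def test_separable_dataset_perfect_accuracy(self, separable_dataset):
        for clf in ("svm", "lda", "qda", "1nn"):
            spec = PipelineSpec(
                classifier=clf, k=3 if clf != "1nn" else None, C=10.0, gamma=0.1
            )
            result = cross_validate(separable_dataset, spec, folds=5, seed=0)
            assert result.micro == 100.0, clf

    def test_majority_dummy_matches_largest_class_share(self):
        config = SyntheticConfig(
            n_samples=200,
            class_labels=("big", "small"),
            class_proportions=(0.7, 0.3),
            n_haplogroups=2,
            mixing=((1.0, 0.0), (0.0, 1.0)),
            motif_size=4,
            private_rate=0.3,
            seed=21,
        )
        dataset, _ = generate_dataset(config)
        share = max(
            sum(1 for s in dataset if s.label == lb) for lb in dataset.label_universe
        ) / len(dataset)
        result = cross_validate(dataset, PipelineSpec(classifier="majority"), seed=0)
        assert result.micro == pytest.approx(100.0 * share)

    def test_class_smaller_than_folds_error(self):
        ds = ProfileDataset(
            tuple(
                make_sample(f"S{i}", [(73, 340)], [], label="a" if i else "b")
                for i in range(6)
            )
        )
        with pytest.raises(ValidationError):
            cross_validate(ds, PipelineSpec(classifier="1nn"), folds=5)

    def test_unlabeled_sample_rejected(self):
        ds = ProfileDataset(
            tuple(make_sample(f"S{i}", [(73, 340)], []) for i in range(10))
        )
        with pytest.raises(ValidationError):
            cross_validate(ds, PipelineSpec(classifier="1nn"))

    def test_metadata_records_fold_settings(self, separable_dataset):
        result = cross_validate(
            separable_dataset, PipelineSpec(**FAST_SVM), folds=5, seed=0
        )
        assert len(result.metadata["fold_settings"]) == 5
        assert all("k" in s for s in result.metadata["fold_settings"])


@pytest.fixture(scope="module")
def split():
    config = SyntheticConfig(
        n_samples=240, seed=17, n_haplogroups=4, motif_size=8,
        private_rate=0.3,
        mixing=tuple(
            tuple(1.0 if h == g else 0.0 for h in range(4)) for g in range(4)
        ),
    )
    return make_biased_split(
        config, 0.3, drop_class_in_test="Hispanic", test_coverage_model="full"
    )


@pytest.fixture(scope="module")
def hvr1_signal_dataset():
    # all class signal confined to a narrow HVR1 sub-interval
    config = SyntheticConfig(
        n_samples=150,
        class_labels=("A", "B", "C"),
        n_haplogroups=3,
        mixing=((1, 0, 0), (0, 1, 0), (0, 0, 1)),
        motif_size=5,
        private_rate=0.0,
        motif_region=((16100, 16200),),
        seed=13,
    )
    dataset, _ = generate_dataset(config)
    return dataset


class TestHoldout:
    def test_strategies_identical_on_complete_coverage(self, split):
        train, test, _ = split
        preds = {}
        for strategy in ("plain", "rcrs", "probability", "common_region"):
            result = holdout_evaluate(
                train, test, strategy, PipelineSpec(**FAST_SVM), seed=0
            )
            preds[strategy] = result.confusion.counts.tolist()
        baseline = preds["plain"]
        for strategy, counts in preds.items():
            assert counts == baseline, strategy

    def test_missing_test_class_gives_column_without_row(self, split):
        train, test, _ = split
        result = holdout_evaluate(train, test, "plain", PipelineSpec(**FAST_SVM))
        ct = result.confusion
        assert "Hispanic" in ct.pred_classes
        assert "Hispanic" not in ct.true_classes

    def test_single_training_class_error(self):
        ds = ProfileDataset(
            tuple(
                make_sample(f"S{i}", [(73, 340)], [], label="only")
                for i in range(10)
            )
        )
        with pytest.raises(ValidationError):
            holdout_evaluate(ds, ds, "plain", PipelineSpec(classifier="1nn"))

    def test_unclassifiable_common_region_sample_excluded(self):
        train = ProfileDataset(
            tuple(
                make_sample(
                    f"T{i}", [(73, 340)], ["100T"] if i % 2 else [],
                    label="a" if i % 2 else "b",
                )
                for i in range(8)
            )
        )
        test = ProfileDataset(
            (
                make_sample("X", [(16024, 16365)], [], label="a"),
                make_sample("Y", [(73, 340)], ["100T"], label="a"),
            )
        )
        result = holdout_evaluate(
            train, test, "common_region", PipelineSpec(classifier="1nn")
        )
        assert result.metadata["unclassifiable"] == ["X"]
        assert result.confusion.total == 1

    def test_rcrs_bias_toward_reference_like_class(self):
        config = SyntheticConfig(
            n_samples=400, seed=7, n_haplogroups=4, motif_size=10,
            motif_hvr2_fraction=0.6, private_rate=0.5,
            reference_like_class="Caucasian",
            mixing=tuple(
                tuple(1.0 if h == g else 0.0 for h in range(4)) for g in range(4)
            ),
        )
        train, test, _ = make_biased_split(
            config, 0.4, drop_class_in_test="Hispanic",
            test_coverage_model="published_like",
        )
        spec = PipelineSpec(**FAST_SVM)
        rcrs = holdout_evaluate(train, test, "rcrs", spec, seed=1)
        common = holdout_evaluate(train, test, "common_region", spec, seed=1)
        assert rcrs.predicted_share("Caucasian") > common.predicted_share("Caucasian")
        assert common.macro > rcrs.macro


class TestScans:
    def test_deletion_baseline_equals_full_cv(self, hvr1_signal_dataset):
        spec = PipelineSpec(classifier="1nn")
        scan = deletion_scan(hvr1_signal_dataset, spec, from_end="hvr1_end", seed=0)
        full = cross_validate(hvr1_signal_dataset, spec, seed=0)
        assert scan.entries[0].result.micro == full.micro

    def test_deletion_feature_count_arithmetic(self, hvr1_signal_dataset):
        spec = PipelineSpec(classifier="1nn")
        scan = deletion_scan(hvr1_signal_dataset, spec, from_end="hvr2_end", seed=0)
        n = scan.entries[0].n_features
        step = -(-n // 10)  # ceil(0.10 n)
        for e in scan.entries:
            assert e.n_features == n - e.index * step

    def test_asymmetric_degradation_with_hvr1_signal(self):
        # signal motifs at the HVR1 start, uninformative private noise everywhere
        config = SyntheticConfig(
            n_samples=150,
            class_labels=("A", "B", "C"),
            n_haplogroups=3,
            mixing=((1, 0, 0), (0, 1, 0), (0, 0, 1)),
            motif_size=5,
            private_rate=2.0,
            motif_region=((16024, 16120),),
            seed=29,
        )
        dataset, _ = generate_dataset(config)
        spec = PipelineSpec(classifier="1nn")
        from_hvr1 = deletion_scan(dataset, spec, from_end="hvr1_end", fraction=0.25, seed=0)
        from_hvr2 = deletion_scan(dataset, spec, from_end="hvr2_end", fraction=0.25, seed=0)
        acc1 = [a for a in from_hvr1.accuracies() if a is not None]
        acc2 = [a for a in from_hvr2.accuracies() if a is not None]
        # round 1 from the HVR1 end removes the signal; from the HVR2 end it
        # removes only noise features
        assert acc1[1] < acc2[1] - 20.0

    def test_window_width_default(self, hvr1_signal_dataset):
        spec = PipelineSpec(classifier="1nn")
        scan = window_scan(
            hvr1_signal_dataset, spec, n_windows=3, folds=5, seed=0
        )
        # default fraction 0.10 of the 1122-position universe
        assert "axis=0-111" in scan.entries[0].descriptor

    def test_first_window_starts_at_16024(self, hvr1_signal_dataset):
        scan = window_scan(
            hvr1_signal_dataset, PipelineSpec(classifier="1nn"), n_windows=3, seed=0
        )
        assert "start_pos=16024" in scan.entries[0].descriptor

    def test_window_peak_at_signal_window(self, hvr1_signal_dataset):
        spec = PipelineSpec(classifier="1nn")
        scan = window_scan(hvr1_signal_dataset, spec, n_windows=10, folds=5, seed=0)
        accs = [a if a is not None else -1.0 for a in scan.accuracies()]
        best = int(np.argmax(accs))
        # signal interval 16100-16200 = axis 76-176; windows are 112 wide,
        # spaced ~112 apart, so the peak must be among the first two windows
        assert best in (0, 1)
        assert accs[best] > 90.0


class TestRendering:
    def test_result_tsv_contains_metrics(self, separable_dataset):
        result = cross_validate(
            separable_dataset, PipelineSpec(classifier="1nn"), seed=0
        )
        text = render_result_tsv(result)
        assert "micro_accuracy\t100.00" in text
        assert "macro_accuracy\t100.00" in text

    def test_scan_tsv_shape(self, hvr1_signal_dataset=None):
        config = SyntheticConfig(
            n_samples=60, class_labels=("A", "B"), n_haplogroups=2,
            mixing=((1, 0), (0, 1)), motif_size=3, private_rate=0.0, seed=3,
        )
        dataset, _ = generate_dataset(config)
        scan = window_scan(
            dataset, PipelineSpec(classifier="1nn"), n_windows=4, seed=0
        )
        lines = render_scan_tsv(scan).strip().splitlines()
        assert len(lines) == 5
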