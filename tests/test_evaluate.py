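"""Fold construction, confusion accounting and metric definitions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegtfdx.evaluate import (
    ConfusionMatrix,
    UndefinedMetricError,
    accuracy,
    confusion,
    cross_validate,
    kfold_split,
    sensitivity,
    specificity,
)
from eegtfdx.models import TrainConfig, build_dcnn

label_vectors = st.lists(
    st.sampled_from(["MD", "HC"]), min_size=1, max_size=60
)


class TestKfold:
    def test_2496_items_partition_into_500_499(self):
        folds = kfold_split(2496, k=5, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [499, 499, 499, 499, 500]
        cat = np.concatenate(folds)
        assert len(np.unique(cat)) == 2496
        for i in range(5):
            for j in range(i + 1, 5):
                assert not set(folds[i]) & set(folds[j])

    def test_exact_20_percent_test_share_when_divisible(self):
        folds = kfold_split(100, k=5, seed=1)
        assert all(len(f) == 20 for f in folds)

    def test_grouped_split_never_splits_a_subject(self):
        groups = np.repeat([f"S{i}" for i in range(10)], 4)
        folds = kfold_split(40, k=5, seed=2, groups=groups)
        for fold in folds:
            for g in np.unique(groups[fold]):
                assert np.sum(groups[fold] == g) == 4  # all of the subject's images

    def test_stratified_folds_balance_classes(self):
        labels = np.array(["MD"] * 40 + ["HC"] * 40)
        folds = kfold_split(80, k=5, seed=3, stratify_labels=labels)
        for fold in folds:
            counts = dict(zip(*np.unique(labels[fold], return_counts=True)))
            assert counts == {"HC": 8, "MD": 8}

    def test_more_folds_than_items_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(3, k=5)

    def test_seeded_reproducibility(self):
        a = kfold_split(101, k=5, seed=11)
        b = kfold_split(101, k=5, seed=11)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)


class TestConfusion:
    def test_perfect_predictions(self):
        cm = confusion(["MD"] * 3 + ["HC"] * 2, ["MD"] * 3 + ["HC"] * 2)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (3, 2, 0, 0)

    def test_all_predicted_md(self):
        cm = confusion(["MD"] * 3 + ["HC"] * 2, ["MD"] * 5)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (3, 2, 0, 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(label_vectors, st.integers(0, 2**31 - 1))
    def test_counts_match_bruteforce_tally(self, truth, seed):
        rng = np.random.default_rng(seed)
        pred = rng.choice(["MD", "HC"], size=len(truth))
        cm = confusion(truth, pred)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for t, p in zip(truth, pred):
            if t == "MD" and p == "MD":
                tally["tp"] += 1
            elif t == "HC" and p == "MD":
                tally["fp"] += 1
            elif t == "HC" and p == "HC":
                tally["tn"] += 1
            else:
                tally["fn"] += 1
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == tuple(tally.values())
        assert cm.total == len(truth)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(["MD"], ["MD", "HC"])

    def test_foreign_label_rejected(self):
        with pytest.raises(ValueError, match="foreign"):
            confusion(["MD", "XX"], ["MD", "HC"])


class TestMetrics:
    def test_perfect_scores(self):
        cm = ConfusionMatrix(tp=3, fp=0, tn=2, fn=0)
        assert accuracy(cm) == sensitivity(cm) == specificity(cm) == 100.0

    def test_balanced_errors_give_fifty(self):
        cm = ConfusionMatrix(tp=1, fp=1, tn=1, fn=1)
        assert accuracy(cm) == sensitivity(cm) == specificity(cm) == 50.0

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedMetricError, match="sensitivity"):
            sensitivity(ConfusionMatrix(tp=0, fp=1, tn=1, fn=0))
        with pytest.raises(UndefinedMetricError, match="specificity"):
            specificity(ConfusionMatrix(tp=1, fp=0, tn=0, fn=1))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_positive_class_swap_symmetry(self, counts):
        tp, fp, tn, fn = counts
        cm = ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
        swapped = ConfusionMatrix(tp=tn, fp=fn, tn=tp, fn=fp)
        assert accuracy(cm) == pytest.approx(accuracy(swapped))
        assert sensitivity(cm) == pytest.approx(specificity(swapped))
        assert specificity(cm) == pytest.approx(sensitivity(swapped))


class TestCrossValidate:
    @staticmethod
    def _dataset(n=30, side=16, seed=0):
        rng = np.random.default_rng(seed)
        images = rng.integers(0, 256, (n, side, side, 3), dtype=np.uint8)
        labels = np.array(["MD", "HC"] * (n // 2))
        return images, labels

    def test_reports_one_entry_per_fold(self):
        images, labels = self._dataset()
        report = cross_validate(
            images, labels,
            lambda fold: build_dcnn(side=16, n_blocks=1, filters=(2,), seed=fold),
            TrainConfig(max_epochs=1, batch_size=8),
            k=5, seed=0,
        )
        assert len(report.folds) == 5
        assert all(f["confusion"].total == f["n_test"] for f in report.folds)

    def test_mean_is_arithmetic_mean_of_folds(self):
        images, labels = self._dataset()
        report = cross_validate(
            images, labels,
            lambda fold: build_dcnn(side=16, n_blocks=1, filters=(2,), seed=fold),
            TrainConfig(max_epochs=1, batch_size=8),
            k=3, seed=1,
        )
        assert report.mean_accuracy == pytest.approx(
            np.mean([f["accuracy"] for f in report.folds])
        )

    def test_training_split_missing_a_class_is_rejected(self):
        images, _ = self._dataset(n=10)
        labels = np.array(["MD"] * 8 + ["HC"] * 2)
        groups = np.array(["A"] * 8 + ["B"] * 2)
        with pytest.raises(ValueError, match="lacks"):
            cross_validate(
                images, labels,
                lambda fold: build_dcnn(side=16, n_blocks=1, filters=(2,), seed=0),
                TrainConfig(max_epochs=1, batch_size=8),
                k=2, seed=0, groups=groups,
            )
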