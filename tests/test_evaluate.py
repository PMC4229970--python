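"""Validation drivers, multi-label metrics and the binomial sigma."""

import numpy as np
import pytest

from enzmech.classify import Prediction, PredictionSet
from enzmech.datasets import (
    Attribute,
    Instance,
    MultiLabelDataset,
    add_empty_instances,
)
from enzmech.errors import CoverageError, InputError, PartitionError
from enzmech.evaluate import (
    MetricCounts,
    PredictorSpec,
    binomial_sigma,
    confusion_counts,
    k_fold,
    leave_one_out,
    macro_metric,
    micro_metric,
    subset_accuracy,
    train_test,
)
from conftest import random_dataset
from oracles import confusion_oracle


def _predset(label_space, mapping):
    return PredictionSet(
        label_space=list(label_space),
        order=list(mapping),
        by_id={k: Prediction(id=k, labels=frozenset(v)) for k, v in mapping.items()},
    )


def _truth(mapping, label_space):
    return MultiLabelDataset(
        instances=[
            Instance(id=k, labels=frozenset(v)) for k, v in mapping.items()
        ],
        attribute_space=[],
        label_space=list(label_space),
    )


# ---------------------------------------------------------------------------
# Subset accuracy and confusion counts
# ---------------------------------------------------------------------------


def test_subset_accuracy_hand_built_cases():
    labels = ["m1", "m2"]
    truth = _truth({"A": {"m1"}, "B": {"m1", "m2"}, "C": set()}, labels)
    perfect = _predset(labels, {"A": {"m1"}, "B": {"m1", "m2"}, "C": set()})
    assert subset_accuracy(perfect, truth) == 1.0
    # 2 of 3 exact: missing one label of B is a miss despite partial overlap.
    partial = _predset(labels, {"A": {"m1"}, "B": {"m1"}, "C": set()})
    assert subset_accuracy(partial, truth) == pytest.approx(2 / 3)


def test_empty_versus_empty_counts_as_correct():
    truth = _truth({"A": set()}, ["m1"])
    pred = _predset(["m1"], {"A": set()})
    assert subset_accuracy(pred, truth) == 1.0


def test_missing_prediction_is_a_coverage_error():
    truth = _truth({"A": {"m1"}, "B": set()}, ["m1"])
    pred = _predset(["m1"], {"A": {"m1"}})
    with pytest.raises(CoverageError):
        subset_accuracy(pred, truth)


def test_confusion_counts_match_enumeration_on_random_cases():
    rng = np.random.default_rng(3)
    labels = [f"m{i}" for i in range(5)]
    for _ in range(20):
        truths = {
            f"I{i}": {l for l in labels if rng.random() < 0.3} for i in range(12)
        }
        preds = {
            f"I{i}": {l for l in labels if rng.random() < 0.3} for i in range(12)
        }
        counts = confusion_counts(
            _predset(labels, preds), _truth(truths, labels)
        )
        expected = confusion_oracle(
            labels,
            [frozenset(truths[f"I{i}"]) for i in range(12)],
            [frozenset(preds[f"I{i}"]) for i in range(12)],
        )
        for k, lab in enumerate(labels):
            assert (
                counts.tp[k], counts.fp[k], counts.tn[k], counts.fn[k]
            ) == expected[lab]
        # Per-label totals all equal the number of evaluated instances.
        assert counts.n_instances == 12


# ---------------------------------------------------------------------------
# Micro / macro averaging
# ---------------------------------------------------------------------------


def _counts(tp, fp, tn, fn):
    labels = [f"m{i}" for i in range(len(tp))]
    return MetricCounts(labels=labels, tp=tp, fp=fp, tn=tn, fn=fn)


def test_single_label_micro_equals_macro_equals_binary():
    counts = _counts([7], [2], [10], [1])
    assert micro_metric(counts, "precision") == macro_metric(counts, "precision")
    assert micro_metric(counts, "precision") == pytest.approx(7 / 9)
    assert micro_metric(counts, "recall") == pytest.approx(7 / 8)
    assert micro_metric(counts, "specificity") == pytest.approx(10 / 12)


def test_two_label_micro_macro_arithmetic():
    """TP=(9,1), FP=(1,9): micro precision 10/20, macro (0.9+0.1)/2;
    with FP=(1,0): micro 10/11, macro (0.9+1.0)/2."""
    counts = _counts([9, 1], [1, 9], [10, 10], [0, 0])
    assert micro_metric(counts, "precision") == pytest.approx(0.5)
    assert macro_metric(counts, "precision") == pytest.approx(0.5)
    counts2 = _counts([9, 1], [1, 0], [10, 19], [0, 0])
    assert micro_metric(counts2, "precision") == pytest.approx(10 / 11)
    assert macro_metric(counts2, "precision") == pytest.approx(0.95)


def test_micro_equals_binary_on_summed_counts_random():
    rng = np.random.default_rng(9)
    for _ in range(30):
        n_lab = int(rng.integers(1, 8))
        n = 40
        tp = rng.integers(0, 10, n_lab)
        fp = rng.integers(0, 10, n_lab)
        fn = rng.integers(0, 10, n_lab)
        tn = n - tp - fp - fn
        if (tn < 0).any():
            continue
        counts = _counts(tp.tolist(), fp.tolist(), tn.tolist(), fn.tolist())
        for metric in ("precision", "recall", "specificity"):
            micro = micro_metric(counts, metric)
            assert 0.0 <= micro <= 1.0
            assert 0.0 <= macro_metric(counts, metric) <= 1.0
        assert micro_metric(counts, "precision") == pytest.approx(
            tp.sum() / max(1, tp.sum() + fp.sum())
        )


def test_macro_zero_over_zero_defaults_to_one():
    counts = _counts([5, 0], [0, 0], [5, 10], [0, 0])
    assert macro_metric(counts, "precision") == 1.0
    assert macro_metric(counts, "precision", undefined_value=0.0) == 0.5


def test_specificity_stays_high_when_false_positives_are_rare():
    """With hundreds of labels and rare FP, micro specificity exceeds
    0.997 — the regime where specificity stops being informative."""
    n_lab = 200
    tp = [1] * n_lab
    fp = [1 if i < 2 else 0 for i in range(n_lab)]
    fn = [0] * n_lab
    tn = [248 - t - f for t, f in zip(tp, fp)]
    counts = _counts(tp, fp, tn, fn)
    assert micro_metric(counts, "specificity") > 0.997
    assert macro_metric(counts, "specificity") > 0.997


# ---------------------------------------------------------------------------
# Validation drivers
# ---------------------------------------------------------------------------


def test_loo_perfect_on_duplicate_pairs():
    """Every instance has an identical-attribute partner with identical
    labels, so leave-one-out recovers every label set."""
    insts = []
    for f in range(3):
        for c in range(2):
            insts.append(
                Instance(
                    id=f"F{f}C{c}",
                    attributes={f: 1.0},
                    labels={f"M950{f}"},
                )
            )
    ds = MultiLabelDataset(
        instances=insts,
        attribute_space=[Attribute(f"s{j}") for j in range(3)],
        label_space=[f"M950{f}" for f in range(3)],
    )
    report = leave_one_out(ds)
    assert report.subset_accuracy == 1.0
    assert report.mispredictions == []


def test_loo_mechanism_with_two_carriers_stays_predictable(clean_synth):
    report = leave_one_out(clean_synth.dataset)
    assert report.subset_accuracy == 1.0


def test_loo_is_invariant_to_instance_order(clean_synth):
    ds = clean_synth.dataset
    rng = np.random.default_rng(4)
    shuffled = ds.subset([ds.ids[i] for i in rng.permutation(len(ds))])
    a = leave_one_out(ds)
    b = leave_one_out(shuffled)
    assert a.subset_accuracy == b.subset_accuracy
    assert sorted(m.accession for m in a.mispredictions) == sorted(
        m.accession for m in b.mispredictions
    )


def test_padding_stays_in_training_and_out_of_metrics(toy_dataset):
    padded = add_empty_instances(toy_dataset, 2)
    report = leave_one_out(padded)
    assert report.counts.n_instances == 3  # only real instances evaluated


def test_kfold_with_n_folds_equals_leave_one_out():
    rng = np.random.default_rng(12)
    ds = random_dataset(rng, n_max=12, d_max=6, l_max=3)
    loo = leave_one_out(ds)
    kf = k_fold(ds, folds=len(ds), seed=99)
    assert kf.subset_accuracy == loo.subset_accuracy
    assert (kf.counts.tp == loo.counts.tp).all()
    assert (kf.counts.fp == loo.counts.fp).all()
    assert (kf.counts.fn == loo.counts.fn).all()


def test_kfold_same_seed_is_reproducible(clean_synth):
    a = k_fold(clean_synth.dataset, folds=2, seed=5)
    b = k_fold(clean_synth.dataset, folds=2, seed=5)
    assert a.fold_assignments == b.fold_assignments
    assert a.subset_accuracy == b.subset_accuracy


def test_kfold_rejects_impossible_partitions(toy_dataset):
    with pytest.raises(PartitionError):
        k_fold(toy_dataset, folds=1, seed=0)
    with pytest.raises(PartitionError):
        k_fold(toy_dataset, folds=10, seed=0)


def test_train_test_unseen_labels_yield_no_false_negatives(clean_synth):
    """Testing enzymes whose mechanisms never occur in training: an ideal
    predictor returns empty sets, so FP = 0 and FN is not applicable."""
    ds = clean_synth.dataset
    train_ids = [i.id for i in ds.instances if not i.labels]  # negatives only
    test_ids = [i.id for i in ds.instances if i.labels]
    train = MultiLabelDataset(
        instances=[ds.instance(a) for a in train_ids],
        attribute_space=list(ds.attribute_space),
        label_space=[],
    )
    test = ds.subset(test_ids)
    report = train_test(train, test)
    assert report.counts.total_fp() == 0
    assert report.counts.total_fn() == 0  # their labels are unpredictable


def test_empty_anchors_prevent_false_positives_on_negatives(clean_synth):
    """A query sharing no (or almost no) attributes with the enzyme
    families finds an empty padding instance at distance sqrt(|nonzero|),
    closer than any labelled instance — so it is predicted unlabeled.
    Without the anchors the nearest labelled family would fire instead."""
    ds = clean_synth.dataset
    labeled = ds.subset([i.id for i in ds.instances if i.labels])
    negatives = MultiLabelDataset(
        instances=[ds.instance(i.id) for i in ds.instances if not i.labels],
        attribute_space=list(ds.attribute_space),
        label_space=[],
    )
    bare = train_test(labeled, negatives)
    anchored = train_test(add_empty_instances(labeled, 2), negatives)
    assert bare.counts.total_fp() > 0
    assert anchored.counts.total_fp() == 0


def test_train_test_aligns_attribute_spaces_by_union():
    train = MultiLabelDataset(
        instances=[Instance(id="T", attributes={0: 1.0}, labels={"m1"})],
        attribute_space=[Attribute("sA")],
        label_space=["m1"],
    )
    test = MultiLabelDataset(
        instances=[Instance(id="Q", attributes={0: 1.0, 1: 1.0}, labels={"m1"})],
        attribute_space=[Attribute("sA"), Attribute("sB")],
        label_space=["m1"],
    )
    report = train_test(train, test)
    assert report.counts.labels == ["m1"]
    assert report.counts.tp[0] == 1  # nearest neighbour is T despite sB


def test_synthetic_confound_shows_up_in_fp_listing(confounded_synth):
    report = leave_one_out(confounded_synth.dataset)
    listed = {m.accession for m in report.mispredictions}
    assert listed == set(confounded_synth.confounded_ids())


# ---------------------------------------------------------------------------
# Binomial sigma
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "p, n, expected",
    [
        (0.963, 250, 1.19),
        (0.0, 100, 0.0),
        (1.0, 100, 0.0),
        (0.5, 100, 5.0),
    ],
)
def test_binomial_sigma_values(p, n, expected):
    assert binomial_sigma(p, n) == pytest.approx(expected, abs=0.005)


def test_binomial_sigma_rejects_out_of_range():
    with pytest.raises(InputError):
        binomial_sigma(1.2, 10)
    with pytest.raises(InputError):
        binomial_sigma(0.5, 0)


def test_predictor_spec_rejects_unknown_algorithm():
    with pytest.raises(InputError):
        PredictorSpec(algorithm="svm")
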