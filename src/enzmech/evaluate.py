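"""Validation drivers and multi-label evaluation metrics.

Subset (classification) accuracy is the strict criterion: the predicted
label set must equal the true set exactly, empty-versus-empty counting as
correct.  Micro metrics pool per-label confusion counts before applying
the binary formula; macro metrics average the per-label binary values,
giving rare mechanisms the same weight as common ones.  Padding instances
(artificial empty rows) are always available for training but never
evaluated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import BRkNNModel, PredictionSet, brknn_predict, direct_transfer
from .datasets import Attribute, Instance, MultiLabelDataset
from .errors import (
    ConsistencyError,
    CoverageError,
    InputError,
    PartitionError,
)

__all__ = [
    "MetricCounts",
    "Misprediction",
    "EvaluationReport",
    "PredictorSpec",
    "subset_accuracy",
    "confusion_counts",
    "micro_metric",
    "macro_metric",
    "leave_one_out",
    "k_fold",
    "train_test",
    "binomial_sigma",
]

_METRICS = ("precision", "recall", "specificity")


@dataclass
class MetricCounts:
    """Per-label TP/FP/TN/FN tallies over the evaluated test instances."""

    labels: list[str]
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        for name in ("tp", "fp", "tn", "fn"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if arr.shape != (n,):
                raise ConsistencyError(f"{name} must have one entry per label")
            if (arr < 0).any():
                raise ConsistencyError(f"{name} counts must be non-negative")
            setattr(self, name, arr)
        totals = self.tp + self.fp + self.tn + self.fn
        if len(set(totals.tolist())) > 1:
            raise ConsistencyError(
                "per-label count totals disagree on the number of evaluated instances"
            )

    @property
    def n_instances(self) -> int:
        if not self.labels:
            return 0
        return int(self.tp[0] + self.fp[0] + self.tn[0] + self.fn[0])

    def total_fp(self) -> int:
        return int(self.fp.sum())

    def total_fn(self) -> int:
        return int(self.fn.sum())


def _binary(metric: str, tp: float, fp: float, tn: float, fn: float,
            undefined: float) -> float:
    if metric == "precision":
        num, den = tp, tp + fp
    elif metric == "recall":
        num, den = tp, tp + fn
    elif metric == "specificity":
        num, den = tn, tn + fp
    else:
        raise InputError(f"unknown metric {metric!r}")
    return float(num / den) if den else float(undefined)


def micro_metric(counts: MetricCounts, metric: str, *,
                 undefined_value: float = 1.0) -> float:
    """Pool counts over all labels, then apply the binary formula."""
    return _binary(
        metric,
        counts.tp.sum(),
        counts.fp.sum(),
        counts.tn.sum(),
        counts.fn.sum(),
        undefined_value,
    )


def macro_metric(counts: MetricCounts, metric: str, *,
                 undefined_value: float = 1.0) -> float:
    """Average the per-label binary values with equal label weight.

    A label whose binary value is 0/0 (never predicted and never true in
    the fold) contributes ``undefined_value`` (default 1.0) before
    averaging.
    """
    if not counts.labels:
        return float(undefined_value)
    vals = [
        _binary(metric, tp, fp, tn, fn, undefined_value)
        for tp, fp, tn, fn in zip(counts.tp, counts.fp, counts.tn, counts.fn)
    ]
    return float(np.mean(vals))


@dataclass
class Misprediction:
    accession: str
    true_labels: frozenset[str]
    predicted_labels: frozenset[str]
    note: str = ""


@dataclass
class EvaluationReport:
    """Aggregated outcome of a validation run."""

    subset_accuracy: float
    micro: dict[str, float]
    macro: dict[str, float]
    counts: MetricCounts
    mispredictions: list[Misprediction]
    fold_assignments: dict[str, int] | None = None
    seed: int | None = None
    per_fold: list["EvaluationReport"] | None = None

    def to_json_dict(self) -> dict:
        return {
            "subset_accuracy": self.subset_accuracy,
            "micro": self.micro,
            "macro": self.macro,
            "n_instances": self.counts.n_instances,
            "n_labels": len(self.counts.labels),
            "false_positives": self.counts.total_fp(),
            "false_negatives": self.counts.total_fn(),
            "n_mispredicted_instances": len(self.mispredictions),
            "seed": self.seed,
            "fold_assignments": self.fold_assignments,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")

    def misprediction_frame(self) -> pd.DataFrame:
        rows = [
            {
                "accession": m.accession,
                "true_mechanism": ";".join(sorted(m.true_labels)),
                "predicted_mechanism": ";".join(sorted(m.predicted_labels)),
                "note": m.note,
            }
            for m in self.mispredictions
        ]
        return pd.DataFrame(
            rows,
            columns=["accession", "true_mechanism", "predicted_mechanism", "note"],
        )

    def write_misprediction_csv(self, path: str | Path) -> None:
        self.misprediction_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Metric computation from predictions
# ---------------------------------------------------------------------------


def _evaluated(pred: PredictionSet, truth: MultiLabelDataset) -> list[Instance]:
    real = truth.real_instances()
    missing = [i.id for i in real if i.id not in pred.by_id]
    if missing:
        raise CoverageError(f"no prediction for instances: {missing[:5]}...")
    return real


def subset_accuracy(pred: PredictionSet, truth: MultiLabelDataset) -> float:
    """Fraction of evaluated instances whose predicted label set equals the
    true set exactly (empty equals empty)."""
    real = _evaluated(pred, truth)
    if not real:
        raise InputError("no real instances to evaluate")
    hits = sum(1 for i in real if pred.labels_of(i.id) == i.labels)
    return hits / len(real)


def confusion_counts(
    pred: PredictionSet,
    truth: MultiLabelDataset,
    *,
    on_unknown_truth: str = "error",
) -> MetricCounts:
    """One-vs-rest TP/FP/TN/FN per label over the evaluated instances.

    Labels are those of the prediction's (training) label space.  A true
    label outside that space is an error by default; ``on_unknown_truth=
    "ignore"`` drops it, the train/test behaviour where such labels are
    unpredictable and yield no FN.
    """
    if on_unknown_truth not in ("error", "ignore"):
        raise InputError("on_unknown_truth must be 'error' or 'ignore'")
    labels = list(pred.label_space)
    known = set(labels)
    real = _evaluated(pred, truth)

    tp = np.zeros(len(labels), dtype=int)
    fp = np.zeros_like(tp)
    tn = np.zeros_like(tp)
    fn = np.zeros_like(tp)
    index = {lab: k for k, lab in enumerate(labels)}
    for inst in real:
        z = pred.labels_of(inst.id)
        stray = z - known
        if stray:
            raise ConsistencyError(
                f"instance {inst.id!r} predicted labels outside the label "
                f"space: {sorted(stray)}"
            )
        y = inst.labels & known
        if on_unknown_truth == "error" and inst.labels - known:
            raise ConsistencyError(
                f"instance {inst.id!r} carries true labels outside the label "
                f"space: {sorted(inst.labels - known)}"
            )
        for lab, k in index.items():
            in_z, in_y = lab in z, lab in y
            if in_z and in_y:
                tp[k] += 1
            elif in_z:
                fp[k] += 1
            elif in_y:
                fn[k] += 1
            else:
                tn[k] += 1
    return MetricCounts(labels=labels, tp=tp, fp=fp, tn=tn, fn=fn)


def _report(
    pred: PredictionSet,
    truth: MultiLabelDataset,
    *,
    on_unknown_truth: str = "error",
    fold_assignments: dict[str, int] | None = None,
    seed: int | None = None,
) -> EvaluationReport:
    counts = confusion_counts(pred, truth, on_unknown_truth=on_unknown_truth)
    known = set(pred.label_space)
    mis = []
    for inst in truth.real_instances():
        z = pred.labels_of(inst.id)
        if z != (inst.labels & known) or (
            on_unknown_truth == "error" and z != inst.labels
        ):
            note = "" if inst.labels <= known else "n/a FN (labels unseen in training)"
            mis.append(
                Misprediction(
                    accession=inst.id,
                    true_labels=inst.labels,
                    predicted_labels=z,
                    note=note,
                )
            )
    return EvaluationReport(
        subset_accuracy=subset_accuracy(pred, truth),
        micro={m: micro_metric(counts, m) for m in _METRICS},
        macro={m: macro_metric(counts, m) for m in _METRICS},
        counts=counts,
        mispredictions=mis,
        fold_assignments=fold_assignments,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Predictor dispatch
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictorSpec:
    """Which predictor to run: BRkNN (k, distance) or direct transfer."""

    algorithm: str = "brknn"
    k: int = 1
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.algorithm not in ("brknn", "direct-transfer"):
            raise InputError(f"unknown algorithm {self.algorithm!r}")

    def predict(
        self, train: MultiLabelDataset, test: MultiLabelDataset
    ) -> PredictionSet:
        if self.algorithm == "brknn":
            return brknn_predict(
                BRkNNModel(train=train, k=self.k, distance=self.distance), test
            )
        return direct_transfer(train, test)


# ---------------------------------------------------------------------------
# Validation drivers
# ---------------------------------------------------------------------------


def _drop(dataset: MultiLabelDataset, ids: set[str]) -> MultiLabelDataset:
    return MultiLabelDataset(
        instances=[replace(i) for i in dataset.instances if i.id not in ids],
        attribute_space=list(dataset.attribute_space),
        label_space=list(dataset.label_space),
    )


def leave_one_out(
    dataset: MultiLabelDataset, spec: PredictorSpec = PredictorSpec()
) -> EvaluationReport:
    """Each real instance is predicted from a model trained on all other
    instances (padding always stays in training)."""
    real = dataset.real_instances()
    if len(real) < 2:
        raise InputError("leave-one-out needs at least 2 real instances")
    merged: PredictionSet | None = None
    by_id = {}
    for inst in real:
        train = _drop(dataset, {inst.id})
        test = dataset.subset([inst.id])
        pred = spec.predict(train, test)
        by_id[inst.id] = pred.by_id[inst.id]
        merged = pred
    assert merged is not None
    pooled = PredictionSet(
        label_space=merged.label_space,
        order=[i.id for i in real],
        by_id=by_id,
    )
    return _report(pooled, dataset)


def k_fold(
    dataset: MultiLabelDataset,
    folds: int,
    seed: int,
    spec: PredictorSpec = PredictorSpec(),
) -> EvaluationReport:
    """Seeded uniform random partition of the real instances into ``folds``
    test folds; train on the rest (plus padding), pool the predictions.

    ``folds`` equal to the number of real instances reproduces
    leave-one-out exactly.
    """
    if folds < 2:
        raise PartitionError("need at least 2 folds")
    real_ids = [i.id for i in dataset.real_instances()]
    if folds > len(real_ids):
        raise PartitionError(
            f"cannot split {len(real_ids)} instances into {folds} non-empty folds"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(real_ids))
    chunks = np.array_split(perm, folds)
    if any(len(c) == 0 for c in chunks):
        raise PartitionError("a fold came out empty")

    assignment = {}
    by_id = {}
    label_space = None
    per_fold = []
    for f, chunk in enumerate(chunks):
        test_ids = [real_ids[i] for i in sorted(chunk)]
        for acc in test_ids:
            assignment[acc] = f
        train = _drop(dataset, set(test_ids))
        test = dataset.subset(test_ids)
        pred = spec.predict(train, test)
        label_space = pred.label_space
        by_id.update(pred.by_id)
        per_fold.append(_report(pred, test, seed=seed))

    pooled = PredictionSet(
        label_space=list(label_space),
        order=real_ids,
        by_id=by_id,
    )
    report = _report(pooled, dataset, fold_assignments=assignment, seed=seed)
    report.per_fold = per_fold
    return report


def _align_union(
    train: MultiLabelDataset, test: MultiLabelDataset
) -> tuple[MultiLabelDataset, MultiLabelDataset]:
    """Remap both datasets onto the union of their attribute spaces
    (train's column order first); absent attributes read as 0."""
    kinds: dict[str, str] = {}
    for ds in (train, test):
        for a in ds.attribute_space:
            if kinds.setdefault(a.name, a.kind) != a.kind:
                raise ConsistencyError(
                    f"attribute {a.name!r} has conflicting kinds across sets"
                )
    names = [a.name for a in train.attribute_space]
    names += [a.name for a in test.attribute_space if a.name not in set(names)]
    space = [Attribute(n, kinds[n]) for n in names]
    col = {n: j for j, n in enumerate(names)}

    def remap(ds: MultiLabelDataset) -> MultiLabelDataset:
        local = [a.name for a in ds.attribute_space]
        return MultiLabelDataset(
            instances=[
                Instance(
                    id=i.id,
                    attributes={col[local[j]]: v for j, v in i.attributes.items()},
                    labels=i.labels,
                    is_padding=i.is_padding,
                )
                for i in ds.instances
            ],
            attribute_space=list(space),
            label_space=list(ds.label_space),
        )

    return remap(train), remap(test)


def train_test(
    train: MultiLabelDataset,
    test: MultiLabelDataset,
    spec: PredictorSpec = PredictorSpec(),
) -> EvaluationReport:
    """Train on one dataset, score on a separate one.

    Attribute spaces are union-aligned (absent columns read 0).  A test
    instance whose true labels never occur in training cannot yield a
    false negative — any predicted label still counts as a false positive;
    such instances are flagged ``n/a FN`` in the misprediction listing.
    """
    train_a, test_a = _align_union(train, test)
    pred = spec.predict(train_a, test_a)
    return _report(pred, test_a, on_unknown_truth="ignore")


def binomial_sigma(p: float, n: int) -> float:
    """Standard deviation, in percentage points, of the success rate of a
    Bernoulli predictor with success probability ``p`` over ``n`` trials:
    ``100 * sqrt(p * (1 - p) / n)``."""
    if not 0.0 <= p <= 1.0:
        raise InputError("p must lie in [0, 1]")
    if n < 1:
        raise InputError("n must be at least 1")
    return 100.0 * math.sqrt(p * (1.0 - p) / n)
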