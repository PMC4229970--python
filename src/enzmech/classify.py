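"""Predictors: binary-relevance k-nearest-neighbour, direct signature
transfer, and the identity-vs-distance line separator.

BRkNN treats each label as an independent binary problem decided by the
query's nearest training instances.  With ``k = 1`` — the parametrisation
used throughout — the closest ring of neighbours is gathered: the k-th
smallest distance is found and *every* training instance tied at that
distance joins the neighbourhood.  A label is predicted iff it appears on
at least half of the gathered neighbours (inclusive threshold).  The ring
rule makes predictions deterministic under any permutation of the training
instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse as sp

from .attributes import PairRecord
from .datasets import MultiLabelDataset
from .errors import DimensionError, InputError

__all__ = [
    "BRkNNModel",
    "Prediction",
    "PredictionSet",
    "LineSeparator",
    "LineResult",
    "brknn_predict",
    "direct_transfer",
    "line_classify",
    "line_sweep",
]

# Relative tolerance for detecting distance ties; exact for binary data
# (squared Euclidean distances are integers there).
_TIE_RTOL = 1e-9


@dataclass
class Prediction:
    """One test instance's predicted label set plus provenance."""

    id: str
    labels: frozenset[str]
    #: (training id, distance) pairs, non-decreasing in distance.
    neighbours: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class PredictionSet:
    """Per-instance predictions over a training label space."""

    label_space: list[str]
    order: list[str]
    by_id: dict[str, Prediction]

    def labels_of(self, accession: str) -> frozenset[str]:
        return self.by_id[accession].labels

    def __len__(self) -> int:
        return len(self.order)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for acc in self.order:
            p = self.by_id[acc]
            rows.append(
                {
                    "test_id": acc,
                    "predicted_labels": ";".join(sorted(p.labels)),
                    "neighbour_ids": ";".join(nid for nid, _ in p.neighbours),
                    "neighbour_distances": ";".join(
                        f"{d:.6g}" for _, d in p.neighbours
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "test_id",
                "predicted_labels",
                "neighbour_ids",
                "neighbour_distances",
            ],
        )


@dataclass
class BRkNNModel:
    """Binary-relevance kNN over Euclidean or Jaccard distance."""

    train: MultiLabelDataset
    k: int = 1
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InputError("k must be at least 1")
        if self.distance not in ("euclidean", "jaccard"):
            raise InputError(f"unknown distance {self.distance!r}")
        if not self.train.instances:
            raise InputError("training set is empty")


def _check_same_space(a: MultiLabelDataset, b: MultiLabelDataset) -> None:
    if a.attribute_space != b.attribute_space:
        raise DimensionError("train and test attribute spaces differ")


def _squared_euclidean(test: sp.csr_matrix, train: sp.csr_matrix) -> np.ndarray:
    tt = np.asarray(test.multiply(test).sum(axis=1)).ravel()
    rr = np.asarray(train.multiply(train).sum(axis=1)).ravel()
    cross = (test @ train.T).toarray()
    d2 = tt[:, None] + rr[None, :] - 2.0 * cross
    np.clip(d2, 0.0, None, out=d2)
    return d2


def _jaccard_matrix(
    test: MultiLabelDataset, train: MultiLabelDataset
) -> np.ndarray:
    for ds in (test, train):
        if any(a.kind != "binary" for a in ds.attribute_space):
            raise InputError("Jaccard distance requires binary attribute sets")
    a = test.to_csr()
    b = train.to_csr()
    inter = (a @ b.T).toarray()
    na = np.asarray((a != 0).sum(axis=1)).ravel()
    nb = np.asarray((b != 0).sum(axis=1)).ravel()
    union = na[:, None] + nb[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1), 1.0)
    return np.where(union > 0, dist, 0.0)


def _distance_matrix(
    model: BRkNNModel, test: MultiLabelDataset
) -> tuple[np.ndarray, bool]:
    """Return (matrix, squared) where ``squared`` flags squared Euclidean
    values (kept squared for exact tie detection on binary data)."""
    if model.distance == "euclidean":
        return _squared_euclidean(test.to_csr(), model.train.to_csr()), True
    return _jaccard_matrix(test, model.train), False


def _ring(dist_row: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest training instances plus all ties with the
    k-th smallest distance."""
    order = np.argsort(dist_row, kind="stable")
    kth = dist_row[order[min(k, len(order)) - 1]]
    cut = kth + _TIE_RTOL * max(1.0, abs(kth))
    return order[dist_row[order] <= cut]


def brknn_predict(model: BRkNNModel, test: MultiLabelDataset) -> PredictionSet:
    """Predict each real test instance's label set by neighbourhood vote.

    The neighbourhood is the k nearest training instances expanded with all
    distance ties; a label is predicted iff at least half of the
    neighbourhood carries it.  With k=1 and a unique nearest neighbour the
    prediction copies that neighbour's label set.
    """
    _check_same_space(model.train, test)
    targets = test.real_instances()
    probe = test.subset([i.id for i in targets])
    train_ids = model.train.ids
    train_labels = [inst.labels for inst in model.train.instances]

    by_id: dict[str, Prediction] = {}
    # Distances are computed in blocks of test rows so the test-by-train
    # matrix never has to be materialised whole on large sets.
    block = 512
    for start in range(0, len(targets), block):
        chunk_ids = [i.id for i in targets[start : start + block]]
        dist, squared = _distance_matrix(model, probe.subset(chunk_ids))
        for r, inst in enumerate(targets[start : start + block]):
            _predict_one(
                inst, dist[r], model, squared, train_ids, train_labels, by_id
            )

    return PredictionSet(
        label_space=list(model.train.label_space),
        order=[i.id for i in targets],
        by_id=by_id,
    )


def _predict_one(inst, dist_row, model, squared, train_ids, train_labels, by_id):
    ring = _ring(dist_row, model.k)
    votes: dict[str, int] = {}
    for t in ring:
        for lab in train_labels[t]:
            votes[lab] = votes.get(lab, 0) + 1
    half = len(ring) / 2.0
    predicted = frozenset(lab for lab, n in votes.items() if n >= half)
    neigh = sorted(
        (
            (
                train_ids[t],
                math.sqrt(dist_row[t]) if squared else float(dist_row[t]),
            )
            for t in ring
        ),
        key=lambda item: (item[1], item[0]),
    )
    by_id[inst.id] = Prediction(id=inst.id, labels=predicted, neighbours=neigh)


def direct_transfer(
    train: MultiLabelDataset, test: MultiLabelDataset
) -> PredictionSet:
    """Assign a test protein the union of label sets of all training
    proteins whose nonzero signature set is *exactly* its own; no exact
    match means no prediction."""
    _check_same_space(train, test)
    for ds in (train, test):
        if any(a.kind != "binary" for a in ds.attribute_space):
            raise InputError("direct transfer requires binary attribute sets")

    by_signature: dict[frozenset[int], list] = {}
    for inst in train.instances:
        if inst.is_padding:
            continue
        by_signature.setdefault(frozenset(inst.attributes), []).append(inst)

    targets = test.real_instances()
    by_id: dict[str, Prediction] = {}
    for inst in targets:
        matches = by_signature.get(frozenset(inst.attributes), [])
        labels = frozenset(lab for m in matches for lab in m.labels)
        by_id[inst.id] = Prediction(
            id=inst.id,
            labels=labels,
            neighbours=sorted((m.id, 0.0) for m in matches),
        )
    return PredictionSet(
        label_space=list(train.label_space),
        order=[i.id for i in targets],
        by_id=by_id,
    )


# ---------------------------------------------------------------------------
# Line separator over (identity, Euclidean distance) pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LineSeparator:
    """A line through the origin in the identity-distance plane:
    ``euclid = slope × identity``; pairs on or below it ("right" of the
    line with identity on x) are called same-mechanism."""

    slope: float

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise InputError("slope must be non-negative")


@dataclass
class LineResult:
    predictions: list[bool]
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else float("nan")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")


def line_classify(
    pairs: Sequence[PairRecord], sep: LineSeparator
) -> LineResult:
    """Predict same-mechanism for each pair iff
    ``euclid <= slope × identity`` (boundary inclusive) and tally the
    confusion counts against the recorded truth."""
    preds, tp, fp, tn, fn = [], 0, 0, 0, 0
    for rec in pairs:
        same = rec.euclid <= sep.slope * rec.identity
        preds.append(same)
        if same and rec.same_mechanism:
            tp += 1
        elif same:
            fp += 1
        elif rec.same_mechanism:
            fn += 1
        else:
            tn += 1
    return LineResult(predictions=preds, tp=tp, fp=fp, tn=tn, fn=fn)


def line_sweep(
    pairs: Sequence[PairRecord],
    angles: Iterable[float] | None = None,
    slopes: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Sweep separator lines and record confusion statistics per line.

    ``angles`` are degrees in [0, 90) mapped to ``slope = tan(angle)``
    (identity as a fraction on x, distance on y); explicit ``slopes`` may
    be given instead or in addition.
    """
    entries: list[tuple[float, float]] = []
    if angles is None and slopes is None:
        angles = range(0, 90)
    for ang in angles or ():
        if not 0 <= ang < 90:
            raise InputError("angles must lie in [0, 90) degrees")
        entries.append((float(ang), math.tan(math.radians(ang))))
    for slope in slopes or ():
        entries.append((math.degrees(math.atan(slope)), float(slope)))

    rows = []
    for angle, slope in entries:
        res = line_classify(pairs, LineSeparator(slope))
        rows.append(
            {
                "angle_deg": angle,
                "slope": slope,
                "TP": res.tp,
                "FP": res.fp,
                "TN": res.tn,
                "FN": res.fn,
                "accuracy": res.accuracy,
                "precision": res.precision,
                "recall": res.recall,
            }
        )
    return pd.DataFrame(rows)
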