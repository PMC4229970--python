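"""Distance functions and derived attribute-set constructions.

Three families of attributes feed the mechanism predictors:

* binary signature-presence matrices (built in :mod:`enzmech.datasets`),
* pairwise global-alignment sequence identity, and
* per-mechanism profile vectors — for a query protein ``p`` and each
  mechanism ``m`` either the minimum Euclidean distance in signature space
  to any training carrier of ``m`` (``a_m``), or the maximum sequence
  identity to any carrier (``b_m``).

Sequence identity follows the EMBOSS needle convention: a global
Needleman-Wunsch alignment with affine gaps (BLOSUM62, gap open 10,
gap extend 0.5, end gaps free), identity = identical aligned positions
divided by the full alignment length including gap columns.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .datasets import Attribute, Instance, MultiLabelDataset, SequenceStore
from .errors import ConsistencyError, DimensionError, InputError

__all__ = [
    "NO_CARRIER_DISTANCE",
    "AlignmentParams",
    "ProfileVector",
    "PairRecord",
    "PairTable",
    "euclidean_distance",
    "jaccard_distance",
    "pairwise_identity",
    "identity_matrix",
    "pair_table",
    "min_euclidean_profile",
    "max_identity_profile",
    "min_euclidean_dataset",
    "max_identity_dataset",
    "combine_attribute_sets",
]

#: Sentinel distance for mechanisms with no carrier in the visible training
#: fold: large enough that the mechanism can never win a nearest-neighbour
#: comparison, yet finite so profile ARFFs stay serialisable.
NO_CARRIER_DISTANCE = 1e6


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment scoring parameters (EMBOSS needle defaults)."""

    matrix: str = "EBLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise InputError("gap penalties must be positive")


@dataclass
class ProfileVector:
    """Per-mechanism derived attribute vector (**a** or **b**)."""

    mechanism_order: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mechanism_order),):
            raise DimensionError("profile length must equal |M|")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.mechanism_order, self.values.tolist()))


@dataclass(frozen=True)
class PairRecord:
    """An unordered protein pair with identity, signature distance and truth."""

    accession_a: str
    accession_b: str
    identity: float
    euclid: float
    same_mechanism: bool

    def __post_init__(self) -> None:
        if self.accession_a >= self.accession_b:
            raise ConsistencyError(
                "pair must be ordered accession_a < accession_b and not a self pair"
            )


@dataclass
class PairTable:
    records: list[PairRecord]
    skipped: list[str]  # accessions omitted for lack of a sequence


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def _as_sparse(v) -> Mapping[int, float]:
    return v.attributes if isinstance(v, Instance) else v


def _check_spaces(space, other_space) -> None:
    if space is not None and other_space is not None and list(space) != list(other_space):
        raise DimensionError("vectors are defined over different attribute spaces")


def euclidean_distance(
    u,
    v,
    space: Sequence[Attribute] | None = None,
    other_space: Sequence[Attribute] | None = None,
) -> float:
    """Euclidean norm of ``u - v`` over sparse vectors.

    For binary vectors this equals ``sqrt(number of differing attributes)``:
    identical vectors are at distance 0, one differing attribute gives 1.
    """
    _check_spaces(space, other_space)
    su, sv = _as_sparse(u), _as_sparse(v)
    total = 0.0
    for j in su.keys() | sv.keys():
        d = su.get(j, 0.0) - sv.get(j, 0.0)
        total += d * d
    return math.sqrt(total)


def jaccard_distance(
    u,
    v,
    space: Sequence[Attribute] | None = None,
    other_space: Sequence[Attribute] | None = None,
) -> float:
    """1 - |nonzero(u) ∩ nonzero(v)| / |nonzero(u) ∪ nonzero(v)|.

    Defined only for binary vectors; two all-zero vectors are at distance 0.
    """
    _check_spaces(space, other_space)
    su, sv = _as_sparse(u), _as_sparse(v)
    for s in (su, sv):
        bad = [val for val in s.values() if val not in (0.0, 1.0)]
        if bad:
            raise InputError("Jaccard distance requires binary vectors")
    a, b = set(su), set(sv)
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


# ---------------------------------------------------------------------------
# Pairwise sequence identity
# ---------------------------------------------------------------------------


def _load_matrix(name: str):
    try:
        return substitution_matrices.load(name)
    except FileNotFoundError:
        pass
    # EMBOSS names prefix a dialect letter: EBLOSUM62 -> BLOSUM62.
    if name.upper().startswith("E"):
        try:
            return substitution_matrices.load(name.upper()[1:])
        except FileNotFoundError:
            pass
    raise InputError(f"unknown substitution matrix {name!r}")


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _load_matrix(params.matrix)
    # EMBOSS charges open + extend*L for a gap of length L; Biopython charges
    # open for the first gap position and extend for each further one.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    # End gaps are free (EMBOSS needle default endweight=false).
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    return aligner


def _sanitise(seq: str, alphabet: str, label: str) -> str:
    seq = seq.upper()
    if not seq:
        raise InputError(f"empty sequence for {label}")
    known = set(alphabet)
    # Residues absent from the matrix (J/U/O) score via the wildcard row.
    return "".join(c if c in known else "X" for c in seq)


def pairwise_identity(
    seq_a: str, seq_b: str, params: AlignmentParams = AlignmentParams()
) -> float:
    """Global-alignment sequence identity in [0, 1].

    Identity counts identical aligned positions over the alignment length
    including gap columns, so it spans 0 (no residue aligned identically)
    to 1 (identical sequences).
    """
    aligner = _make_aligner(params)
    alphabet = str(aligner.substitution_matrix.alphabet)
    a = _sanitise(seq_a, alphabet, "seq_a")
    b = _sanitise(seq_b, alphabet, "seq_b")
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def alignment_score(
    seq_a: str, seq_b: str, params: AlignmentParams = AlignmentParams()
) -> float:
    """Optimal global alignment score under ``params`` (exposed for checks)."""
    aligner = _make_aligner(params)
    alphabet = str(aligner.substitution_matrix.alphabet)
    return aligner.score(
        _sanitise(seq_a, alphabet, "seq_a"), _sanitise(seq_b, alphabet, "seq_b")
    )


def identity_matrix(
    store: Mapping[str, str],
    accessions: Sequence[str],
    params: AlignmentParams = AlignmentParams(),
) -> np.ndarray:
    """Symmetric all-vs-all identity matrix over ``accessions`` (diagonal 1)."""
    missing = [a for a in accessions if a not in store]
    if missing:
        raise InputError(f"no sequence for accessions: {missing}")
    n = len(accessions)
    mat = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        ident = pairwise_identity(store[accessions[i]], store[accessions[j]], params)
        mat[i, j] = mat[j, i] = ident
    return mat


# ---------------------------------------------------------------------------
# Pair tables (identity vs signature distance)
# ---------------------------------------------------------------------------


def pair_table(
    dataset: MultiLabelDataset,
    store: Mapping[str, str],
    params: AlignmentParams = AlignmentParams(),
) -> PairTable:
    """All unordered pairs of real instances with identity, Euclidean
    signature distance and same-mechanism truth (label sets intersect).

    Instances without a sequence are skipped and reported; with full
    sequence coverage the table has exactly C(n, 2) records.
    """
    real = dataset.real_instances()
    skipped = sorted(inst.id for inst in real if inst.id not in store)
    usable = [inst for inst in real if inst.id in store]
    records = []
    for u, v in itertools.combinations(usable, 2):
        a, b = sorted((u, v), key=lambda inst: inst.id)
        records.append(
            PairRecord(
                accession_a=a.id,
                accession_b=b.id,
                identity=pairwise_identity(store[a.id], store[b.id], params),
                euclid=euclidean_distance(a, b),
                same_mechanism=bool(a.labels & b.labels),
            )
        )
    return PairTable(records=records, skipped=skipped)


# ---------------------------------------------------------------------------
# Profile vectors
# ---------------------------------------------------------------------------


def _carriers(train: MultiLabelDataset) -> dict[str, list[Instance]]:
    by_mech: dict[str, list[Instance]] = {m: [] for m in train.label_space}
    for inst in train.instances:
        for lab in inst.labels:
            by_mech[lab].append(inst)
    return by_mech


def min_euclidean_profile(
    query: Instance, train: MultiLabelDataset
) -> ProfileVector:
    """a_m = min over training carriers of mechanism m of the Euclidean
    distance between the query's and the carrier's signature vectors.

    A mechanism with no carrier in the visible fold takes the sentinel
    :data:`NO_CARRIER_DISTANCE` so it can never win a neighbour comparison.
    """
    by_mech = _carriers(train)
    values = np.empty(len(train.label_space))
    for k, mech in enumerate(train.label_space):
        carriers = by_mech[mech]
        if not carriers:
            values[k] = NO_CARRIER_DISTANCE
        else:
            values[k] = min(euclidean_distance(query, c) for c in carriers)
    return ProfileVector(mechanism_order=list(train.label_space), values=values)


def max_identity_profile(
    query_seq: str,
    train: MultiLabelDataset,
    store: Mapping[str, str],
    params: AlignmentParams = AlignmentParams(),
) -> ProfileVector:
    """b_m = max over training carriers of mechanism m of the pairwise
    sequence identity with the query; 0 when m has no carriers."""
    by_mech = _carriers(train)
    values = np.zeros(len(train.label_space))
    for k, mech in enumerate(train.label_space):
        best = 0.0
        for carrier in by_mech[mech]:
            if carrier.id not in store:
                raise InputError(f"no sequence for training protein {carrier.id!r}")
            best = max(best, pairwise_identity(query_seq, store[carrier.id], params))
        values[k] = best
    return ProfileVector(mechanism_order=list(train.label_space), values=values)


def _without(dataset: MultiLabelDataset, accession: str) -> MultiLabelDataset:
    return MultiLabelDataset(
        instances=[replace(i) for i in dataset.instances if i.id != accession],
        attribute_space=list(dataset.attribute_space),
        label_space=list(dataset.label_space),
    )


def min_euclidean_dataset(dataset: MultiLabelDataset) -> MultiLabelDataset:
    """Rebuild a dataset whose attributes are leave-self-out minimum
    Euclidean distance profiles, one numeric column per mechanism."""
    space = [Attribute(f"minEuclid_{m}", "numeric") for m in dataset.label_space]
    new_instances = []
    for inst in dataset.instances:
        if inst.is_padding:
            new_instances.append(Instance(id=inst.id, is_padding=True))
            continue
        profile = min_euclidean_profile(inst, _without(dataset, inst.id))
        attrs = {j: v for j, v in enumerate(profile.values) if v != 0.0}
        new_instances.append(
            Instance(id=inst.id, attributes=attrs, labels=inst.labels)
        )
    return MultiLabelDataset(
        instances=new_instances,
        attribute_space=space,
        label_space=list(dataset.label_space),
    )


def max_identity_dataset(
    dataset: MultiLabelDataset,
    store: Mapping[str, str],
    params: AlignmentParams = AlignmentParams(),
    identities: np.ndarray | None = None,
) -> MultiLabelDataset:
    """Rebuild a dataset whose attributes are leave-self-out maximum
    sequence identity profiles, one numeric column per mechanism.

    ``identities`` may carry a precomputed all-vs-all matrix over the real
    instances (in dataset order) to avoid re-aligning.
    """
    real = dataset.real_instances()
    ids = [inst.id for inst in real]
    if identities is None:
        identities = identity_matrix(store, ids, params)
    row = {acc: k for k, acc in enumerate(ids)}
    by_mech = _carriers(dataset)

    space = [Attribute(f"maxId_{m}", "numeric") for m in dataset.label_space]
    new_instances = []
    for inst in dataset.instances:
        if inst.is_padding:
            new_instances.append(Instance(id=inst.id, is_padding=True))
            continue
        attrs = {}
        for j, mech in enumerate(dataset.label_space):
            best = 0.0
            for carrier in by_mech[mech]:
                if carrier.id == inst.id:
                    continue
                best = max(best, identities[row[inst.id], row[carrier.id]])
            if best != 0.0:
                attrs[j] = best
        new_instances.append(
            Instance(id=inst.id, attributes=attrs, labels=inst.labels)
        )
    return MultiLabelDataset(
        instances=new_instances,
        attribute_space=space,
        label_space=list(dataset.label_space),
    )


# ---------------------------------------------------------------------------
# Attribute-set combination
# ---------------------------------------------------------------------------


def combine_attribute_sets(
    sets: Sequence[MultiLabelDataset],
    prefixes: Sequence[str] | None = None,
) -> MultiLabelDataset:
    """Column-wise concatenation of attribute sets over the same instances.

    All sets must list the same instance ids in the same order and agree on
    labels; attribute names must be disjoint (pass ``prefixes`` to namespace
    them per source set).  The combined width is the sum of the widths.
    """
    if not sets:
        raise InputError("no attribute sets to combine")
    if prefixes is not None and len(prefixes) != len(sets):
        raise InputError("one prefix per attribute set required")

    first = sets[0]
    for ds in sets[1:]:
        if ds.ids != first.ids:
            raise ConsistencyError("attribute sets list different instances")
        for a, b in zip(first.instances, ds.instances):
            if a.labels != b.labels or a.is_padding != b.is_padding:
                raise ConsistencyError(
                    f"label disagreement between sets on instance {a.id!r}"
                )

    space: list[Attribute] = []
    for s, ds in enumerate(sets):
        pre = f"{prefixes[s]}:" if prefixes is not None else ""
        space.extend(Attribute(pre + a.name, a.kind) for a in ds.attribute_space)
    if len({a.name for a in space}) != len(space):
        raise ConsistencyError(
            "attribute names collide across sets; pass prefixes to namespace them"
        )

    new_instances = []
    for i, inst in enumerate(first.instances):
        attrs: dict[int, float] = {}
        offset = 0
        for ds in sets:
            for j, v in ds.instances[i].attributes.items():
                attrs[offset + j] = v
            offset += len(ds.attribute_space)
        new_instances.append(
            Instance(
                id=inst.id,
                attributes=attrs,
                labels=inst.labels,
                is_padding=inst.is_padding,
            )
        )
    return MultiLabelDataset(
        instances=new_instances,
        attribute_space=space,
        label_space=list(first.label_space),
    )
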