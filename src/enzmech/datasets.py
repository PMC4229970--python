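"""Multi-label dataset types and I/O.

The on-disk dialect is the one used by the Mulan multi-label learning
ecosystem: a Weka ARFF file (dense or sparse) holding one row per protein,
plus an XML file that names which ARFF columns are class labels.  Label
columns are binary {0,1} columns appended after the attribute columns; the
XML file is the sole authority on which columns are labels.

Instances are proteins identified by accession.  Attributes are either
binary signature-presence flags (InterPro / Catalytic Site Atlas matches)
or numeric derived values (distance and identity profiles).  Labels are
enzyme mechanism identifiers following the MACiE convention: a 5-character
code ``M`` + 4 digits, optionally extended with a subunit suffix such as
``M0314_component_I``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence
from xml.etree import ElementTree

import numpy as np
from scipy import sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConsistencyError, FormatError, InputError

__all__ = [
    "Attribute",
    "Instance",
    "MultiLabelDataset",
    "LabelSplitMap",
    "SplitEntry",
    "SequenceStore",
    "read_mulan",
    "write_mulan",
    "build_dataset",
    "split_labels",
    "truncate_labels",
    "add_empty_instances",
    "read_fasta",
    "write_fasta",
    "read_pairs_tsv",
    "read_split_map_tsv",
]

PADDING_PREFIX = "__EMPTY_"
MACIE_CODE_RE = re.compile(r"^M\d{4}$")

# 20 standard residues + IUPAC ambiguity codes + selenocysteine/pyrrolysine.
AMINO_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY" "BXZJUO*")


@dataclass(frozen=True)
class Attribute:
    """A named dataset column: ``binary`` ({0,1}) or ``numeric``."""

    name: str
    kind: str = "binary"

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "numeric"):
            raise FormatError(f"unknown attribute kind {self.kind!r}")


@dataclass
class Instance:
    """One protein: sparse attribute map plus a (possibly empty) label set.

    ``attributes`` maps attribute index -> value and stores no explicit
    zeros.  ``is_padding`` marks artificial empty instances added to anchor
    nearest-neighbour distances; they never appear in test folds.
    """

    id: str
    attributes: dict[int, float] = field(default_factory=dict)
    labels: frozenset[str] = frozenset()
    is_padding: bool = False

    def __post_init__(self) -> None:
        self.labels = frozenset(self.labels)
        self.attributes = {
            int(i): v for i, v in self.attributes.items() if v != 0
        }

    def nonzero_names(self, space: Sequence[Attribute]) -> frozenset[str]:
        return frozenset(space[i].name for i in self.attributes)


@dataclass
class MultiLabelDataset:
    """An ordered collection of instances over declared attribute and label
    spaces.

    Invariants (enforced by :meth:`validate`): attribute indices fall inside
    the attribute space; every instance label belongs to the label space;
    instance ids are unique; binary attributes only take values in {0,1}.
    """

    instances: list[Instance]
    attribute_space: list[Attribute]
    label_space: list[str]

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        labels = set(self.label_space)
        if len(labels) != len(self.label_space):
            raise ConsistencyError("duplicate labels in label space")
        names = [a.name for a in self.attribute_space]
        if len(set(names)) != len(names):
            raise ConsistencyError("duplicate attribute names")
        seen: set[str] = set()
        width = len(self.attribute_space)
        for inst in self.instances:
            if inst.id in seen:
                raise ConsistencyError(f"duplicate instance id {inst.id!r}")
            seen.add(inst.id)
            for idx, value in inst.attributes.items():
                if not 0 <= idx < width:
                    raise ConsistencyError(
                        f"instance {inst.id!r}: attribute index {idx} outside space"
                    )
                if (
                    self.attribute_space[idx].kind == "binary"
                    and value not in (0, 1)
                ):
                    raise FormatError(
                        f"instance {inst.id!r}: binary attribute "
                        f"{self.attribute_space[idx].name!r} has value {value!r}"
                    )
            extra = inst.labels - labels
            if extra:
                raise ConsistencyError(
                    f"instance {inst.id!r} carries labels outside the label "
                    f"space: {sorted(extra)}"
                )

    # -- conveniences ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self) -> Iterator[Instance]:
        return iter(self.instances)

    @property
    def ids(self) -> list[str]:
        return [inst.id for inst in self.instances]

    @property
    def attribute_names(self) -> list[str]:
        return [a.name for a in self.attribute_space]

    def real_instances(self) -> list[Instance]:
        """Instances excluding padding (the evaluation universe)."""
        return [inst for inst in self.instances if not inst.is_padding]

    def instance(self, accession: str) -> Instance:
        for inst in self.instances:
            if inst.id == accession:
                return inst
        raise KeyError(accession)

    def to_csr(self) -> sp.csr_matrix:
        """Instance-by-attribute matrix in CSR form."""
        rows, cols, vals = [], [], []
        for i, inst in enumerate(self.instances):
            for j, v in inst.attributes.items():
                rows.append(i)
                cols.append(j)
                vals.append(v)
        return sp.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(self.instances), len(self.attribute_space)),
            dtype=float,
        )

    def label_matrix(self) -> np.ndarray:
        y = np.zeros((len(self.instances), len(self.label_space)), dtype=bool)
        index = {lab: k for k, lab in enumerate(self.label_space)}
        for i, inst in enumerate(self.instances):
            for lab in inst.labels:
                y[i, index[lab]] = True
        return y

    def subset(self, accessions: Iterable[str]) -> "MultiLabelDataset":
        wanted = list(accessions)
        by_id = {inst.id: inst for inst in self.instances}
        missing = [a for a in wanted if a not in by_id]
        if missing:
            raise ConsistencyError(f"unknown instance ids: {missing}")
        return MultiLabelDataset(
            instances=[replace(by_id[a]) for a in wanted],
            attribute_space=list(self.attribute_space),
            label_space=list(self.label_space),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultiLabelDataset):
            return NotImplemented
        return (
            self.attribute_space == other.attribute_space
            and self.label_space == other.label_space
            and [(i.id, i.attributes, i.labels, i.is_padding) for i in self]
            == [(i.id, i.attributes, i.labels, i.is_padding) for i in other]
        )


@dataclass(frozen=True)
class SplitEntry:
    """One (original MACiE code, protein) -> subunit-split label record."""

    original: str
    accession: str
    split: str

    def __post_init__(self) -> None:
        if len(self.original) != 5 or not MACIE_CODE_RE.match(self.original):
            raise FormatError(
                f"original label {self.original!r} is not a 5-character MACiE code"
            )
        if not self.split.startswith(self.original):
            raise FormatError(
                f"split label {self.split!r} does not begin with {self.original!r}"
            )


@dataclass
class LabelSplitMap:
    """Maps (MACiE code, accession) pairs to refined MACiE+subunit labels."""

    entries: list[SplitEntry]

    def lookup(self) -> dict[tuple[str, str], str]:
        table: dict[tuple[str, str], str] = {}
        for e in self.entries:
            key = (e.original, e.accession)
            if key in table and table[key] != e.split:
                raise ConsistencyError(
                    f"conflicting split labels for {key}: "
                    f"{table[key]!r} vs {e.split!r}"
                )
            table[key] = e.split
        return table


class SequenceStore(dict):
    """Accession -> upper-case amino-acid sequence.

    Sequences are validated on insertion: non-empty and drawn from the 20
    standard one-letter codes plus ambiguity letters.
    """

    def __setitem__(self, accession: str, sequence: str) -> None:
        sequence = str(sequence).upper()
        if not sequence:
            raise FormatError(f"empty sequence for {accession!r}")
        bad = set(sequence) - AMINO_LETTERS
        if bad:
            raise FormatError(
                f"sequence {accession!r} contains non-amino letters {sorted(bad)}"
            )
        super().__setitem__(accession, sequence)

    def update(self, other=(), **kw) -> None:  # keep validation on update()
        items = other.items() if isinstance(other, Mapping) else other
        for k, v in items:
            self[k] = v
        for k, v in kw.items():
            self[k] = v


# ---------------------------------------------------------------------------
# Mulan ARFF + XML
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r"@attribute\s+(?:'([^']+)'|\"([^\"]+)\"|(\S+))\s+(.+)", re.I)


def _parse_attr_decl(line: str) -> tuple[str, str]:
    m = _ATTR_RE.match(line)
    if not m:
        raise FormatError(f"malformed @attribute line: {line!r}")
    name = m.group(1) or m.group(2) or m.group(3)
    typ = m.group(4).strip()
    compact = typ.replace(" ", "").lower()
    if compact in ("{0,1}", "{0.0,1.0}"):
        return name, "binary"
    if compact in ("numeric", "real", "integer"):
        return name, "numeric"
    if compact == "string":
        return name, "string"
    raise FormatError(f"unsupported attribute type {typ!r} for column {name!r}")


def _read_label_xml(xml_path: Path) -> list[str]:
    try:
        tree = ElementTree.parse(xml_path)
    except ElementTree.ParseError as exc:
        raise FormatError(f"cannot parse label XML {xml_path}: {exc}") from exc
    labels = [
        el.attrib["name"]
        for el in tree.getroot().iter()
        if el.tag.rsplit("}", 1)[-1] == "label" and "name" in el.attrib
    ]
    if not labels:
        raise FormatError(f"label XML {xml_path} declares no labels")
    return labels


def _split_sparse_row(body: str) -> list[tuple[int, str]]:
    body = body.strip()
    if not (body.startswith("{") and body.endswith("}")):
        raise FormatError(f"malformed sparse row: {body!r}")
    inner = body[1:-1].strip()
    if not inner:
        return []
    out = []
    for chunk in inner.split(","):
        parts = chunk.strip().split(None, 1)
        if len(parts) != 2:
            raise FormatError(f"malformed sparse entry {chunk!r}")
        out.append((int(parts[0]), parts[1].strip()))
    return out


def _coerce(token: str, kind: str, column: str) -> float:
    token = token.strip().strip("'\"")
    try:
        value = float(token)
    except ValueError as exc:
        raise FormatError(f"non-numeric value {token!r} in column {column!r}") from exc
    if kind == "binary" and value not in (0.0, 1.0):
        raise FormatError(
            f"binary column {column!r} holds non-{{0,1}} value {token!r}"
        )
    return value


def read_mulan(arff_path: str | Path, xml_path: str | Path) -> MultiLabelDataset:
    """Read a Mulan dataset: ARFF instances + XML label declaration.

    Label columns named by the XML are removed from the attribute space and
    materialised as per-instance label sets.  Row order is preserved.  An
    optional leading ``string`` attribute supplies instance ids; otherwise
    ids are generated from the row number.
    """
    arff_path, xml_path = Path(arff_path), Path(xml_path)
    label_names = _read_label_xml(xml_path)

    columns: list[tuple[str, str]] = []
    data_lines: list[str] = []
    in_data = False
    for raw in arff_path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("@relation"):
            continue
        if low.startswith("@attribute"):
            if in_data:
                raise FormatError("@attribute after @data")
            columns.append(_parse_attr_decl(line))
            continue
        if low.startswith("@data"):
            in_data = True
            continue
        if in_data:
            data_lines.append(line)

    names = [n for n, _ in columns]
    missing = [lab for lab in label_names if lab not in names]
    if missing:
        raise FormatError(f"XML labels absent from ARFF columns: {missing}")

    id_col = 0 if columns and columns[0][1] == "string" else None
    for k, (name, kind) in enumerate(columns):
        if kind == "string" and k != id_col:
            raise FormatError(f"string column {name!r} only allowed first, as id")

    label_set = set(label_names)
    attr_cols = [
        (k, name, kind)
        for k, (name, kind) in enumerate(columns)
        if k != id_col and name not in label_set
    ]
    label_cols = {k: name for k, (name, _) in enumerate(columns) if name in label_set}
    col_to_attr = {k: j for j, (k, _, _) in enumerate(attr_cols)}
    kind_of = {k: kind for k, _, kind in attr_cols}
    name_of = dict(enumerate(names))

    instances: list[Instance] = []
    for row_num, line in enumerate(data_lines):
        values: dict[int, str]
        if line.startswith("{"):
            values = {k: tok for k, tok in _split_sparse_row(line)}
        else:
            toks = [t.strip() for t in line.split(",")]
            if len(toks) != len(columns):
                raise FormatError(
                    f"row {row_num}: {len(toks)} fields, expected {len(columns)}"
                )
            values = dict(enumerate(toks))

        if id_col is not None and id_col in values:
            inst_id = values.pop(id_col).strip("'\"")
        elif id_col is not None:
            raise FormatError(f"row {row_num}: missing id value")
        else:
            inst_id = f"instance_{row_num}"

        attrs: dict[int, float] = {}
        labels: set[str] = set()
        for k, tok in values.items():
            if k >= len(columns) or k < 0:
                raise FormatError(f"row {row_num}: column index {k} out of range")
            if k in label_cols:
                v = _coerce(tok, "binary", name_of[k])
                if v == 1.0:
                    labels.add(label_cols[k])
            else:
                v = _coerce(tok, kind_of[k], name_of[k])
                if v != 0.0:
                    attrs[col_to_attr[k]] = v
        instances.append(
            Instance(
                id=inst_id,
                attributes=attrs,
                labels=frozenset(labels),
                is_padding=inst_id.startswith(PADDING_PREFIX),
            )
        )

    return MultiLabelDataset(
        instances=instances,
        attribute_space=[Attribute(name, kind) for _, name, kind in attr_cols],
        label_space=list(label_names),
    )


def _format_value(value: float, kind: str) -> str:
    if kind == "binary" or float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def write_mulan(
    dataset: MultiLabelDataset,
    arff_path: str | Path,
    xml_path: str | Path,
    *,
    sparse: bool = True,
    relation: str = "enzmech",
) -> None:
    """Write ARFF + XML such that :func:`read_mulan` inverts it exactly.

    With ``sparse=True`` data rows list only nonzero (column, value) pairs;
    label columns are appended after attribute columns, and a leading string
    column carries the instance id.
    """
    arff_path, xml_path = Path(arff_path), Path(xml_path)
    lines = [f"@relation {relation}", "", "@attribute protein_id string"]
    for attr in dataset.attribute_space:
        typ = "{0,1}" if attr.kind == "binary" else "numeric"
        lines.append(f"@attribute {attr.name} {typ}")
    for lab in dataset.label_space:
        lines.append(f"@attribute {lab} {{0,1}}")
    lines += ["", "@data"]

    n_attr = len(dataset.attribute_space)
    label_col = {lab: 1 + n_attr + k for k, lab in enumerate(dataset.label_space)}
    for inst in dataset.instances:
        if sparse:
            entries = [f"0 {inst.id}"]
            for j in sorted(inst.attributes):
                kind = dataset.attribute_space[j].kind
                entries.append(f"{1 + j} {_format_value(inst.attributes[j], kind)}")
            for lab in dataset.label_space:
                if lab in inst.labels:
                    entries.append(f"{label_col[lab]} 1")
            lines.append("{" + ",".join(entries) + "}")
        else:
            row = [inst.id]
            for j, attr in enumerate(dataset.attribute_space):
                row.append(_format_value(inst.attributes.get(j, 0.0), attr.kind))
            for lab in dataset.label_space:
                row.append("1" if lab in inst.labels else "0")
            lines.append(",".join(row))

    arff_path.write_text("\n".join(lines) + "\n")

    root = ElementTree.Element(
        "labels", xmlns="http://mulan.sourceforge.net/labels"
    )
    for lab in dataset.label_space:
        ElementTree.SubElement(root, "label", name=lab)
    ElementTree.indent(root)
    ElementTree.ElementTree(root).write(xml_path, xml_declaration=True)


# ---------------------------------------------------------------------------
# Construction from annotation tables
# ---------------------------------------------------------------------------


def read_pairs_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column tab-separated table, skipping blanks and # comments."""
    pairs = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"expected 2 tab-separated fields: {raw!r}")
        pairs.append((parts[0], parts[1]))
    return pairs


def read_split_map_tsv(path: str | Path) -> LabelSplitMap:
    """Read a 3-column (original_label, protein, split_label) table."""
    entries = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"expected 3 tab-separated fields: {raw!r}")
        entries.append(SplitEntry(original=parts[0], accession=parts[1], split=parts[2]))
    return LabelSplitMap(entries=entries)


def build_dataset(
    annotations: Iterable[tuple[str, str]],
    labels: Iterable[tuple[str, str]] = (),
) -> MultiLabelDataset:
    """Build a binary signature-presence dataset from annotation tables.

    ``annotations`` is a (protein, signature) relation; ``labels`` a
    (protein, label) relation.  The attribute space is the sorted set of
    distinct signatures; attribute j of a protein is 1 iff the protein
    carries signature j.  Duplicate rows collapse; a protein appearing only
    in the label table gets an all-zero attribute vector.  Instances are
    ordered by accession.
    """
    sig_of: dict[str, set[str]] = {}
    for protein, signature in annotations:
        sig_of.setdefault(protein, set()).add(signature)
    lab_of: dict[str, set[str]] = {}
    for protein, label in labels:
        lab_of.setdefault(protein, set()).add(label)
    if not sig_of and not lab_of:
        raise InputError("both annotation and label tables are empty")

    signatures = sorted({s for sigs in sig_of.values() for s in sigs})
    col = {s: j for j, s in enumerate(signatures)}
    proteins = sorted(set(sig_of) | set(lab_of))
    instances = [
        Instance(
            id=p,
            attributes={col[s]: 1.0 for s in sig_of.get(p, ())},
            labels=frozenset(lab_of.get(p, ())),
        )
        for p in proteins
    ]
    return MultiLabelDataset(
        instances=instances,
        attribute_space=[Attribute(s, "binary") for s in signatures],
        label_space=sorted({l for labs in lab_of.values() for l in labs}),
    )


# ---------------------------------------------------------------------------
# Label manipulation
# ---------------------------------------------------------------------------


def split_labels(
    dataset: MultiLabelDataset, split_map: LabelSplitMap
) -> MultiLabelDataset:
    """Refine MACiE labels into MACiE+subunit labels per the split map.

    Mapped (label, protein) pairs are replaced by the split label; unmapped
    labels and instances are untouched.  Map entries for accessions not in
    the dataset are ignored; an entry whose protein is present but lacks the
    original label is a consistency error.
    """
    table = split_map.lookup()
    present = set(dataset.ids)
    for (original, accession), split in table.items():
        if accession in present:
            inst = dataset.instance(accession)
            if original not in inst.labels:
                raise ConsistencyError(
                    f"split map assigns {split!r} to {accession!r}, which does "
                    f"not carry label {original!r}"
                )

    new_instances = []
    for inst in dataset.instances:
        labels = {
            table.get((lab, inst.id), lab) for lab in inst.labels
        }
        new_instances.append(replace(inst, labels=frozenset(labels)))

    used = {lab for inst in new_instances for lab in inst.labels}
    space = [lab for lab in dataset.label_space if lab in used]
    space += sorted(used - set(space))
    return MultiLabelDataset(
        instances=new_instances,
        attribute_space=list(dataset.attribute_space),
        label_space=space,
    )


def truncate_labels(dataset: MultiLabelDataset) -> MultiLabelDataset:
    """Discard subunit suffixes: keep only the 5-character MACiE code.

    Duplicate labels produced on one instance collapse (sets).  Every label
    must be at least 5 characters and start with a valid MACiE code.
    """
    for lab in dataset.label_space:
        if len(lab) < 5:
            raise FormatError(f"label {lab!r} shorter than 5 characters")
        if not MACIE_CODE_RE.match(lab[:5]):
            raise FormatError(f"label {lab!r} does not start with a MACiE code")

    new_instances = [
        replace(inst, labels=frozenset(lab[:5] for lab in inst.labels))
        for inst in dataset.instances
    ]
    space: list[str] = []
    for lab in dataset.label_space:
        if lab[:5] not in space:
            space.append(lab[:5])
    return MultiLabelDataset(
        instances=new_instances,
        attribute_space=list(dataset.attribute_space),
        label_space=space,
    )


def add_empty_instances(dataset: MultiLabelDataset, count: int) -> MultiLabelDataset:
    """Append ``count`` attribute-less, label-less padding instances.

    Padding anchors nearest-neighbour distance for queries sharing no
    attribute with any real instance; padding is excluded from test folds
    and metric denominators.  Ids are ``__EMPTY_1`` upward, continuing past
    any padding already present.
    """
    if count < 0:
        raise InputError("count must be non-negative")
    start = sum(1 for inst in dataset.instances if inst.is_padding)
    pads = [
        Instance(id=f"{PADDING_PREFIX}{start + k + 1}", is_padding=True)
        for k in range(count)
    ]
    return MultiLabelDataset(
        instances=[replace(i) for i in dataset.instances] + pads,
        attribute_space=list(dataset.attribute_space),
        label_space=list(dataset.label_space),
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_UNIPROT_HEADER_RE = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


def _accession_from_header(header: str) -> str:
    first = header.split()[0]
    m = _UNIPROT_HEADER_RE.match(first)
    return m.group(1) if m else first


def read_fasta(path: str | Path) -> SequenceStore:
    """Read amino-acid FASTA; accession = first header token (UniProt
    ``sp|ACC|NAME`` headers resolve to ``ACC``)."""
    store = SequenceStore()
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n += 1
        seq = str(record.seq)
        if not seq:
            raise FormatError(f"empty FASTA record {record.id!r} in {path}")
        store[_accession_from_header(record.description or record.id)] = seq
    if n == 0:
        raise FormatError(f"no FASTA records in {path}")
    return store


def write_fasta(store: SequenceStore | Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in store.items()
    ]
    SeqIO.write(records, str(path), "fasta")
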