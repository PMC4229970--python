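"""Deterministic synthetic protein families for end-to-end testing.

The generator emulates the population structure the mechanism predictors
assume: families of orthologous enzymes that share a signature set (with
occasional signature dropout) and moderate-to-high pairwise sequence
identity; a background of unlabeled "negative" proteins that share a few
background signatures with each other and at most one signature with any
enzyme family; optional *confounder* family pairs that share signatures
but carry different mechanism labels (the situation where two distinct
mechanisms live on near-identical signature sets); and optional
multi-subunit complex families whose chains receive refined
``M####_component_X`` labels, exercising the label split/truncate
machinery.

Geometry guarantees on a clean configuration (no confounders): orthologs
of one family are within squared signature distance 2 of each other,
while any cross-family or family-to-negative squared distance is at least
4, so a 1-nearest-neighbour vote always recovers the family label and
negatives are always predicted empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .attributes import AlignmentParams, pairwise_identity
from .datasets import (
    LabelSplitMap,
    MultiLabelDataset,
    SequenceStore,
    SplitEntry,
    build_dataset,
)
from .errors import GenerationError, InputError

__all__ = ["SynthConfig", "SynthResult", "generate", "mutate_sequence"]

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator.

    Defaults model the population the predictors target: families of ~3
    orthologs carrying on average 4.4 signatures each (with 10% dropout),
    ortholog sequence identity in the 0.40-0.90 band, and a background of
    unlabeled proteins.
    """

    seed: int
    n_families: int = 5
    orthologs_per_family: int = 3
    signatures_per_family_mean: float = 4.4
    signature_dropout: float = 0.1
    confounder_pairs: int = 0
    shared_signature_overlap: float = 1.0
    identity_band: tuple[float, float] = (0.40, 0.90)
    n_negatives: int = 10
    n_complex_families: int = 0
    subunits_per_complex: int = 2
    sequence_length_band: tuple[int, int] = (250, 400)

    def __post_init__(self) -> None:
        lo, hi = self.identity_band
        if not (0.0 < lo <= hi <= 1.0):
            raise InputError("identity band must satisfy 0 < lo <= hi <= 1")
        if not 0.0 <= self.signature_dropout < 1.0:
            raise InputError("signature dropout must lie in [0, 1)")
        if not 0.0 <= self.shared_signature_overlap <= 1.0:
            raise InputError("signature overlap must lie in [0, 1]")
        if min(self.n_families, self.orthologs_per_family, self.n_negatives) < 0:
            raise InputError("counts must be non-negative")
        if 2 * self.confounder_pairs + self.n_complex_families > self.n_families:
            raise InputError(
                "confounder and complex families exceed the family count"
            )
        if self.n_complex_families and not (
            2 <= self.subunits_per_complex <= len(_ROMAN)
        ):
            raise InputError("subunit count must be between 2 and 10")
        llo, lhi = self.sequence_length_band
        if not (30 <= llo <= lhi):
            raise InputError("sequence length band must start at >= 30")
        # Feasibility: the mutation scheduler needs room below full identity.
        if lo < 0.05:
            raise InputError(
                "identity floor below chance-level identity is unreachable"
            )


@dataclass
class SynthResult:
    dataset: MultiLabelDataset
    store: SequenceStore
    split_map: LabelSplitMap
    #: "membership": accession, label, family kind; "confounders": label pairs
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)

    def confounded_ids(self) -> frozenset[str]:
        tab = self.truth["membership"]
        return frozenset(tab.loc[tab["kind"] == "confounder", "accession"])


def mutate_sequence(
    seq: str,
    target_identity: float,
    seed: int | np.random.Generator,
    *,
    tolerance: float = 0.02,
    indel_rate: float = 0.02,
    max_iter: int = 40,
    params: AlignmentParams = AlignmentParams(),
) -> str:
    """Mutate ``seq`` until its alignment identity to the original is within
    ``tolerance`` of ``target_identity``.

    Point substitutions (always to a different residue) plus a small
    fraction of indels (capped at 5%) are applied; the substitution count
    is adjusted iteratively against the measured identity.
    """
    if not 0.0 < target_identity <= 1.0:
        raise InputError("target identity must lie in (0, 1]")
    if indel_rate > 0.05:
        raise InputError("indel rate is capped at 5%")
    if target_identity == 1.0:
        return seq

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = len(seq)
    n_sub = int(round(n * (1.0 - target_identity)))
    n_indel = int(round(n * indel_rate))

    best: tuple[float, str] | None = None
    for _ in range(max_iter):
        n_sub = int(np.clip(n_sub, 0, n))
        positions = rng.choice(n, size=n_sub, replace=False) if n_sub else []
        chars = list(seq)
        for p in positions:
            options = _RESIDUES.replace(chars[p], "")
            chars[p] = options[rng.integers(len(options))]
        for _ in range(n_indel):
            p = int(rng.integers(len(chars)))
            if rng.random() < 0.5 and len(chars) > 30:
                del chars[p]
            else:
                chars.insert(p, _RESIDUES[rng.integers(len(_RESIDUES))])
        candidate = "".join(chars)
        measured = pairwise_identity(seq, candidate, params)
        err = measured - target_identity
        if best is None or abs(err) < abs(best[0] - target_identity):
            best = (measured, candidate)
        if abs(err) <= tolerance:
            return candidate
        # Each extra substitution moves identity by roughly 1/n.
        n_sub += int(round(err * n)) or (1 if err > 0 else -1)

    assert best is not None
    if abs(best[0] - target_identity) <= tolerance:
        return best[1]
    raise GenerationError(
        f"could not reach identity {target_identity:.2f} +/- {tolerance:.2f} "
        f"in {max_iter} iterations (best {best[0]:.3f})"
    )


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_RESIDUES[i] for i in rng.integers(len(_RESIDUES), size=length))


def _family_signatures(rng: np.random.Generator, tag: str, mean: float) -> list[str]:
    # At least 4 signatures so one-signature dropout keeps orthologs within
    # squared distance 2 of each other while cross-family distances stay >= 4.
    k = max(4, int(rng.poisson(mean)))
    return [f"SIG_{tag}_{j:02d}" for j in range(k)]


def _dropout(
    rng: np.random.Generator, signatures: list[str], rate: float
) -> list[str]:
    """Drop at most one signature per ortholog (each marked at ``rate``)."""
    if rate == 0.0:
        return list(signatures)
    marked = [s for s in signatures if rng.random() < rate]
    if not marked:
        return list(signatures)
    victim = marked[int(rng.integers(len(marked)))]
    return [s for s in signatures if s != victim]


def generate(config: SynthConfig) -> SynthResult:
    """Generate the synthetic dataset, sequences, split map and truth tables.

    Family roles, in order: confounder pairs first, then complex
    (multi-subunit) families, then plain families.  The same seed always
    produces byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.identity_band
    llo, lhi = config.sequence_length_band

    # Per-ortholog ancestor-identity targets are geometric-mean scheduled:
    # pairwise ortholog identity ~ t_i * t_j stays inside the band when each
    # t_i is the square root of a value drawn from the (slightly shrunk) band.
    margin = min(0.04, (hi - lo) / 4.0)
    draw_lo, draw_hi = lo + margin, max(lo + margin, hi - margin)

    annotations: list[tuple[str, str]] = []
    labels: list[tuple[str, str]] = []
    membership_rows = []
    confounder_rows = []
    split_entries: list[SplitEntry] = []
    store = SequenceStore()
    counter = 0

    def next_accession() -> str:
        nonlocal counter
        counter += 1
        return f"SYN{counter:04d}"

    def emit_group(
        signatures: list[str],
        label: str,
        kind: str,
        *,
        dropout: float,
        base_label: str | None = None,
    ) -> None:
        ancestor = _random_sequence(rng, int(rng.integers(llo, lhi + 1)))
        for _ in range(config.orthologs_per_family):
            acc = next_accession()
            target = float(np.sqrt(rng.uniform(draw_lo, draw_hi)))
            child_seed = int(rng.integers(2**31))
            store[acc] = mutate_sequence(ancestor, target, child_seed)
            for sig in _dropout(rng, signatures, dropout):
                annotations.append((acc, sig))
            labels.append((acc, label))
            membership_rows.append(
                {"accession": acc, "label": label, "kind": kind}
            )
            if base_label is not None:
                split_entries.append(
                    SplitEntry(original=base_label, accession=acc, split=label)
                )

    family_labels = [f"M{9000 + i:04d}" for i in range(1, config.n_families + 1)]
    fam = 0

    for pair in range(config.confounder_pairs):
        label_a, label_b = family_labels[fam], family_labels[fam + 1]
        fam += 2
        sigs_a = _family_signatures(rng, f"F{fam - 1:02d}", config.signatures_per_family_mean)
        n_shared = int(round(config.shared_signature_overlap * len(sigs_a)))
        sigs_b = sigs_a[:n_shared] + [
            f"SIG_F{fam:02d}_{j:02d}" for j in range(len(sigs_a) - n_shared)
        ]
        # Fully-overlapping confounders get no dropout: identical vectors
        # guarantee the cross-family tie the scenario is meant to create.
        drop = 0.0 if config.shared_signature_overlap == 1.0 else config.signature_dropout
        emit_group(sigs_a, label_a, "confounder", dropout=drop)
        emit_group(sigs_b, label_b, "confounder", dropout=drop)
        confounder_rows.append({"label_a": label_a, "label_b": label_b})

    for _ in range(config.n_complex_families):
        base = family_labels[fam]
        fam += 1
        for s in range(config.subunits_per_complex):
            sub_label = f"{base}_component_{_ROMAN[s]}"
            sigs = _family_signatures(
                rng, f"F{fam:02d}S{s}", config.signatures_per_family_mean
            )
            emit_group(
                sigs, sub_label, "complex", dropout=config.signature_dropout,
                base_label=base,
            )

    while fam < config.n_families:
        label = family_labels[fam]
        fam += 1
        sigs = _family_signatures(rng, f"F{fam:02d}", config.signatures_per_family_mean)
        emit_group(sigs, label, "plain", dropout=config.signature_dropout)

    # Negatives: 3 shared background signatures plus one drawn from the
    # family pools, so each negative touches the enzyme families (overlap
    # exactly 1) yet always has a closer unlabeled twin.
    background = [f"SIG_BG_{j}" for j in range(3)]
    family_pool = sorted({sig for _, sig in annotations})
    for _ in range(config.n_negatives):
        acc = next_accession()
        store[acc] = _random_sequence(rng, int(rng.integers(llo, lhi + 1)))
        sigs = list(background)
        if family_pool:
            sigs.append(family_pool[int(rng.integers(len(family_pool)))])
        for sig in sigs:
            annotations.append((acc, sig))
        membership_rows.append({"accession": acc, "label": "", "kind": "negative"})

    dataset = build_dataset(annotations, labels)
    truth = {
        "membership": pd.DataFrame(
            membership_rows, columns=["accession", "label", "kind"]
        ),
        "confounders": pd.DataFrame(
            confounder_rows, columns=["label_a", "label_b"]
        ),
    }
    return SynthResult(
        dataset=dataset,
        store=store,
        split_map=LabelSplitMap(entries=split_entries),
        truth=truth,
    )
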