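# enzmech

Multi-label prediction of enzyme **chemical mechanism** from protein
sequence-derived attributes.

Enzyme function is usually annotated at the level of the reaction (EC
numbers, GO terms). This package targets a finer question: *by which
catalytic mechanism* does an enzyme perform its reaction — which residues,
cofactors and chemical steps. Mechanism labels follow the MACiE convention
(`M` + 4 digits, e.g. `M0314`), optionally refined with a subunit suffix
naming the chain's role in a multi-subunit complex
(`M0314_component_I`). Because a protein may carry zero, one or several
mechanism labels, prediction is *multi-label*: each instance `(x_i, Y_i)`
has a label set `Y_i ⊆ L`, and a predictor `h` emits a set `Z_i = h(x_i)`.

## Method

Attributes are computed from sequence alone:

* **Signature presence** — binary columns recording the presence (1) or
  absence (0) of each InterPro / Catalytic Site Atlas signature.
* **Sequence identity** — global Needleman–Wunsch alignment (BLOSUM62,
  gap open 10, extend 0.5, free end gaps); identity = identical aligned
  positions / alignment length including gap columns.
* **Profile vectors** — per mechanism `m`: the minimum Euclidean distance
  in signature space to any training carrier of `m`
  (`a_m = min_{p_m ∈ m} d(p, p_m)`), and the maximum sequence identity to
  any carrier (`b_m = max_{p_m ∈ m} id(p, p_m)`).

The core predictor is **binary-relevance k-nearest-neighbour** (BRkNN,
default `k = 1`) over Euclidean or Jaccard distance: the query's closest
ring of training instances (the k nearest plus all distance ties) votes,
and a label is predicted iff it sits on at least half of the ring. Two
baselines accompany it: **direct transfer** (copy labels only from
training proteins with an *exactly* identical signature set) and a
**line separator** through the origin of the identity–distance plane
(`euclid ≤ slope × identity` ⇒ same mechanism).

Evaluation uses the strict subset accuracy
`(1/|D|) Σ I(Z_i = Y_i)` plus micro/macro-averaged precision, recall and
specificity from per-label confusion counts, with leave-one-out, seeded
k-fold and train/test drivers, and the binomial significance helper
`σ = 100·sqrt(P(1−P)/N)`.

A deterministic synthetic generator (`enzmech.synth`) builds protein
families — signatures, sequences within a configured identity band,
subunit complexes, confounder family pairs and unlabeled negatives — so
the whole pipeline is testable without any database downloads.

## Worked example

```bash
# Generate a fixture: 5 families x 3 orthologs + 10 negatives.
enzmech synth --seed 7 --out fix

# Leave-one-out evaluation of BRkNN (k=1, Euclidean) on it.
enzmech evaluate --arff fix/dataset.arff --xml fix/dataset.xml \
    --mode loo --algo brknn --k 1 --distance euclidean --out ev
# {"precision": 1.0, "recall": 1.0, "specificity": 1.0, "subset_accuracy": 1.0}

# The direct-transfer baseline on the same data: precise but incomplete —
# instances without an exact signature twin get no prediction.
enzmech evaluate --arff fix/dataset.arff --xml fix/dataset.xml \
    --algo direct-transfer --mode loo --out ev-dt
# {"precision": 1.0, "recall": 0.4666666666666667, "specificity": 1.0, "subset_accuracy": 0.68}

# Binomial significance: a 96.3%-accurate predictor over 250 predictions.
enzmech sigma --p 0.963 --n 250
# 1.19
```

The first line says BRkNN recovers every label set exactly
(subset accuracy 1.0): each ortholog's nearest neighbour in signature
space is a family mate, and each negative's nearest neighbour is another
unlabeled protein. The direct-transfer line shows the characteristic
trade-off of the exact-match rule: everything it asserts is right
(precision 1.0), but signature dropout leaves many instances without an
identical twin, so recall is low. The `sigma` output means one standard
deviation of such a predictor's accuracy is 1.19 percentage points, so
accuracies within ±2.4 points are not significantly different.

`enzmech pairs` builds the all-vs-all identity/distance pair table and
line-separator statistics, and `enzmech build-attrs` derives the
min-Euclidean / max-identity profile attribute sets.

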