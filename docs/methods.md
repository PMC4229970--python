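# Methods

## Problem and data model

An instance is a protein chain identified by accession, carrying a sparse
attribute vector and a set of zero or more mechanism labels. Labels are
opaque strings except for one convention: the first five characters form a
MACiE-style code (`M` + 4 digits), optionally extended with a subunit
suffix (`M0314_component_I`). Subunit refinement matters because a single
mechanism code can annotate chemically unrelated chains of one enzyme
complex (e.g. the light and heavy chains of an amine dehydrogenase share
a code while having <12% sequence identity); splitting the label per
subunit gives the nearest-neighbour machinery homogeneous classes.
`split_labels` applies such a refinement from an explicit
(code, accession) → split-label map, and `truncate_labels` undoes it by
keeping the first five characters — the two are inverse on per-instance
label sets, which the tests enforce as a property.

Datasets are stored in the Mulan dialect: a Weka ARFF file (dense or
sparse `{index value, …}` rows) plus an XML file that is the sole
authority on which columns are labels. The writer emits a leading
`string` column carrying the accession; the reader accepts files with or
without it. Binary columns accept only {0,1}; violations are format
errors, not warnings, because silent coercion would corrupt distances.

**Padding instances.** Nearest-neighbour prediction forces every query to
have *some* closest instance, so a query sharing no attributes with any
training instance would gravitate to whichever training instance has the
fewest attributes. `add_empty_instances` appends attribute-less,
label-less instances (ids `__EMPTY_n`) that anchor such queries at
distance `sqrt(|nonzero attributes of the query|)` and yield an empty
prediction. Padding always stays in training folds and never enters the
evaluation universe or metric denominators.

## Distances and alignment

* Euclidean distance over the sparse vectors; on binary data it equals
  `sqrt(#differing attributes)`.
* Jaccard distance on nonzero index sets; defined as 0 when both vectors
  are all-zero; refuses numeric attributes.
* Sequence identity from a global affine-gap alignment via Biopython's
  `PairwiseAligner`: BLOSUM62, gap open 10, gap extend 0.5. Conventions
  chosen to match the EMBOSS `needle` defaults: a gap of length L costs
  `open + extend·L` (so the aligner's first-gap-position score is
  −10.5), end gaps are free, and identity divides identical aligned
  columns by the full alignment length *including* gap columns, giving a
  value in [0, 1]. Residue letters absent from the matrix (J/U/O) map to
  the X wildcard row. Because co-optimal alignments can differ in
  identity, the independent check in the test suite compares the optimal
  *score* against a plain three-state Gotoh recurrence exactly, and pins
  identity on frozen examples and symmetry/bound properties.

## Profile attribute sets

For a query `p` and each mechanism `m` of the training label space:
`a_m` is the minimum Euclidean distance in signature space to any carrier
of `m`, and `b_m` the maximum pairwise sequence identity to any carrier.
The dataset-level builders compute each instance's profile leave-self-out
(the instance's own labels never contribute their zero distance), which
is the construction a subsequent leave-one-out evaluation expects. In a
fold where a mechanism loses all carriers, `a_m` takes a large finite
sentinel (1e6, serialisable in ARFF) and `b_m` takes 0, so the mechanism
can never win a neighbour comparison. Profile values are used raw —
identities in [0,1], distances unbounded — with no normalisation; the
scale difference is deliberate and documented rather than hidden, since
no principled scaling rule exists for mixing the two.

## Predictors

**BRkNN.** Binary relevance over the k nearest neighbours with *ring
expansion*: after finding the k-th smallest distance, every training
instance tied with it joins the neighbourhood, and a label is predicted
iff it appears on at least half of the neighbourhood (inclusive at
exactly one half). The ring rule makes predictions invariant under
permutation of the training set — ties are resolved by including
everyone, not by order. Tie detection compares squared Euclidean
distances with relative tolerance 1e-9; on binary data squared distances
are integers, so ties there are exact. With k=1 and several training
instances at distance 0, the ring vote coincides with the union vote of
direct transfer at threshold one half. Distances are computed blockwise
(512 test rows at a time) over CSR matrices, so large sparse datasets
never materialise a full distance matrix.

**Direct transfer.** A test protein receives the union of the label sets
of all training proteins whose nonzero signature set equals its own
exactly; no exact twin means no prediction. High precision, recall
limited to instances with an identical-signature twin.

**Line separator.** Over the pair table (all unordered pairs of real
instances with identity, signature-space Euclidean distance and a
same-mechanism flag), the line `euclid = slope × identity` through the
origin classifies a pair as same-mechanism iff
`euclid ≤ slope × identity`, boundary inclusive — with identity on the x
axis this is the region to the right of the line. `line_sweep` maps
angles in [0°, 90°) to `slope = tan(angle)` with identity expressed as a
fraction; explicit slopes are accepted as well since useful separators
(e.g. slope 7) correspond to angles near 82°. Predicted-same counts are
non-decreasing in slope (nested half-planes), which the tests assert.

## Evaluation

* Subset accuracy: exact set equality per instance, empty-vs-empty
  correct.
* Per-label one-vs-rest confusion counts over the evaluated (real, test)
  instances; micro metrics pool counts before the binary formula, macro
  metrics average per-label values. A label with a 0/0 binary value in a
  fold (never predicted, never true) contributes 1.0 under macro before
  averaging — the choice is switchable (`undefined_value`) and logged
  here rather than buried: rare labels that a fold simply never touches
  should not be scored as failures.
* Leave-one-out trains on all-but-one real instance (padding always in
  training); k-fold partitions the real instances uniformly from a single
  recorded integer seed and reduces exactly to leave-one-out when the
  fold count equals the instance count.
* Train/test aligns the two attribute spaces by union (absent columns
  read 0), because independently-built signature sets rarely share a
  column set. A test instance whose true labels never occur in training
  is flagged `n/a FN`: its labels are unpredictable, so it contributes no
  false negatives, while any label predicted for it still counts as a
  false positive.
* `binomial_sigma(P, N) = 100·sqrt(P(1−P)/N)` gives the standard
  deviation, in percentage points, of a Bernoulli predictor's accuracy —
  the yardstick for deciding whether two attribute sets differ
  significantly.

## Synthetic generator

`enzmech.synth.generate` emulates the population structure the method
assumes, from one mandatory seed (byte-identical reruns):

* **Families**: each gets a fresh mechanism label, a signature set of at
  least 4 signatures (Poisson with mean 4.4, the observed average
  signatures-per-protein in curated enzyme sets), and an ancestor
  sequence of 250–400 uniform residues.
* **Orthologs** (3 per family by default) mutate the ancestor by point
  substitutions plus ≤5% indels until the measured alignment identity
  hits a per-ortholog target; targets are geometric-mean scheduled
  (`t_i = sqrt(m_i)`, `m_i` drawn from the slightly-shrunk identity
  band, default 0.40–0.90) so that *pairwise* ortholog identity
  `≈ t_i·t_j` lands inside the band. The band mirrors the observed
  same-mechanism identity range, which concentrates well above the
  ~18% chance-identity floor.
* **Signature dropout**: each ortholog loses at most one signature
  (each marked with probability 0.1), keeping same-family squared
  distances in {0, 1, 2} — the observed same-mechanism distance band —
  while cross-family distances stay ≥ sqrt(6).
* **Negatives** carry 3 shared background signatures plus exactly one
  signature drawn from the family pools: they touch the enzyme families
  (overlap 1, squared distance ≥ 5) yet always have a closer unlabeled
  twin (squared distance ≤ 2), so a clean configuration provably yields
  leave-one-out subset accuracy 1.0 with at least two negatives present.
* **Confounder pairs** share a configured fraction of signatures across
  two families with different labels; at full overlap dropout is
  disabled so all members are identical in signature space, which makes
  the cross-family tie — and hence mispredictions on exactly those
  instances — deterministic.
* **Complex families** emit per-subunit labels (`…_component_I`, …) and
  the corresponding split map.

What the generator does *not* model: phylogenetic correlation structure,
realistic signature position/length semantics (signatures are opaque
tokens), the chance-identity floor of unrelated real sequences, and the
long-tailed label frequency distribution of curated databases. Passing
tests on generated data therefore demonstrate the correctness of the
machinery and its qualitative behaviour (precision/recall trade-offs,
anchor effects, confounder sensitivity), not quantitative performance on
real annotation corpora.

## Problem sizes and numerical choices

The bundled checks run the full pipeline at 25 instances (5 families × 3
orthologs + 10 negatives), 100 random datasets of up to 30×10 for the
brute-force nearest-neighbour comparison, 1,000 random vector pairs for
the distance identity, and ~300 global alignments per generated fixture —
sizes chosen so the whole suite completes in seconds while every code
path (ties, sentinels, padding, union alignment) is exercised. Distance
ties use relative tolerance 1e-9; ARFF numeric values are serialised with
`repr` so round-trips are exact; all randomness flows from explicit
integer seeds (`numpy.random.default_rng`).

## Known limitations

* Identity of co-optimal alignments is aligner-dependent at the margin;
  scores are exact, identities are pinned by convention (first reported
  alignment).
* The evaluation of train/test runs reports strict subset accuracy even
  when test labels are unpredictable (where false negatives are already
  flagged `n/a`); interpret accuracy only on runs whose label spaces
  overlap.
* Jaccard distance is restricted to binary attribute sets by design;
  profile (numeric) attribute sets must use Euclidean distance.
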