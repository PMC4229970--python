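"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most direct route possible
(exhaustive loops, exact rational arithmetic, a plain Gotoh matrix) and
share no code with the package implementation they check.
"""

from __future__ import annotations

from fractions import Fraction


def hamming_squared(u: dict, v: dict) -> int:
    """Number of differing attributes between two sparse binary vectors."""
    return sum(1 for j in set(u) | set(v) if u.get(j, 0) != v.get(j, 0))


def jaccard_fraction(u: dict, v: dict) -> Fraction:
    a, b = set(u), set(v)
    if not (a | b):
        return Fraction(0)
    return 1 - Fraction(len(a & b), len(a | b))


def brknn_oracle(
    train: list[tuple[dict, frozenset]],
    query: dict,
    k: int = 1,
    distance: str = "euclidean",
) -> frozenset:
    """Closest-ring vote, spelled out naively with exact distances.

    ``train`` is a list of (sparse binary vector, label set) pairs.  The
    ring is the k nearest plus all ties with the k-th distance; a label is
    predicted iff it sits on at least half of the ring.
    """
    if distance == "euclidean":
        dists = [hamming_squared(query, vec) for vec, _ in train]
    else:
        dists = [jaccard_fraction(query, vec) for vec, _ in train]
    kth = sorted(dists)[min(k, len(dists)) - 1]
    ring = [i for i, d in enumerate(dists) if d <= kth]
    votes: dict[str, int] = {}
    for i in ring:
        for lab in train[i][1]:
            votes[lab] = votes.get(lab, 0) + 1
    return frozenset(lab for lab, n in votes.items() if 2 * n >= len(ring))


def confusion_oracle(
    labels: list[str],
    truths: list[frozenset],
    preds: list[frozenset],
) -> dict[str, tuple[int, int, int, int]]:
    """Per-label (TP, FP, TN, FN) by direct enumeration."""
    out = {}
    for lab in labels:
        tp = fp = tn = fn = 0
        for y, z in zip(truths, preds):
            if lab in z and lab in y:
                tp += 1
            elif lab in z:
                fp += 1
            elif lab in y:
                fn += 1
            else:
                tn += 1
        out[lab] = (tp, fp, tn, fn)
    return out


def line_oracle(pairs, slope: float) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) of the slope separator by direct enumeration."""
    tp = fp = tn = fn = 0
    for rec in pairs:
        same = rec.euclid <= slope * rec.identity
        if same and rec.same_mechanism:
            tp += 1
        elif same:
            fp += 1
        elif rec.same_mechanism:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def gotoh_score(
    a: str,
    b: str,
    matrix,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Optimal global alignment score with affine gaps and free end gaps.

    A gap of length L costs ``gap_open + gap_extend * L``; leading and
    trailing gaps are free.  Plain O(nm) three-state recurrence.
    """
    open_cost = gap_open + gap_extend  # first gap position
    ext = gap_extend
    neg = float("-inf")
    n, m = len(a), len(b)

    # best[i][j]: best score aligning a[:i] with b[:j], any end state.
    best = [[neg] * (m + 1) for _ in range(n + 1)]
    gap_a = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    gap_b = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    best[0][0] = 0.0
    for i in range(1, n + 1):
        best[i][0] = 0.0  # leading gap in b is free
    for j in range(1, m + 1):
        best[0][j] = 0.0  # leading gap in a is free

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = matrix[a[i - 1], b[j - 1]]
            diag = best[i - 1][j - 1] + sub
            gap_b[i][j] = max(best[i - 1][j] - open_cost, gap_b[i - 1][j] - ext)
            gap_a[i][j] = max(best[i][j - 1] - open_cost, gap_a[i][j - 1] - ext)
            best[i][j] = max(diag, gap_a[i][j], gap_b[i][j])

    # Trailing gaps free: finish anywhere on the last row or column.
    tail = max(
        max(best[i][m] for i in range(n + 1)),
        max(best[n][j] for j in range(m + 1)),
    )
    return tail
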