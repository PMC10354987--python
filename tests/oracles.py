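"""Independent reference computations used to validate pipeline output.

These deliberately avoid the library code paths they check: the
suffix-prefix overlap oracle is a plain dynamic-programming matrix (with a
vectorized inner loop but the textbook recurrence), and cyclic comparisons
use edlib directly on doubled strings.
"""

from __future__ import annotations

import numpy as np
import edlib

from mitoloop.records import revcomp


def suffix_prefix_distances(a: str, b: str) -> np.ndarray:
    """dist[j] = min edit distance aligning some suffix of a to b[:j].

    Row recurrence of the full DP table with free start anywhere in a
    (M[i][0] = 0) and anchored start of b (M[0][j] = j); the horizontal
    dependency is resolved with the prefix-minimum identity
    M[j] = min_{j' <= j}(cand[j'] + j - j').
    """
    m = len(b)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    idx = np.arange(m + 1)
    prev = idx.copy().astype(np.int64)
    for ch in a.encode():
        sub = prev[:-1] + (bv != ch)
        cand = np.minimum(sub, prev[1:] + 1)
        arr = np.concatenate(([0], cand)) - idx
        prev = np.minimum.accumulate(arr) + idx
    return prev


#: the four dovetail classes between an unordered read pair (a, b):
#: F_ab  suffix(a+) meets prefix(b+)
#: F_ba  suffix(b+) meets prefix(a+)
#: SS    suffix(a+) meets prefix(b-)   (suffix-suffix in + frames)
#: PP    suffix(a-) meets prefix(b+)   (prefix-prefix in + frames)
DOVETAIL_CLASSES = ("F_ab", "F_ba", "SS", "PP")


def _best_dovetail(x: str, y: str, min_overlap: int, max_err: float):
    dist = suffix_prefix_distances(x, y)
    best, best_score = None, None
    for j in range(min_overlap, min(len(x), len(y))):
        if dist[j] <= max_err * j:
            score = j - 20 * dist[j]  # prefer long, heavily penalize errors
            if best_score is None or score > best_score:
                best, best_score = j, score
    return best


def oracle_overlaps(reads, min_overlap: int, min_identity: float):
    """All dovetail overlaps by exhaustive DP over every read pair.

    Returns {(a_id, b_id, class): overlap_len} with a_id < b_id and class in
    DOVETAIL_CLASSES. Containments (overlap spanning a whole read) are not
    reported; build oracle instances without contained reads.
    """
    max_err = 1.0 - min_identity
    found = {}
    n = len(reads)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = reads[i], reads[j]
            if a.id > b.id:
                a, b = b, a
            cases = {
                "F_ab": (a.bases, b.bases),
                "F_ba": (b.bases, a.bases),
                "SS": (a.bases, revcomp(b.bases)),
                "PP": (revcomp(a.bases), b.bases),
            }
            for cls, (x, y) in cases.items():
                best = _best_dovetail(x, y, min_overlap, max_err)
                if best is not None:
                    found[(a.id, b.id, cls)] = best
    return found


def overlap_class(ov) -> str:
    """Map a computed Overlap record onto the oracle's class labels."""
    if ov.orientation == "forward":
        cls = "F_ab" if ov.a_hang > 0 else "F_ba"
    else:
        cls = "SS" if ov.a_hang > 0 else "PP"
    if ov.a_id > ov.b_id:
        cls = {"F_ab": "F_ba", "F_ba": "F_ab", "SS": "SS", "PP": "PP"}[cls]
        return cls
    return cls


def cyclic_distance(seq: str, truth: str) -> int:
    """Edit distance of seq to its best placement on the doubled truth."""
    if not seq or not truth:
        return max(len(seq), len(truth))
    return edlib.align(seq, truth + truth, mode="HW",
                       task="distance")["editDistance"]


def cyclic_identity(seq: str, truth: str) -> float:
    """Identity of seq against truth as a cyclic sequence, strand-agnostic."""
    d = min(cyclic_distance(seq, truth), cyclic_distance(revcomp(seq), truth))
    return 1.0 - d / len(seq)


def cyclic_equal(seq: str, truth: str) -> bool:
    """Exact cyclic equality up to strand."""
    if len(seq) != len(truth):
        return False
    return seq in truth + truth or revcomp(seq) in truth + truth
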