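"""Thin alignment layer over edlib plus k-mer seeding utilities.

edlib supplies banded edit-distance alignment in three modes (global,
prefix-anchored, infix); everything above that — seeding, diagonal
clustering, identity bookkeeping from extended CIGARs — lives here and is
shared by the mapper, the assembler, the contig filters and annotation
transfer.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass

import edlib

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class AlignmentStats:
    """Summary of one pairwise alignment.

    identity is matches / alignment columns; ``max_indel`` is the longest
    single insertion or deletion run (used to spot structural disagreement).
    """

    matches: int
    columns: int
    query_consumed: int
    target_consumed: int
    max_indel: int
    insertions: int = 0
    deletions: int = 0

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def aligned_query(self) -> int:
        """Query bases sitting in match/mismatch columns."""
        return self.columns - self.insertions - self.deletions


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG_RE.findall(cigar)]


def cigar_stats(cigar: str) -> AlignmentStats:
    matches = columns = qc = tc = max_indel = ins = dels = 0
    for n, op in parse_cigar(cigar):
        columns += n
        if op == "=":
            matches += n
            qc += n
            tc += n
        elif op in ("X", "M"):
            qc += n
            tc += n
        elif op == "I":  # consumes query only
            qc += n
            ins += n
            max_indel = max(max_indel, n)
        elif op == "D":  # consumes target only
            tc += n
            dels += n
            max_indel = max(max_indel, n)
    return AlignmentStats(matches, columns, qc, tc, max_indel, ins, dels)


@dataclass
class Alignment:
    """A located edlib alignment of query against target."""

    t_start: int   # 0-based half-open on target
    t_end: int
    distance: int
    cigar: str
    stats: AlignmentStats

    @property
    def identity(self) -> float:
        return self.stats.identity


def _run(query: str, target: str, mode: str) -> Alignment | None:
    if not query or not target:
        return None
    res = edlib.align(query, target, mode=mode, task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = res["locations"][0]
    start = 0 if start is None else start
    stats = cigar_stats(res["cigar"])
    return Alignment(start, end + 1, res["editDistance"], res["cigar"], stats)


def align_global(a: str, b: str) -> Alignment | None:
    """Needleman-Wunsch-style end-to-end alignment (mode NW)."""
    return _run(a, b, "NW")


def align_prefix(query: str, target: str) -> Alignment | None:
    """Anchor both starts; target end is free (mode SHW): suffix-prefix checks."""
    return _run(query, target, "SHW")


def align_infix(query: str, target: str) -> Alignment | None:
    """Best placement of the whole query inside the target (mode HW)."""
    return _run(query, target, "HW")


def seed_index(seq: str, k: int, max_occurrences: int = 64) -> dict[str, list[int]]:
    """Exact k-mer -> positions index; hyper-repetitive k-mers are dropped."""
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i:i + k]].append(i)
    return {
        kmer: pos for kmer, pos in index.items()
        if len(pos) <= max_occurrences and "N" not in kmer
    }


def seed_hits(query: str, index: dict[str, list[int]], k: int,
              step: int = 1) -> list[tuple[int, int]]:
    """(query_pos, target_pos) pairs of exact k-mer matches."""
    hits = []
    for i in range(0, len(query) - k + 1, step):
        for j in index.get(query[i:i + k], ()):
            hits.append((i, j))
    return hits


def diagonal_clusters(hits: list[tuple[int, int]], band: int = 100
                      ) -> list[tuple[int, list[tuple[int, int]]]]:
    """Group seed hits by target-minus-query diagonal into +-band buckets.

    Returns (representative_diagonal, hits) sorted by descending support;
    the representative is the median diagonal of the bucket. Deterministic.
    """
    buckets: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for q, t in hits:
        buckets[(t - q) // band].append((q, t))
    merged: dict[int, list[tuple[int, int]]] = {}
    seen = set()
    for b in sorted(buckets):
        if b in seen:
            continue
        group = list(buckets[b])
        if b + 1 in buckets:
            group += buckets[b + 1]
            seen.add(b + 1)
        merged[b] = group
    out = []
    for b, group in merged.items():
        diags = sorted(t - q for q, t in group)
        rep = diags[len(diags) // 2]
        out.append((rep, sorted(group)))
    out.sort(key=lambda x: (-len(x[1]), x[0]))
    return out
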