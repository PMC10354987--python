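"""Terminal-redundancy detection and trimming.

A contig assembled from a circular molecule carries a duplicated stretch:
its end repeats its start. The redundancy is located by shared k-mer
diagonals between a prefix window and a suffix window, then verified by
global alignment of the implied copies. A contig is circular iff the
redundancy is strictly longer than ``circular_size`` (default 220 bp) at
identity >= 0.99; the suffix copy is then trimmed, iteratively (a tandem
double redundancy needs two rounds; capped at three).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import align_global, diagonal_clusters, seed_hits, seed_index
from .config import PipelineConfig
from .records import SequenceRecord
from .assemble import DraftContig
from .io import write_tsv

_WINDOW_CAP = 30_000
_SEED_K = 15


@dataclass
class CircularityResult:
    contig_id: str
    is_circular: bool
    overlap_len: int = 0
    prefix_interval: tuple[int, int] = (0, 0)
    suffix_interval: tuple[int, int] = (0, 0)
    identity: float = 0.0
    trimmed: bool = False
    reason: str = ""


def detect_terminal_redundancy(contig: SequenceRecord | DraftContig,
                               config: PipelineConfig | None = None
                               ) -> CircularityResult:
    """Best prefix-window/suffix-window self-overlap of one contig."""
    config = config or PipelineConfig()
    bases = contig.bases
    n = len(bases)
    if n <= 2 * config.circular_size:
        return CircularityResult(contig.id, False, reason="too short")
    w = min(n // 2, _WINDOW_CAP)
    prefix = bases[:w]
    suffix = bases[n - w:]
    k = min(_SEED_K, max(8, config.circular_size // 4))
    index = seed_index(prefix, k)
    hits = seed_hits(suffix, index, k)  # (suffix_local_pos, prefix_pos)
    best: CircularityResult | None = None
    for diag, cl_hits in diagonal_clusters(hits)[:3]:
        if len(cl_hits) < 2:
            continue
        # suffix-window position s matches prefix position s + diag, and the
        # redundant copy runs to the contig end: contig[n-r:] ~ contig[:r]
        # with r = w + diag
        r = w + diag
        if r <= 0 or r > n - 1:
            continue
        a = bases[:r]
        b = bases[n - r:]
        aln = align_global(b, a)
        if aln is None:
            continue
        ident = aln.identity
        res = CircularityResult(
            contig.id,
            is_circular=(r > config.circular_size
                         and ident >= config.circular_min_identity),
            overlap_len=r,
            prefix_interval=(0, r),
            suffix_interval=(n - r, n),
            identity=round(ident, 6),
        )
        if res.is_circular and (best is None or r > best.overlap_len):
            best = res
        elif best is None:
            best = res
    if best is None:
        return CircularityResult(contig.id, False, reason="no self-overlap")
    if not best.is_circular and not best.reason:
        best.reason = ("below circular-size threshold"
                       if best.overlap_len <= config.circular_size
                       else "below identity threshold")
    return best


def trim_redundancy(contig: SequenceRecord | DraftContig,
                    result: CircularityResult,
                    config: PipelineConfig | None = None,
                    max_rounds: int = 3) -> DraftContig:
    """Remove the suffix copy; re-detect and repeat until convergence."""
    if not result.is_circular:
        raise ValueError(f"{contig.id}: not circular, nothing to trim")
    config = config or PipelineConfig()
    support = getattr(contig, "supporting_read_ids", [])
    bases = contig.bases
    res = result
    for _ in range(max_rounds):
        bases = bases[: len(bases) - res.overlap_len]
        trimmed = DraftContig(contig.id, bases, support, True)
        res = detect_terminal_redundancy(trimmed, config)
        if not res.is_circular:
            break
    return DraftContig(contig.id, bases, support, True)


def write_circularisation_report(results: list[CircularityResult], path,
                                 contig_lengths: dict[str, int] | None = None
                                 ) -> None:
    """all_contigs.circularisationCheck.txt; coordinates 1-based inclusive."""
    rows = []
    for r in results:
        rows.append({
            "contig_id": r.contig_id,
            "is_circular": r.is_circular,
            "overlap_len": r.overlap_len,
            "prefix_start": r.prefix_interval[0] + 1 if r.overlap_len else 0,
            "prefix_end": r.prefix_interval[1],
            "suffix_start": r.suffix_interval[0] + 1 if r.overlap_len else 0,
            "suffix_end": r.suffix_interval[1],
            "identity": r.identity,
            "trimmed_length": (
                (contig_lengths or {}).get(r.contig_id, "")
            ),
            "note": r.reason,
        })
    df = pd.DataFrame(rows, columns=["contig_id", "is_circular", "overlap_len",
                                     "prefix_start", "prefix_end",
                                     "suffix_start", "suffix_end", "identity",
                                     "trimmed_length", "note"])
    write_tsv(df, path)
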