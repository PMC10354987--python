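"""Recruit reads of plausible organellar origin.

Reads are mapped to the reference mitogenome concatenated to itself, so a
read that spans the origin of the circular reference still maps in one
piece. A read is recruited iff it has a primary mapping and is no longer
than ``max_read_len`` (default: the exact reference length) — longer reads
are likely NUMT-derived, carrying mitochondrial homology plus nuclear flank.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import align_infix, diagonal_clusters, seed_hits, seed_index
from .config import PipelineConfig
from .records import SequenceRecord, revcomp
from .io import write_tsv


@dataclass
class ReadMapping:
    """Primary placement of one read on the (doubled) reference."""

    read_id: str
    ref_start: int   # 0-based, < reference length after renormalization
    ref_end: int     # may exceed reference length when the read wraps
    read_start: int
    read_end: int
    strand: str
    identity: float
    mapq: int

    def __post_init__(self) -> None:
        assert self.ref_start < self.ref_end
        assert self.read_start < self.read_end
        assert 0.0 <= self.identity <= 1.0


@dataclass
class RecruitmentReport:
    n_input: int
    n_mapped: int
    n_length_excluded: int
    n_recruited: int


def map_reads(reads: list[SequenceRecord], reference: SequenceRecord,
              config: PipelineConfig | None = None,
              circular: bool = True) -> list[ReadMapping]:
    """Best single placement per read via k-mer seed, chain, banded extend."""
    config = config or PipelineConfig()
    k = config.seed_k
    if len(reference) < k:
        raise ValueError(f"reference shorter than seed size ({k} bp)")
    ref_len = len(reference)
    target = reference.bases + reference.bases if circular else reference.bases
    index = seed_index(target, k)
    step = max(1, k - 5)
    pad = 200

    mappings = []
    for read in reads:
        candidates = []  # (matches, strand, Alignment, window_offset)
        for strand in ("+", "-"):
            seq = read.bases if strand == "+" else revcomp(read.bases)
            hits = seed_hits(seq, index, k, step=step)
            if not hits:
                continue
            clusters = diagonal_clusters(hits)
            for diag, cl_hits in clusters[:2]:
                if len(cl_hits) < config.min_chain_seeds:
                    continue
                w0 = max(0, diag - pad)
                w1 = min(len(target), diag + len(seq) + pad)
                aln = align_infix(seq, target[w0:w1])
                if aln is None:
                    continue
                candidates.append((aln.stats.matches, strand, aln, w0))
        candidates = [c for c in candidates
                      if c[2].identity >= config.recruit_min_identity]
        if not candidates:
            continue
        candidates.sort(key=lambda c: (-c[0], c[1]))
        best = candidates[0]
        if len(candidates) > 1 and candidates[1][0] > 0:
            ratio = candidates[1][0] / best[0]
            mapq = max(0, min(60, int(60 * (1 - ratio))))
        else:
            mapq = 60
        matches, strand, aln, w0 = best
        ref_start = w0 + aln.t_start
        ref_end = w0 + aln.t_end
        if circular and ref_start >= ref_len:
            ref_start -= ref_len
            ref_end -= ref_len
        mappings.append(
            ReadMapping(read.id, ref_start, ref_end, 0, len(read), strand,
                        round(aln.identity, 6), mapq)
        )
    return mappings


def recruit_reads(reads: list[SequenceRecord], mappings: list[ReadMapping],
                  config: PipelineConfig, reference_length: int
                  ) -> tuple[list[SequenceRecord], RecruitmentReport]:
    """Keep mapped reads no longer than max_read_len; input order preserved."""
    max_len = config.resolved_max_read_len(reference_length)
    mapped_ids = {m.read_id for m in mappings}
    recruited, n_long = [], 0
    for read in reads:
        if read.id not in mapped_ids:
            continue
        if len(read) > max_len:  # strictly "more than" -> NUMT-like
            n_long += 1
            continue
        recruited.append(read)
    report = RecruitmentReport(
        n_input=len(reads),
        n_mapped=len(mapped_ids),
        n_length_excluded=n_long,
        n_recruited=len(recruited),
    )
    return recruited, report


def write_mappings_tsv(mappings: list[ReadMapping], path) -> None:
    df = pd.DataFrame(
        [
            {
                "read_id": m.read_id, "ref_start": m.ref_start,
                "ref_end": m.ref_end, "read_start": m.read_start,
                "read_end": m.read_end, "strand": m.strand,
                "identity": m.identity, "mapq": m.mapq,
            }
            for m in mappings
        ],
        columns=["read_id", "ref_start", "ref_end", "read_start", "read_end",
                 "strand", "identity", "mapq"],
    )
    write_tsv(df, path)
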