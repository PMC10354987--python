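"""Retain candidate contigs that look like whole mitogenomes.

Each contig is compared to the reference by local alignment blocks; a contig
survives iff (i) more than ``p_coverage`` percent of its length lies inside
merged match blocks, (ii) it is shorter than five times the reference
(long contigs are likely NUMTs; skipped in plant mode, where genuine
mitogenomes vary hugely in size), and (iii) it is longer than 80 percent of
the reference (shorter contigs are likely fragments). All three bounds are
strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import align_global, diagonal_clusters, seed_hits, seed_index
from .config import PipelineConfig
from .records import SequenceRecord, revcomp
from .io import write_tsv

_BLOCK_MIN_IDENTITY = 0.7
_CHAIN_GAP = 500


@dataclass
class ContigReferenceMatch:
    contig_id: str
    contig_len: int
    ref_len: int
    covered_fraction: float
    #: (contig interval, reference interval, strand, identity)
    blocks: list[tuple[tuple[int, int], tuple[int, int], str, float]] = field(
        default_factory=list)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def match_contig_to_reference(contig: SequenceRecord,
                              reference: SequenceRecord,
                              config: PipelineConfig | None = None
                              ) -> ContigReferenceMatch:
    """Local alignment blocks (both strands) merged on contig coordinates."""
    config = config or PipelineConfig()
    k = config.seed_k
    index = seed_index(reference.bases, k)
    blocks = []
    for strand in ("+", "-"):
        seq = contig.bases if strand == "+" else revcomp(contig.bases)
        hits = seed_hits(seq, index, k, step=max(1, k - 5))
        for _, cl_hits in diagonal_clusters(hits, band=_CHAIN_GAP):
            if len(cl_hits) < 2:
                continue
            # chain runs of seeds separated by at most _CHAIN_GAP on the contig
            runs: list[list[tuple[int, int]]] = []
            for q, t in cl_hits:
                if runs and q - runs[-1][-1][0] <= _CHAIN_GAP:
                    runs[-1].append((q, t))
                else:
                    runs.append([(q, t)])
            for run in runs:
                q0, t0 = run[0]
                q1, t1 = run[-1][0] + k, run[-1][1] + k
                if q1 - q0 < k:
                    continue
                aln = align_global(seq[q0:q1], reference.bases[t0:t1])
                ident = aln.identity if aln else 0.0
                if ident < _BLOCK_MIN_IDENTITY:
                    continue
                if strand == "+":
                    c_iv = (q0, q1)
                else:
                    c_iv = (len(contig) - q1, len(contig) - q0)
                blocks.append((c_iv, (t0, t1), strand, round(ident, 6)))
    covered = sum(e - s for s, e in _merge([b[0] for b in blocks]))
    return ContigReferenceMatch(
        contig.id, len(contig), len(reference),
        covered_fraction=round(covered / len(contig), 6),
        blocks=sorted(blocks),
    )


def filter_contigs(matches: list[ContigReferenceMatch],
                   config: PipelineConfig
                   ) -> tuple[list[str], list[dict]]:
    """Apply retention rules; every contig gets a verdict row."""
    retained, verdicts = [], []
    plant = config.taxon_mode == "plant"
    for m in matches:
        pass_cov = m.covered_fraction > config.p_coverage / 100.0
        pass_upper = True if plant else m.contig_len < 5 * m.ref_len
        pass_lower = m.contig_len > 0.8 * m.ref_len
        keep = pass_cov and pass_upper and pass_lower
        verdicts.append({
            "contig_id": m.contig_id,
            "contig_len": m.contig_len,
            "ref_len": m.ref_len,
            "covered_fraction": m.covered_fraction,
            "pass_coverage": pass_cov,
            "pass_max_length": pass_upper,
            "pass_min_length": pass_lower,
            "retained": keep,
        })
        if keep:
            retained.append(m.contig_id)
    return retained, verdicts


_VERDICT_COLUMNS = ["contig_id", "contig_len", "ref_len", "covered_fraction",
                    "pass_coverage", "pass_max_length", "pass_min_length",
                    "retained"]


def write_parsed_blast(verdicts: list[dict], all_path, filtered_path) -> None:
    """parsed_blast_all.txt (every contig) and parsed_blast.txt (retained)."""
    df = pd.DataFrame(verdicts, columns=_VERDICT_COLUMNS)
    write_tsv(df, all_path)
    write_tsv(df[df["retained"]].reset_index(drop=True), filtered_path)
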