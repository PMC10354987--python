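"""Rotation to the tRNA-Phe start, candidate ranking, and report emission.

By convention a mitogenome is published starting at the first base of the
tRNA-Phe (trnF) locus on the plus strand. When no candidate carries trnF,
the tRNA present on the most candidates anchors the rotation instead.

The representative genome is chosen among candidates sorted by number of
genes annotated in relation to the reference: the first that is circular
(A), of a size similar to the reference (B), and free of gene frameshifts
(C) wins; failing that, the best circular candidate also satisfying B, then
one satisfying C, then any circular one; with nothing circular the
top-ranked candidate is selected under a prominent warning.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneCall
from .config import PipelineConfig
from .records import (AnnotationSet, FeatureRecord, ORIGIN_SPANNING,
                      SequenceRecord, normalize_gene_name, revcomp)
from .recruit import map_reads
from . import io as fio


@dataclass
class ContigReport:
    """Per-candidate ledger row feeding contigs_stats.tsv."""

    contig_id: str
    length: int
    gene_count: int = 0
    missing_genes: int = 0
    frameshift_count: int = 0
    is_circular: bool = False
    circular_overlap_len: int = 0
    trimmed_length: int = 0
    covered_fraction: float = 0.0
    size_similar_to_ref: bool = False
    selection_rank: int = 0
    is_final: bool = False


def choose_rotation_anchor(annotations: dict[str, AnnotationSet]
                           ) -> str | None:
    """trnF if any contig has it, else the most widespread tRNA name."""
    if not annotations:
        raise ValueError("no annotated contigs")
    per_contig = {
        cid: {normalize_gene_name(f.name) for f in ann.of_kind("tRNA")}
        for cid, ann in annotations.items()
    }
    if any("trnF" in names for names in per_contig.values()):
        return "trnF"
    tally = Counter()
    for names in per_contig.values():
        tally.update(names)
    if not tally:
        return None
    return min(tally, key=lambda name: (-tally[name], name))


def _shift_feature(f: FeatureRecord, shift: int, L: int) -> FeatureRecord:
    start = (f.start - shift) % L
    length = len(f)
    quals = dict(f.qualifiers)
    quals.pop(ORIGIN_SPANNING, None)
    if start + length > L:
        quals[ORIGIN_SPANNING] = True
    g = GeneCall(seq_id=f.seq_id, kind=f.kind, start=start,
                 end=start + length, strand=f.strand, name=f.name,
                 qualifiers=quals)
    for attr in ("identity", "ref_length", "frameshift_flag", "notes"):
        if hasattr(f, attr):
            setattr(g, attr, getattr(f, attr))
    return g


def _flip_feature(f: FeatureRecord, L: int) -> FeatureRecord:
    start = (L - f.end) % L
    g = _shift_feature(f, 0, L)
    g.start, g.end = start, start + len(f)
    g.strand = "+" if f.strand == "-" else "-"
    return g


def rotate_contig(contig: SequenceRecord, annotation: AnnotationSet,
                  anchor: str) -> tuple[SequenceRecord, AnnotationSet]:
    """Cyclically permute a circular contig so the anchor gene starts at 0.

    If the anchor lies on the minus strand the contig is reverse-complemented
    first, so the anchor always ends up at position 0 on the plus strand.
    The cyclic sequence content is unchanged.
    """
    hits = annotation.by_name(anchor)
    if not hits:
        raise ValueError(f"anchor {anchor!r} not annotated on {contig.id}")
    feat = hits[0]
    L = len(contig)
    bases = contig.bases
    features = list(annotation.features)
    if feat.strand == "-":
        bases = revcomp(bases)
        features = [_flip_feature(f, L) for f in features]
        anchor_start = next(f.start for f in features
                            if normalize_gene_name(f.name)
                            == normalize_gene_name(anchor))
    else:
        anchor_start = feat.start
    rotated = bases[anchor_start:] + bases[:anchor_start]
    out_features = [_shift_feature(f, anchor_start, L) for f in features]
    rec = SequenceRecord(contig.id, rotated, contig.description)
    ann = AnnotationSet(contig.id, out_features,
                        genetic_code_id=annotation.genetic_code_id)
    return rec, ann


def rank_and_select(reports: list[ContigReport], ref_len: int,
                    config: PipelineConfig | None = None
                    ) -> tuple[str, list[str]]:
    """Pick the representative genome; returns (contig_id, warnings)."""
    if not reports:
        raise ValueError("no final mitogenome: empty candidate list")
    config = config or PipelineConfig()
    lo, hi = config.size_similarity
    for r in reports:
        r.size_similar_to_ref = lo * ref_len <= r.length <= hi * ref_len
    ranked = sorted(
        reports,
        key=lambda r: (-r.gene_count, abs(r.length - ref_len), r.contig_id),
    )
    for i, r in enumerate(ranked):
        r.selection_rank = i + 1
    warnings: list[str] = []

    def pick(pred):
        return next((r for r in ranked if pred(r)), None)

    winner = pick(lambda r: r.is_circular and r.size_similar_to_ref
                  and r.frameshift_count == 0)
    if winner is None:
        winner = pick(lambda r: r.is_circular and r.size_similar_to_ref)
    if winner is None:
        winner = pick(lambda r: r.is_circular and r.frameshift_count == 0)
    if winner is None:
        winner = pick(lambda r: r.is_circular)
        if winner is not None:
            warnings.append(
                f"{winner.contig_id}: circular but neither size-similar nor "
                "frameshift-free; inspect manually")
    if winner is None:
        winner = ranked[0]
        warnings.append(
            f"no circular candidate; selected top-ranked linear contig "
            f"{winner.contig_id} — treat as a draft")
    for r in reports:
        r.is_final = r.contig_id == winner.contig_id
    return winner.contig_id, warnings


def compute_coverage(recruited_reads: list[SequenceRecord],
                     contigs: list[tuple[SequenceRecord, bool]],
                     config: PipelineConfig | None = None
                     ) -> pd.DataFrame:
    """Per-base read depth over one or more target contigs.

    ``contigs`` holds (record, is_circular) pairs; all are concatenated into
    one mapping target so each read lands on its best-supported candidate.
    Alignments with mapq below ``cov_mapq_min`` are discarded.
    """
    config = config or PipelineConfig()
    frames = []
    for rec, circular in contigs:
        L = len(rec)
        depth = np.zeros(L, dtype=np.int64)
        if recruited_reads:
            mappings = map_reads(recruited_reads, rec, config,
                                 circular=circular)
            for m in mappings:
                if m.mapq < config.cov_mapq_min:
                    continue
                s, e = m.ref_start, m.ref_end
                if e <= L:
                    depth[s:e] += 1
                else:  # wrapped mapping on the doubled reference
                    depth[s:] += 1
                    depth[: e - L] += 1
        frames.append(pd.DataFrame({
            "contig_id": rec.id,
            "position": np.arange(1, L + 1),
            "depth": depth,
        }))
    return pd.concat(frames, ignore_index=True)


def render_coverage_plot(depth: pd.DataFrame, path) -> None:
    """Optional presentation layer; requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    for cid, sub in depth.groupby("contig_id"):
        ax.fill_between(sub["position"], sub["depth"], step="mid",
                        alpha=0.6, label=cid)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("read depth")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def emit_outputs(final_id: str,
                 contigs: dict[str, SequenceRecord],
                 annotations: dict[str, AnnotationSet],
                 reports: list[ContigReport],
                 reference_annotation: AnnotationSet,
                 outdir: str | os.PathLike,
                 reference_id: str = "",
                 genetic_code_id: int = 5) -> list[str]:
    """Write the final genome, per-candidate files and summary tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def _w(name):
        written.append(str(outdir / name))
        return outdir / name

    final_rec = contigs[final_id]
    final_out = SequenceRecord("final_mitogenome", final_rec.bases)
    fio.write_fasta([final_out], _w("final_mitogenome.fasta"))
    final_ann = annotations[final_id]
    renamed = AnnotationSet(
        "final_mitogenome",
        [_rename(f, "final_mitogenome") for f in final_ann.features],
        genetic_code_id=final_ann.genetic_code_id,
    )
    fio.write_genbank(final_out, renamed, _w("final_mitogenome.gb"))
    fio.write_gff3(renamed, _w("final_mitogenome.gff"),
                   seq_len=len(final_out))

    cdir = outdir / "potential_contigs"
    cdir.mkdir(exist_ok=True)
    for cid, rec in contigs.items():
        fio.write_fasta([rec], cdir / f"{cid}.fasta")
        fio.write_genbank(rec, annotations[cid], cdir / f"{cid}.gb")
        written.extend([str(cdir / f"{cid}.fasta"), str(cdir / f"{cid}.gb")])

    rows = [vars(r).copy() for r in sorted(reports,
                                           key=lambda r: r.selection_rank)]
    preamble = [f"reference: {reference_id}",
                f"genetic code: {genetic_code_id}"]
    fio.write_stats_table(
        [
            {
                "contig_id": r["contig_id"], "length": r["length"],
                "gene_count": r["gene_count"],
                "missing_genes": r["missing_genes"],
                "frameshift_count": r["frameshift_count"],
                "is_circular": r["is_circular"],
                "circular_overlap_len": r["circular_overlap_len"],
                "trimmed_length": r["trimmed_length"],
                "covered_fraction": r["covered_fraction"],
                "size_similar_to_ref": r["size_similar_to_ref"],
                "selection_rank": r["selection_rank"],
                "is_final": r["is_final"],
            }
            for r in rows
        ],
        _w("contigs_stats.tsv"), preamble)
    fio.write_shared_genes(reference_annotation, annotations,
                           _w("shared_genes.tsv"))
    return written


def _rename(f: FeatureRecord, seq_id: str) -> FeatureRecord:
    return FeatureRecord(seq_id, f.kind, f.start, f.end, f.strand, f.name,
                         dict(f.qualifiers))
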