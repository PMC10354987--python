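"""Readers and writers for FASTA/FASTQ, GenBank, GFF3 and the TSV reports.

Parsing of FASTA/FASTQ/GenBank is delegated to Biopython; this module owns
the conversion to the pipeline's internal convention (0-based half-open
coordinates, normalized gene names) and back (1-based inclusive on output).
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import (
    ORIGIN_SPANNING,
    AnnotationSet,
    FeatureRecord,
    SequenceRecord,
    normalize_gene_name,
)

_FEATURE_TYPES = ("CDS", "tRNA", "rRNA")


def sniff_format(path: str | os.PathLike) -> str:
    """Return 'fasta' or 'fastq' from the first non-blank character."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line.lstrip()[0]
                if first == ">":
                    return "fasta"
                if first == "@":
                    return "fastq"
                raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")
    raise ValueError(f"{path}: no sequences (empty file)")


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read FASTA or FASTQ (auto-detected); qualities are discarded."""
    fmt = sniff_format(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    except ValueError as exc:
        raise ValueError(f"{path}: parse error: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no sequences")
    return records


def write_fasta(records, path: str | os.PathLike, width: int = 60) -> None:
    """Write 60-column wrapped FASTA with LF line endings."""
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i:i + width] + "\n")


def _location_to_coords(feature: SeqFeature, seq_len: int):
    """GenBank location -> (start, end, strand, spans_origin) 0-based half-open."""
    loc = feature.location
    strand = "-" if loc.strand == -1 else "+"
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    starts = [int(p.start) for p in parts]
    ends = [int(p.end) for p in parts]
    if len(parts) == 2 and ends[0] == seq_len and starts[1] == 0:
        # join(a..L, 1..b): wraps the origin of a circular sequence
        return starts[0], seq_len + ends[1], strand, True
    if len(parts) == 2 and strand == "-" and ends[1] == seq_len and starts[0] == 0:
        return starts[1], seq_len + ends[0], strand, True
    start, end = min(starts), max(ends)
    if end > seq_len:
        raise ValueError(
            f"feature {feature.type} at {start}..{end} exceeds sequence length {seq_len}"
        )
    return start, end, strand, False


def read_genbank(path: str | os.PathLike) -> tuple[SequenceRecord, AnnotationSet]:
    """Read one GenBank flat-file record: sequence plus CDS/tRNA/rRNA features."""
    try:
        rec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise ValueError(f"{path}: no GenBank records") from None
    if len(rec.seq) == 0:
        raise ValueError(f"{path}: missing ORIGIN sequence")
    seq = SequenceRecord(rec.id or rec.name, str(rec.seq), rec.description)
    code_id = 5
    features = []
    for bf in rec.features:
        if bf.type not in _FEATURE_TYPES:
            continue
        start, end, strand, wraps = _location_to_coords(bf, len(rec.seq))
        name = bf.qualifiers.get("gene", bf.qualifiers.get("product", ["?"]))[0]
        quals = {}
        for key in ("gene", "product", "transl_table"):
            if key in bf.qualifiers:
                quals[key] = bf.qualifiers[key][0]
        if wraps:
            quals[ORIGIN_SPANNING] = True
        if "transl_table" in quals:
            code_id = int(quals["transl_table"])
        features.append(
            FeatureRecord(seq.id, bf.type, start, end, strand,
                          normalize_gene_name(name), quals)
        )
    return seq, AnnotationSet(seq.id, features, genetic_code_id=code_id)


def _coords_to_location(f: FeatureRecord, seq_len: int) -> SimpleLocation | CompoundLocation:
    strand = -1 if f.strand == "-" else 1
    if f.end <= seq_len:
        return SimpleLocation(f.start, f.end, strand)
    a = SimpleLocation(f.start, seq_len, strand)
    b = SimpleLocation(0, f.end - seq_len, strand)
    return CompoundLocation([b, a] if strand == -1 else [a, b])


def write_genbank(record: SequenceRecord, annotation: AnnotationSet,
                  path: str | os.PathLike) -> None:
    if annotation.seq_id != record.id:
        raise ValueError(
            f"annotation is for {annotation.seq_id!r}, record is {record.id!r}"
        )
    rec = BioSeqRecord(
        Seq(record.bases),
        id=record.id,
        name=record.id[:16].replace("|", "_"),
        description=record.description,
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for f in sorted(annotation.features, key=lambda x: (x.start, x.end)):
        quals = {"gene": [f.name]}
        if f.kind == "CDS":
            quals["transl_table"] = [str(annotation.genetic_code_id)]
        if "product" in f.qualifiers:
            quals["product"] = [f.qualifiers["product"]]
        rec.features.append(
            SeqFeature(_coords_to_location(f, len(record.bases)), type=f.kind,
                       qualifiers=quals)
        )
    SeqIO.write([rec], str(path), "genbank")


def write_gff3(annotation: AnnotationSet, path: str | os.PathLike,
               seq_len: int | None = None) -> None:
    """Emit GFF3 with 1-based inclusive coordinates.

    An origin-spanning feature is written as two lines sharing one ID, the
    standard flat representation of a wrap-around location.
    """
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(annotation.features):
            attrs = f"ID={f.name}.{i};Name={f.name}"
            if f.spans_origin and seq_len:
                segs = [(f.start + 1, seq_len), (1, f.end - seq_len)]
            else:
                segs = [(f.start + 1, f.end)]
            for s1, e1 in segs:
                fh.write(
                    "\t".join([
                        annotation.seq_id, "mitoloop", f.kind,
                        str(s1), str(e1), ".", f.strand, ".", attrs,
                    ]) + "\n"
                )


def write_tsv(df: pd.DataFrame, path: str | os.PathLike,
              preamble: list[str] | None = None) -> None:
    with open(path, "w", newline="\n") as fh:
        for line in preamble or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_stats_table(rows: list[dict], path: str | os.PathLike,
                      preamble: list[str] | None = None) -> None:
    """contigs_stats.tsv: one row per candidate contig."""
    columns = [
        "contig_id", "length", "gene_count", "missing_genes",
        "frameshift_count", "is_circular", "circular_overlap_len",
        "trimmed_length", "covered_fraction", "size_similar_to_ref",
        "selection_rank", "is_final",
    ]
    df = pd.DataFrame(rows, columns=columns)
    write_tsv(df, path, preamble)


def write_shared_genes(reference_annotation: AnnotationSet,
                       contig_annotations: dict[str, AnnotationSet],
                       path: str | os.PathLike) -> pd.DataFrame:
    """shared_genes.tsv: reference genes x contigs presence/absence matrix."""
    ref_genes = []
    for f in reference_annotation.of_kind("CDS", "rRNA", "tRNA"):
        name = normalize_gene_name(f.name)
        if name not in ref_genes:
            ref_genes.append(name)
    rows = []
    for gene in ref_genes:
        row = {"gene": gene}
        for cid, ann in contig_annotations.items():
            row[cid] = "present" if gene in set(ann.gene_names()) else "absent"
        rows.append(row)
    df = pd.DataFrame(rows, columns=["gene", *contig_annotations.keys()])
    write_tsv(df, path)
    return df
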