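"""End-to-end orchestration: reads (or contigs) in, final mitogenome out.

Stage order: recruit -> assemble -> filter -> circularize -> annotate ->
rotate -> select -> report. Starting from pre-assembled contigs skips
recruitment and assembly, and no coverage tables are produced (there are no
reads to map back).
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import io as fio
from .annotate import count_genes, transfer_features
from .assemble import accept_contigs, assemble
from .circular import (detect_terminal_redundancy, trim_redundancy,
                       write_circularisation_report)
from .config import PipelineConfig
from .filters import filter_contigs, match_contig_to_reference, write_parsed_blast
from .finalize import (ContigReport, choose_rotation_anchor, compute_coverage,
                       emit_outputs, rank_and_select, rotate_contig)
from .records import AnnotationSet, FeatureRecord, SequenceRecord
from .recruit import map_reads, recruit_reads, write_mappings_tsv

EXIT_NO_READS_RECRUITED = 3
EXIT_NO_CONTIGS_RETAINED = 4


class PipelineError(RuntimeError):
    def __init__(self, message: str, exit_code: int = 1):
        super().__init__(message)
        self.exit_code = exit_code


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    final_contig_id: str | None = None
    reports: list[ContigReport] = field(default_factory=list)
    recruitment: object | None = None


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_reference(ref_fasta, ref_gb):
    ref_seq = fio.read_fasta(ref_fasta)[0]
    gb_seq, gb_ann = fio.read_genbank(ref_gb)
    warnings = []
    if len(gb_seq) != len(ref_seq):
        warnings.append(
            f"reference FASTA ({len(ref_seq)} bp) and GenBank "
            f"({len(gb_seq)} bp) differ in length; using FASTA sequence")
    ann = AnnotationSet(
        ref_seq.id,
        [FeatureRecord(ref_seq.id, f.kind, f.start, f.end, f.strand, f.name,
                       dict(f.qualifiers)) for f in gb_ann.features],
        genetic_code_id=gb_ann.genetic_code_id,
    )
    return ref_seq, ann, warnings


def run_from_reads(reads_path, ref_fasta, ref_gb,
                   config: PipelineConfig | None = None,
                   outdir="mitoloop_out") -> RunManifest:
    reads = fio.read_fasta(reads_path)
    return _run(reads=reads, contigs_in=None, ref_fasta=ref_fasta,
                ref_gb=ref_gb, config=config, outdir=outdir,
                input_paths=[reads_path, ref_fasta, ref_gb])


def run_from_contigs(contigs_path, ref_fasta, ref_gb,
                     config: PipelineConfig | None = None,
                     outdir="mitoloop_out") -> RunManifest:
    contigs = fio.read_fasta(contigs_path)
    return _run(reads=None, contigs_in=contigs, ref_fasta=ref_fasta,
                ref_gb=ref_gb, config=config, outdir=outdir,
                input_paths=[contigs_path, ref_fasta, ref_gb])


def _run(reads, contigs_in, ref_fasta, ref_gb, config, outdir,
         input_paths) -> RunManifest:
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    for p in input_paths:
        manifest.inputs[str(p)] = _sha256(p)

    t0 = time.perf_counter()
    reference, ref_annotation, warn = _load_reference(ref_fasta, ref_gb)
    manifest.warnings.extend(warn)
    manifest.stage_seconds["load_reference"] = time.perf_counter() - t0

    recruited = None
    if reads is not None:
        t0 = time.perf_counter()
        mappings = map_reads(reads, reference, config, circular=True)
        recruited, report = recruit_reads(reads, mappings, config,
                                          len(reference))
        manifest.recruitment = report
        write_mappings_tsv(mappings, outdir / "reads.mappings.tsv")
        manifest.outputs.append(str(outdir / "reads.mappings.tsv"))
        if not recruited:
            raise PipelineError("no reads recruited against the reference",
                                EXIT_NO_READS_RECRUITED)
        fio.write_fasta(recruited, outdir / "gbk.HiFiMapped.bam.filtered.fasta")
        manifest.outputs.append(str(outdir / "gbk.HiFiMapped.bam.filtered.fasta"))
        manifest.stage_seconds["recruit"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        drafts = assemble(recruited, config)
        manifest.stage_seconds["assemble"] = time.perf_counter() - t0
    else:
        drafts = accept_contigs(contigs_in)

    t0 = time.perf_counter()
    matches = [
        match_contig_to_reference(
            SequenceRecord(d.id, d.bases), reference, config)
        for d in drafts
    ]
    retained_ids, verdicts = filter_contigs(matches, config)
    write_parsed_blast(verdicts, outdir / "parsed_blast_all.txt",
                       outdir / "parsed_blast.txt")
    manifest.outputs += [str(outdir / "parsed_blast_all.txt"),
                         str(outdir / "parsed_blast.txt")]
    if not retained_ids:
        raise PipelineError("no candidate contigs retained after filtering",
                            EXIT_NO_CONTIGS_RETAINED)
    match_by_id = {m.contig_id: m for m in matches}
    drafts = [d for d in drafts if d.id in set(retained_ids)]
    manifest.stage_seconds["filter"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    circ_results = []
    trimmed: dict[str, SequenceRecord] = {}
    circ_by_id = {}
    for d in drafts:
        res = detect_terminal_redundancy(d, config)
        circ_results.append(res)
        circ_by_id[d.id] = res
        if res.is_circular:
            t = trim_redundancy(d, res, config)
            trimmed[d.id] = SequenceRecord(d.id, t.bases)
        else:
            trimmed[d.id] = SequenceRecord(d.id, d.bases)
    write_circularisation_report(
        circ_results, outdir / "all_contigs.circularisationCheck.txt",
        {cid: len(rec) for cid, rec in trimmed.items()})
    manifest.outputs.append(str(outdir / "all_contigs.circularisationCheck.txt"))
    manifest.stage_seconds["circularize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    annotations: dict[str, AnnotationSet] = {}
    missing: dict[str, list[str]] = {}
    for cid in sorted(trimmed):
        ann, miss = transfer_features(
            reference, ref_annotation, trimmed[cid], config,
            contig_is_circular=circ_by_id[cid].is_circular)
        annotations[cid] = ann
        missing[cid] = miss
    manifest.stage_seconds["annotate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    anchor = choose_rotation_anchor(annotations)
    if anchor is None:
        manifest.warnings.append("no tRNA annotated on any contig; "
                                 "rotation skipped")
    else:
        for cid in sorted(trimmed):
            if not circ_by_id[cid].is_circular:
                continue
            if not annotations[cid].by_name(anchor):
                manifest.warnings.append(
                    f"{cid}: rotation anchor {anchor} absent; left unrotated")
                continue
            rec, ann = rotate_contig(trimmed[cid], annotations[cid], anchor)
            trimmed[cid], annotations[cid] = rec, ann
    manifest.stage_seconds["rotate"] = time.perf_counter() - t0

    counts, _shared = count_genes(annotations, ref_annotation)
    reports = []
    for cid in sorted(trimmed):
        ann = annotations[cid]
        frameshifts = sum(
            1 for f in ann.features if getattr(f, "frameshift_flag", False))
        res = circ_by_id[cid]
        reports.append(ContigReport(
            contig_id=cid,
            length=len(trimmed[cid]),
            gene_count=counts[cid],
            missing_genes=len(missing[cid]),
            frameshift_count=frameshifts,
            is_circular=res.is_circular,
            circular_overlap_len=res.overlap_len if res.is_circular else 0,
            trimmed_length=len(trimmed[cid]),
            covered_fraction=match_by_id[cid].covered_fraction,
        ))
    final_id, warnings = rank_and_select(reports, len(reference), config)
    manifest.warnings.extend(warnings)
    manifest.final_contig_id = final_id
    manifest.reports = reports

    if reads is not None:
        t0 = time.perf_counter()
        depth = compute_coverage(
            recruited, [(trimmed[final_id], circ_by_id[final_id].is_circular)],
            config)
        fio.write_tsv(depth, outdir / "final_mitogenome.coverage.tsv")
        all_depth = compute_coverage(
            recruited,
            [(SequenceRecord("all_candidates",
                             "".join(trimmed[cid].bases
                                     for cid in sorted(trimmed))), False)],
            config) if len(trimmed) > 1 else depth
        fio.write_tsv(all_depth, outdir / "contigs_coverage.tsv")
        manifest.outputs += [str(outdir / "final_mitogenome.coverage.tsv"),
                             str(outdir / "contigs_coverage.tsv")]
        manifest.stage_seconds["coverage"] = time.perf_counter() - t0

    written = emit_outputs(final_id, trimmed, annotations, reports,
                           ref_annotation, outdir,
                           reference_id=reference.id,
                           genetic_code_id=config.genetic_code_id)
    manifest.outputs += written

    manifest_path = outdir / "run_manifest.tsv"
    _write_manifest(manifest, manifest_path)
    manifest.outputs.append(str(manifest_path))
    return manifest


def _write_manifest(manifest: RunManifest, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("key\tvalue\n")
        for k, v in sorted(manifest.config.items()):
            fh.write(f"config.{k}\t{v}\n")
        for k, v in manifest.inputs.items():
            fh.write(f"input_sha256.{Path(k).name}\t{v}\n")
        fh.write(f"final_contig\t{manifest.final_contig_id}\n")
        for w in manifest.warnings:
            fh.write(f"warning\t{w}\n")
        for o in manifest.outputs:
            fh.write(f"output\t{Path(o).name}\n")
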