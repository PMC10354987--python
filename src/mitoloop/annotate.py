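"""Homology-based annotation transfer and frameshift flagging.

Every reference feature (CDS, rRNA, tRNA) is extracted in reading
orientation and aligned to the candidate contig on both strands; the best
placement passing identity and reference-coverage floors becomes a gene
call. A circular contig is searched as its doubled sequence so genes
spanning the origin are found intact. tRNAs and other short features use a
stricter identity floor plus an exact-seed requirement, because a 65-70 bp
query can reach deceptively high identity against random sequence.

A CDS call is flagged as frameshifted when its span length modulo 3
disagrees with the reference CDS, or when translation yields a stop codon
before 90 percent of the expected protein length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from .align import align_infix
from .config import PipelineConfig
from .records import (AnnotationSet, FeatureRecord, ORIGIN_SPANNING,
                      SequenceRecord, normalize_gene_name, revcomp)

SHORT_FEATURE = 100  # bp; below this the strict transfer floor applies
_SEED_K = 12


@dataclass
class GeneticCode:
    """An NCBI translation table as plain lookup maps."""

    table_id: int
    codons: dict[str, str]
    start_codons: frozenset
    stop_codons: frozenset

    @classmethod
    def from_table_id(cls, table_id: int) -> "GeneticCode":
        try:
            table = CodonTable.unambiguous_dna_by_id[table_id]
        except KeyError:
            raise ValueError(f"unsupported genetic code table {table_id}") from None
        codons = dict(table.forward_table)
        for stop in table.stop_codons:
            codons[stop] = "*"
        if len(codons) != 64:
            raise ValueError(f"table {table_id} does not map all 64 codons")
        return cls(table_id, codons,
                   frozenset(table.start_codons), frozenset(table.stop_codons))

    def translate(self, seq: str) -> str:
        n = len(seq) - len(seq) % 3
        return "".join(
            self.codons.get(seq[i:i + 3], "X") for i in range(0, n, 3)
        )


@dataclass
class GeneCall(FeatureRecord):
    """A transferred feature with its homology evidence."""

    identity: float = 0.0
    ref_length: int = 0
    frameshift_flag: bool = False
    notes: str = ""


def _place(query: str, target: str) -> tuple[str, object] | None:
    best = None
    for strand, q in (("+", query), ("-", revcomp(query))):
        aln = align_infix(q, target)
        if aln is None:
            continue
        if best is None or aln.stats.matches > best[1].stats.matches:
            best = (strand, aln, q)
    return best


def transfer_features(reference_record: SequenceRecord,
                      reference_annotation: AnnotationSet,
                      contig: SequenceRecord,
                      config: PipelineConfig | None = None,
                      contig_is_circular: bool = False
                      ) -> tuple[AnnotationSet, list[str]]:
    """Best homologous placement of each reference feature on the contig.

    Returns the annotation (GeneCall features) and the names of reference
    genes that could not be placed.
    """
    config = config or PipelineConfig()
    if not reference_annotation.features:
        raise ValueError("reference annotation is empty")
    L = len(contig)
    target = contig.bases + contig.bases if contig_is_circular else contig.bases
    code = GeneticCode.from_table_id(config.genetic_code_id)

    calls: list[FeatureRecord] = []
    missing: list[str] = []
    best_by_gene: dict[str, GeneCall] = {}
    for ref_feat in reference_annotation.of_kind("CDS", "rRNA", "tRNA"):
        gene_seq = ref_feat.extract(reference_record.bases)
        placed = _place(gene_seq, target)
        ok = False
        if placed is not None:
            strand, aln, oriented_q = placed
            floor = (config.transfer_min_identity_short
                     if len(gene_seq) < SHORT_FEATURE
                     else config.transfer_min_identity)
            coverage = aln.stats.aligned_query / len(gene_seq)
            ok = (aln.identity >= floor
                  and coverage >= config.transfer_min_ref_coverage)
            if ok and len(gene_seq) < SHORT_FEATURE:
                window = target[aln.t_start:aln.t_end]
                ok = any(oriented_q[i:i + _SEED_K] in window
                         for i in range(0, len(oriented_q) - _SEED_K + 1, 4))
        name = normalize_gene_name(ref_feat.name)
        if not ok:
            if name not in best_by_gene:
                missing.append(name)
            continue
        start, end = aln.t_start, aln.t_end
        quals = dict(ref_feat.qualifiers)
        quals.pop(ORIGIN_SPANNING, None)
        if contig_is_circular and start >= L:
            start -= L
            end -= L
        if end > L:
            quals[ORIGIN_SPANNING] = True
        call = GeneCall(
            seq_id=contig.id, kind=ref_feat.kind, start=start, end=end,
            strand=strand, name=name, qualifiers=quals,
            identity=round(aln.identity, 6), ref_length=len(ref_feat),
        )
        if call.kind == "CDS":
            call.frameshift_flag = detect_frameshift(call, contig.bases, code)
        prev = best_by_gene.get(name)
        if prev is None or call.identity > prev.identity:
            if prev is None and name in missing:
                missing.remove(name)
            best_by_gene[name] = call

    calls = list(best_by_gene.values())
    # genes sharing a placement resolve to the higher-identity call only
    annotation = AnnotationSet(contig.id, calls,
                               genetic_code_id=config.genetic_code_id)
    return annotation, sorted(dict.fromkeys(missing))


def detect_frameshift(gene_call: GeneCall, contig_bases: str,
                      genetic_code: GeneticCode) -> bool:
    """Frame disruption: length-mod-3 disagreement or premature stop."""
    if gene_call.kind != "CDS":
        raise ValueError("frameshift detection applies to CDS features only")
    if gene_call.ref_length and len(gene_call) % 3 != gene_call.ref_length % 3:
        return True
    seq = gene_call.extract(contig_bases)
    protein = genetic_code.translate(seq)
    expected_aa = (gene_call.ref_length or len(gene_call)) // 3
    stop = protein.find("*")
    if stop != -1 and stop < 0.9 * expected_aa:
        return True
    return False


def count_genes(annotation_sets: dict[str, AnnotationSet],
                reference_annotation: AnnotationSet
                ) -> tuple[dict[str, int], pd.DataFrame]:
    """Per-contig gene counts and the reference-gene presence matrix."""
    counts = {
        cid: len(ann.of_kind("CDS", "rRNA", "tRNA"))
        for cid, ann in annotation_sets.items()
    }
    ref_genes = list(dict.fromkeys(
        normalize_gene_name(f.name)
        for f in reference_annotation.of_kind("CDS", "rRNA", "tRNA")
    ))
    rows = []
    for gene in ref_genes:
        row = {"gene": gene}
        for cid, ann in annotation_sets.items():
            row[cid] = gene in set(ann.gene_names())
        rows.append(row)
    matrix = pd.DataFrame(rows, columns=["gene", *annotation_sets.keys()])
    return counts, matrix
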