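"""Rotation anchoring, representative selection, and coverage accounting."""

import itertools

import numpy as np
import pytest

from conftest import random_dna
from mitoloop.annotate import transfer_features
from mitoloop.config import PipelineConfig
from mitoloop.finalize import (ContigReport, choose_rotation_anchor,
                               compute_coverage, emit_outputs,
                               rank_and_select, rotate_contig)
from mitoloop.records import AnnotationSet, FeatureRecord, SequenceRecord
from mitoloop.simulate import simulate_mitogenome
from mitoloop import io as fio


def _trna_set(cid, names):
    feats = [FeatureRecord(cid, "tRNA", 10 + 100 * i, 80 + 100 * i, "+", n)
             for i, n in enumerate(names)]
    return AnnotationSet(cid, feats)


def test_anchor_is_trnf_when_present():
    anns = {"c1": _trna_set("c1", ["trnF", "trnM"]),
            "c2": _trna_set("c2", ["trnM"])}
    assert choose_rotation_anchor(anns) == "trnF"


def test_anchor_falls_back_to_most_frequent_trna():
    anns = {f"c{i}": _trna_set(f"c{i}", ["trnM", "trnW"] if i == 0
                               else ["trnM"]) for i in range(4)}
    assert choose_rotation_anchor(anns) == "trnM"


def test_anchor_absent_when_no_trnas():
    anns = {"c1": AnnotationSet("c1", [
        FeatureRecord("c1", "CDS", 0, 90, "+", "COX1")])}
    assert choose_rotation_anchor(anns) is None


@pytest.fixture(scope="module")
def truth13k():
    return simulate_mitogenome(length=13_000, genetic_code_id=5, seed=29)


def test_rotation_moves_plus_strand_anchor_to_zero(truth13k):
    t = truth13k
    ann, _ = transfer_features(t.mito, t.annotation, t.mito)
    anchor = next(f for f in ann.of_kind("tRNA") if f.strand == "+")
    rec, rot_ann = rotate_contig(t.mito, ann, anchor.name)
    s = anchor.start
    assert rec.bases == t.mito.bases[s:] + t.mito.bases[:s]
    moved = rot_ann.by_name(anchor.name)[0]
    assert (moved.start, moved.strand) == (0, "+")


def test_rotation_of_minus_strand_anchor_reverse_complements(truth13k):
    t = truth13k
    ann, _ = transfer_features(t.mito, t.annotation, t.mito)
    anchor = next(f for f in ann.of_kind("tRNA") if f.strand == "-")
    rec, rot_ann = rotate_contig(t.mito, ann, anchor.name)
    moved = rot_ann.by_name(anchor.name)[0]
    assert (moved.start, moved.strand) == (0, "+")
    # oracle: re-transferring the reference onto the rotated sequence places
    # the anchor at the origin on the plus strand
    fresh, _ = transfer_features(t.mito, t.annotation, rec,
                                 contig_is_circular=True)
    check = fresh.by_name(anchor.name)[0]
    assert (check.start, check.strand) == (0, "+")
    # cyclic content is unchanged (up to strand)
    from oracles import cyclic_equal
    assert cyclic_equal(rec.bases, t.mito.bases)


def test_rotation_preserves_all_gene_lengths(truth13k):
    t = truth13k
    ann, _ = transfer_features(t.mito, t.annotation, t.mito)
    rec, rot_ann = rotate_contig(t.mito, ann, "trnF")
    assert sorted((f.name, len(f)) for f in rot_ann) == \
           sorted((f.name, len(f)) for f in ann)


def _report(cid, genes=37, length=16_000, circular=True, frameshifts=0):
    return ContigReport(contig_id=cid, length=length, gene_count=genes,
                        frameshift_count=frameshifts, is_circular=circular)


REF_LEN = 16_000


def test_selection_prefers_full_criteria():
    x = _report("X", genes=37, length=16_160, circular=True)
    y = _report("Y", genes=37, circular=False)
    final, warnings = rank_and_select([x, y], REF_LEN)
    assert final == "X" and not warnings
    assert x.is_final and not y.is_final


def test_fallback_prefers_size_over_frameshift_free():
    z = _report("Z", length=16_000, circular=True, frameshifts=1)
    w = _report("W", length=40_000, circular=True, frameshifts=0)
    final, _ = rank_and_select([z, w], REF_LEN)
    assert final == "Z"  # circular+size (A, B) outranks circular+clean (A, C)


def test_single_linear_candidate_selected_with_warning():
    lin = _report("L", circular=False)
    final, warnings = rank_and_select([lin], REF_LEN)
    assert final == "L"
    assert any("linear" in w for w in warnings)


def test_empty_candidate_list_is_an_error():
    with pytest.raises(ValueError, match="no final mitogenome"):
        rank_and_select([], REF_LEN)


def test_selection_is_invariant_to_input_order():
    reports = [
        _report("A", genes=35, circular=True),
        _report("B", genes=37, circular=True, frameshifts=1),
        _report("C", genes=37, length=17_000, circular=True),
        _report("D", genes=37, circular=False),
    ]
    results = set()
    for perm in itertools.permutations(reports):
        fresh = [ContigReport(**vars(r)) for r in perm]
        final, _ = rank_and_select(fresh, REF_LEN)
        results.add(final)
    assert results == {"C"}


def test_coverage_conserves_aligned_bases():
    rng = np.random.default_rng(91)
    genome = SequenceRecord("g", random_dna(rng, 8_000))
    reads = [SequenceRecord(f"r{i}", genome.bases[s:s + 2_000])
             for i, s in enumerate(range(0, 6_000, 600))]
    depth = compute_coverage(reads, [(genome, False)])
    assert depth["depth"].sum() == sum(len(r) for r in reads)


def test_mapq_floor_above_all_mappings_zeroes_depth():
    rng = np.random.default_rng(92)
    genome = SequenceRecord("g", random_dna(rng, 8_000))
    reads = [SequenceRecord("r0", genome.bases[1_000:4_000])]
    depth = compute_coverage(reads, [(genome, False)],
                             PipelineConfig(cov_mapq_min=61))
    assert depth["depth"].sum() == 0


def test_emit_outputs_smoke_and_rerun_byte_identical(tmp_path, truth13k):
    t = truth13k
    ann, _ = transfer_features(t.mito, t.annotation, t.mito)
    contig = SequenceRecord("contig_1", t.mito.bases)
    ann = AnnotationSet("contig_1",
                        [FeatureRecord("contig_1", f.kind, f.start, f.end,
                                       f.strand, f.name, dict(f.qualifiers))
                         for f in ann.features])
    report = _report("contig_1", genes=len(ann.features),
                     length=len(contig))
    rank_and_select([report], len(t.mito))
    outputs = {}
    for sub in ("a", "b"):
        outdir = tmp_path / sub
        emit_outputs("contig_1", {"contig_1": contig}, {"contig_1": ann},
                     [report], t.annotation, outdir, reference_id="ref")
        outputs[sub] = {
            p.name: p.read_bytes()
            for p in sorted(outdir.rglob("*")) if p.is_file()
        }
    assert outputs["a"] == outputs["b"]
    names = set(outputs["a"])
    assert {"final_mitogenome.fasta", "final_mitogenome.gb",
            "contigs_stats.tsv", "shared_genes.tsv"} <= names
    # everything emitted parses back
    rec = fio.read_fasta(tmp_path / "a" / "final_mitogenome.fasta")[0]
    assert rec.bases == t.mito.bases
    stats = (tmp_path / "a" / "contigs_stats.tsv").read_text()
    assert "True" in stats.splitlines()[-1]  # final flag on its row
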