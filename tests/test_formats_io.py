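"""Format round-trips and coordinate-convention boundaries."""

import pytest
from hypothesis import given, settings, strategies as st

from mitoloop import io as fio
from mitoloop.records import (AnnotationSet, FeatureRecord, SequenceRecord,
                              normalize_gene_name)

DNA = st.text(alphabet="ACGTacgtu", min_size=1, max_size=300)


def test_fasta_reads_and_normalizes(tmp_path):
    p = tmp_path / "x.fasta"
    p.write_text(">r1 a read\nacgt\n>r2\nACGUacgu\n")
    recs = fio.read_fasta(p)
    assert [(r.id, r.bases) for r in recs] == [("r1", "ACGT"),
                                               ("r2", "ACGTACGT")]
    assert recs[0].description == "a read"


def test_fastq_equals_fasta_of_same_sequences(tmp_path):
    fq = tmp_path / "x.fastq"
    fq.write_text("@r1\nACGTACGT\n+\nIIIIIIII\n")
    fa = tmp_path / "x.fasta"
    fa.write_text(">r1\nACGTACGT\n")
    assert [(r.id, r.bases) for r in fio.read_fasta(fq)] == \
           [(r.id, r.bases) for r in fio.read_fasta(fa)]


def test_empty_file_raises_no_sequences(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    with pytest.raises(ValueError, match="no sequences"):
        fio.read_fasta(p)


@settings(max_examples=25, deadline=None)
@given(st.lists(DNA, min_size=1, max_size=5))
def test_fasta_round_trip_preserves_sequences(tmp_path_factory, seqs):
    tmp = tmp_path_factory.mktemp("rt")
    records = [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
    fio.write_fasta(records, tmp / "x.fasta")
    back = fio.read_fasta(tmp / "x.fasta")
    assert [(r.id, r.bases) for r in back] == \
           [(r.id, r.bases) for r in records]


GB_TEXT = """LOCUS       testrec                  200 bp    DNA     circular INV 01-JAN-2024
DEFINITION  test record.
ACCESSION   testrec
FEATURES             Location/Qualifiers
     tRNA            1..68
                     /gene="trnF"
     CDS             complement(100..160)
                     /gene="ND1"
                     /transl_table=5
ORIGIN
        1 {seq}
//
"""


def _gb_fixture(tmp_path):
    import textwrap
    seq = ("acgt" * 50)
    lines = []
    for i in range(0, 200, 60):
        chunk = seq[i:i + 60]
        grouped = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {grouped}")
    text = GB_TEXT.replace("        1 {seq}", "\n".join(lines))
    p = tmp_path / "ref.gb"
    p.write_text(text)
    return p


def test_genbank_coordinates_are_zero_based_half_open(tmp_path):
    rec, ann = fio.read_genbank(_gb_fixture(tmp_path))
    assert len(rec) == 200
    trna = ann.by_name("trnF")[0]
    assert (trna.start, trna.end, trna.strand) == (0, 68, "+")
    cds = ann.by_name("NAD1")[0]  # /gene="ND1" normalized
    assert (cds.start, cds.end, cds.strand) == (99, 160, "-")
    assert ann.genetic_code_id == 5


def test_genbank_round_trip(tmp_path):
    rec, ann = fio.read_genbank(_gb_fixture(tmp_path))
    out = tmp_path / "out.gb"
    fio.write_genbank(rec, ann, out)
    rec2, ann2 = fio.read_genbank(out)
    assert rec2.bases == rec.bases
    assert [(f.kind, f.start, f.end, f.strand, f.name) for f in ann2] == \
           [(f.kind, f.start, f.end, f.strand, f.name) for f in ann]


def test_genbank_origin_spanning_feature_round_trip(tmp_path):
    rec = SequenceRecord("circ", "ACGT" * 100)
    feat = FeatureRecord("circ", "tRNA", 380, 430, "+", "trnF",
                         {"origin_spanning": True})
    ann = AnnotationSet("circ", [feat])
    fio.write_genbank(rec, ann, tmp_path / "c.gb")
    rec2, ann2 = fio.read_genbank(tmp_path / "c.gb")
    f = ann2.features[0]
    assert (f.start, f.end) == (380, 430)
    assert f.spans_origin


def test_write_genbank_rejects_mismatched_ids(tmp_path):
    rec = SequenceRecord("a", "ACGT" * 20)
    ann = AnnotationSet("b", [])
    with pytest.raises(ValueError):
        fio.write_genbank(rec, ann, tmp_path / "x.gb")


def test_gff3_emits_one_based_inclusive(tmp_path):
    ann = AnnotationSet("c1", [
        FeatureRecord("c1", "tRNA", 0, 68, "+", "trnF"),
        FeatureRecord("c1", "CDS", 99, 160, "-", "NAD1"),
    ])
    fio.write_gff3(ann, tmp_path / "x.gff")
    lines = (tmp_path / "x.gff").read_text().splitlines()
    assert lines[0] == "##gff-version 3"
    cols = lines[1].split("\t")
    assert cols[3:5] == ["1", "68"]
    cols2 = lines[2].split("\t")
    assert cols2[3:5] == ["100", "160"] and cols2[6] == "-"


def test_gff3_empty_annotation_is_header_only(tmp_path):
    fio.write_gff3(AnnotationSet("c1", []), tmp_path / "e.gff")
    assert (tmp_path / "e.gff").read_text() == "##gff-version 3\n"


@pytest.mark.parametrize("raw,expected", [
    ("COI", "COX1"), ("CO1", "COX1"), ("COX1", "COX1"), ("COIII", "COX3"),
    ("ND4L", "NAD4L"), ("nad2", "NAD2"), ("CYB", "CYTB"), ("COB", "CYTB"),
    ("ATPase6", "ATP6"), ("tRNA-Phe", "trnF"), ("trnF", "trnF"),
    ("TRNA-LEU2", "trnL2"), ("12S rRNA", "rrnS"), ("16S", "rrnL"),
    ("unknown-orf", "unknown-orf"),
])
def test_gene_name_normalization(raw, expected):
    assert normalize_gene_name(raw) == expected


def test_shared_genes_marks_presence(tmp_path):
    ref = AnnotationSet("ref", [
        FeatureRecord("ref", "CDS", i * 100, i * 100 + 90, "+", n)
        for i, n in enumerate(["COX1", "COX2", "NAD1"])
    ])
    full = AnnotationSet("cA", [
        FeatureRecord("cA", "CDS", i * 100, i * 100 + 90, "+", n)
        for i, n in enumerate(["COX1", "COX2", "NAD1"])
    ])
    partial = AnnotationSet("cB", [
        FeatureRecord("cB", "CDS", 0, 90, "+", "COX1")])
    df = fio.write_shared_genes(ref, {"cA": full, "cB": partial},
                                tmp_path / "sg.tsv")
    assert list(df["cA"]) == ["present"] * 3
    assert list(df["cB"]) == ["present", "absent", "absent"]


def test_stats_table_degenerate_and_passthrough(tmp_path):
    fio.write_stats_table([], tmp_path / "empty.tsv")
    text = (tmp_path / "empty.tsv").read_text()
    assert text.startswith("contig_id\t") and len(text.splitlines()) == 1
    fio.write_stats_table(
        [{"contig_id": "c1", "length": 16000, "is_circular": True,
          "circular_overlap_len": 221}],
        tmp_path / "one.tsv")
    row = (tmp_path / "one.tsv").read_text().splitlines()[1].split("\t")
    assert "True" in row and "221" in row
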