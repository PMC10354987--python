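"""Overlap detection, greedy layout, consensus, and the DP overlap oracle."""

import numpy as np
import pytest

from conftest import random_dna
from oracles import cyclic_equal, oracle_overlaps, overlap_class
from mitoloop.assemble import (accept_contigs, assemble, call_consensus,
                               compute_overlaps, greedy_layout)
from mitoloop.circular import detect_terminal_redundancy, trim_redundancy
from mitoloop.config import PipelineConfig
from mitoloop.records import SequenceRecord, revcomp


def test_minimal_suffix_prefix_overlap():
    reads = [SequenceRecord("a", "AAAACCCCGGTA"),
             SequenceRecord("b", "CCCCGGTATTTT")]
    ovs = compute_overlaps(reads, min_overlap=8, min_identity=1.0)
    dovetails = [o for o in ovs if not o.is_containment]
    assert len(dovetails) == 1
    ov = dovetails[0]
    assert (ov.a_id, ov.b_id, ov.orientation) == ("a", "b", "forward")
    assert ov.overlap_len == 8 and ov.identity == 1.0 and ov.a_hang == 4


def test_identical_reads_flagged_as_containment():
    seq = random_dna(np.random.default_rng(0), 500)
    reads = [SequenceRecord("a", seq), SequenceRecord("b", seq)]
    ovs = compute_overlaps(reads, min_overlap=100, min_identity=0.99)
    assert any(o.is_containment and o.contained_id == "b" for o in ovs)


def test_opposite_strand_reads_overlap_in_reverse_orientation():
    genome = random_dna(np.random.default_rng(5), 2_000)
    reads = [SequenceRecord("a", genome[:1_200]),
             SequenceRecord("b", revcomp(genome[800:2_000]))]
    ovs = compute_overlaps(reads, min_overlap=200, min_identity=0.99)
    assert any(o.orientation == "reverse" and not o.is_containment
               for o in ovs)


def test_duplicate_read_ids_rejected():
    r = SequenceRecord("a", "ACGT" * 100)
    with pytest.raises(ValueError, match="duplicate"):
        compute_overlaps([r, r], 50, 0.99)


def test_single_read_yields_one_linear_contig_equal_to_it():
    read = SequenceRecord("solo", random_dna(np.random.default_rng(2), 3_000))
    (contig,) = assemble([read], PipelineConfig())
    assert contig.bases == read.bases
    assert not contig.layout_is_cyclic
    assert contig.supporting_read_ids == ["solo"]


def test_consensus_majority_corrects_lone_substitution():
    seq = random_dna(np.random.default_rng(9), 2_000)
    variant = seq[:1_000] + ("A" if seq[1_000] != "A" else "C") + seq[1_001:]
    reads = [SequenceRecord(f"r{i}", seq) for i in range(9)]
    reads.append(SequenceRecord("r9", variant))
    cfg = PipelineConfig(min_overlap=500)
    contigs = assemble(reads, cfg)
    assert len(contigs) == 1
    assert contigs[0].bases == seq


def _circular_reads(genome, read_len, step, rng=None):
    doubled = genome + genome
    reads = []
    for i, start in enumerate(range(0, len(genome), step)):
        seq = doubled[start:start + read_len]
        strand = "+" if (rng is None or rng.random() < 0.5) else "-"
        reads.append(SequenceRecord(f"r{i:03d}",
                                    seq if strand == "+" else revcomp(seq)))
    return reads


def test_exact_reads_recover_circular_genome():
    """Error-free tiling reads of a repeat-free circle assemble exactly."""
    genome = random_dna(np.random.default_rng(11), 6_000)
    reads = _circular_reads(genome, 1_500, 200, np.random.default_rng(12))
    cfg = PipelineConfig(min_overlap=500, circular_size=220)
    contigs = assemble(reads, cfg)
    cyclic = [c for c in contigs if c.layout_is_cyclic]
    assert len(cyclic) == 1
    res = detect_terminal_redundancy(cyclic[0], cfg)
    assert res.is_circular
    trimmed = trim_redundancy(cyclic[0], res, cfg)
    assert cyclic_equal(trimmed.bases, genome)


def test_assembly_is_deterministic():
    genome = random_dna(np.random.default_rng(21), 6_000)
    reads = _circular_reads(genome, 1_500, 250, np.random.default_rng(22))
    cfg = PipelineConfig(min_overlap=500)
    a = assemble(reads, cfg)
    b = assemble(reads, cfg)
    assert [(c.id, c.bases, c.layout_is_cyclic) for c in a] == \
           [(c.id, c.bases, c.layout_is_cyclic) for c in b]


def test_accept_contigs_is_byte_identical_passthrough():
    recs = [SequenceRecord("c1", "ACGT" * 50), SequenceRecord("c2", "GGCC" * 50)]
    drafts = accept_contigs(recs)
    assert [(d.id, d.bases) for d in drafts] == \
           [(r.id, r.bases) for r in recs]
    with pytest.raises(ValueError):
        accept_contigs([])


def _oracle_instance(rng, n_reads, genome_len, read_len, min_overlap):
    """Staggered reads over a linear genome: dovetails, no containments."""
    genome = random_dna(rng, genome_len)
    starts = np.sort(rng.choice(
        np.arange(0, genome_len - read_len), size=n_reads, replace=False))
    while len(starts) > 1 and np.diff(starts).min() < 20:
        starts = np.sort(rng.choice(
            np.arange(0, genome_len - read_len), size=n_reads, replace=False))
    reads = []
    for i, s in enumerate(starts):
        seq = genome[s:s + read_len]
        if rng.random() < 0.4:
            seq = revcomp(seq)
        reads.append(SequenceRecord(f"q{i:02d}", seq))
    return reads


@pytest.mark.parametrize("seed", [101, 202])
def test_overlaps_match_dp_oracle(seed):
    rng = np.random.default_rng(seed)
    reads = _oracle_instance(rng, n_reads=6, genome_len=1_200,
                             read_len=400, min_overlap=60)
    computed = compute_overlaps(reads, min_overlap=60, min_identity=0.99)
    expected = oracle_overlaps(reads, min_overlap=60, min_identity=0.99)
    got = {
        (min(o.a_id, o.b_id), max(o.a_id, o.b_id), overlap_class(o)):
        o.overlap_len
        for o in computed if not o.is_containment
    }
    assert set(got) == set(expected)
    for key, length in expected.items():
        assert abs(got[key] - length) <= 2
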