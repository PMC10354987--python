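"""Fully labelled synthetic fixtures: mitogenomes, reads, NUMTs, haplotypes.

The generator emulates the data regime the pipeline is built for: a
metazoan-scale circular mitogenome (13 protein genes, 2 rRNAs, 22 tRNAs
including trnF) sequenced with long, highly accurate reads (truncated-normal
lengths around 10 kb, ~0.2% substitutions and ~0.05% indels). Every read
carries a provenance record (source, start, strand, haplotype), so
end-to-end accuracy can be measured against ground truth.

All sampling flows through one numpy Generator seeded explicitly; identical
seeds give identical fixtures on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import GeneticCode
from .records import AnnotationSet, FeatureRecord, SequenceRecord, revcomp

BASES = np.array(list("ACGT"))

CDS_NAMES = ["COX1", "COX2", "COX3", "CYTB", "ATP6", "ATP8", "NAD1", "NAD2",
             "NAD3", "NAD4", "NAD4L", "NAD5", "NAD6"]
TRNA_NAMES = ["trnF", "trnV", "trnL1", "trnL2", "trnI", "trnQ", "trnM",
              "trnA", "trnN", "trnC", "trnY", "trnW", "trnD", "trnG",
              "trnH", "trnK", "trnP", "trnR", "trnS1", "trnS2", "trnT",
              "trnE"]
RRNA_NAMES = ["rrnS", "rrnL"]


@dataclass
class ReadProvenance:
    source: str          # "mito" | "nuclear" | haplotype id
    start: int
    strand: str
    length: int
    haplotype: str | None = None
    n_errors: int = 0


@dataclass
class TruthSet:
    mito: SequenceRecord
    annotation: AnnotationSet
    nuclear: SequenceRecord | None = None
    numt_interval: tuple[int, int] | None = None   # on the nuclear sequence
    haplotypes: list[tuple[SequenceRecord, float]] = field(default_factory=list)
    read_provenance: dict[str, ReadProvenance] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, n_codons: int,
                code: GeneticCode) -> str:
    """ATG-initiated ORF with no internal stop, terminated by a stop codon."""
    sense = sorted(c for c, aa in code.codons.items() if aa != "*")
    stops = sorted(code.stop_codons)
    body = [sense[i] for i in rng.integers(0, len(sense), n_codons - 2)]
    return "ATG" + "".join(body) + stops[int(rng.integers(0, len(stops)))]


def simulate_mitogenome(length: int = 16_500, n_cds: int = 13,
                        n_trna: int = 22, genetic_code_id: int = 5,
                        seed: int = 7) -> TruthSet:
    """A random circular mitogenome with planted, non-overlapping genes."""
    if length < 12_000:
        raise ValueError("length must be >= 12000 for default gene counts")
    rng = np.random.default_rng(seed)
    code = GeneticCode.from_table_id(genetic_code_id)

    plan: list[tuple[str, str, int]] = []  # (kind, name, length)
    plan.append(("rRNA", "rrnS", int(rng.integers(750, 900))))
    plan.append(("rRNA", "rrnL", int(rng.integers(1100, 1350))))
    for name in TRNA_NAMES[:n_trna]:
        plan.append(("tRNA", name, int(rng.integers(65, 76))))
    # protein genes share whatever space rRNAs, tRNAs and spacers leave
    non_cds = sum(l for _, _, l in plan)
    spacer_budget = 30 * (len(plan) + n_cds) + 200
    mean_codons = max(80, (length - non_cds - spacer_budget) // (3 * n_cds))
    lo_codons = max(60, (3 * mean_codons) // 4)
    for name in CDS_NAMES[:n_cds]:
        n_codons = int(rng.integers(lo_codons, mean_codons + 1))
        plan.append(("CDS", name, 3 * n_codons))
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]

    gene_total = sum(l for _, _, l in plan)
    spare = length - gene_total
    if spare < len(plan) + 1:
        raise ValueError("length too small for requested gene content")
    cuts = np.sort(rng.integers(0, spare, len(plan)))
    spacers = np.diff(np.concatenate([[0], cuts, [spare]]))

    pieces: list[str] = []
    features: list[FeatureRecord] = []
    pos = 0
    for (kind, name, flen), gap in zip(plan, spacers[:-1]):
        pieces.append(_random_seq(rng, int(gap)))
        pos += int(gap)
        if kind == "CDS":
            gene = _random_cds(rng, flen // 3, code)
        else:
            gene = _random_seq(rng, flen)
        strand = "+" if rng.random() < 0.7 else "-"
        pieces.append(gene if strand == "+" else revcomp(gene))
        features.append(FeatureRecord("mito_truth", kind, pos, pos + flen,
                                      strand, name,
                                      {"product": name}))
        pos += flen
    pieces.append(_random_seq(rng, int(spacers[-1])))
    bases = "".join(pieces)
    assert len(bases) == length
    mito = SequenceRecord("mito_truth", bases, "simulated circular mitogenome")
    ann = AnnotationSet("mito_truth", features, genetic_code_id=genetic_code_id)
    return TruthSet(mito=mito, annotation=ann,
                    haplotypes=[(mito, 1.0)])


def _apply_errors(rng: np.random.Generator, seq: str, sub_rate: float,
                  indel_rate: float) -> tuple[str, int]:
    n = len(seq)
    r = rng.random(n)
    out: list[str] = []
    n_err = 0
    bases = "ACGT"
    for i, c in enumerate(seq):
        x = r[i]
        if x < sub_rate:
            out.append(bases[(bases.index(c) + 1 + int(rng.integers(0, 3))) % 4])
            n_err += 1
        elif x < sub_rate + indel_rate / 2:      # deletion
            n_err += 1
        elif x < sub_rate + indel_rate:          # insertion before base
            out.append(bases[int(rng.integers(0, 4))])
            out.append(c)
            n_err += 1
        else:
            out.append(c)
    return "".join(out), n_err


def simulate_reads(sequence: SequenceRecord, circular: bool = True,
                   coverage: float = 30.0, mean_len: int = 10_000,
                   sd_len: int = 2_000, min_len: int = 5_000,
                   sub_rate: float = 0.002, indel_rate: float = 0.0005,
                   seed: int = 1, id_prefix: str = "read",
                   source: str = "mito", haplotype: str | None = None
                   ) -> tuple[list[SequenceRecord], dict[str, ReadProvenance]]:
    """Uniform sampling of the (optionally circular) source at given depth."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    L = len(sequence)
    doubled = sequence.bases + sequence.bases
    max_len = min(L, mean_len + 4 * sd_len)
    reads, provenance = [], {}
    total = 0
    i = 0
    target = coverage * L
    while total < target:
        length = int(np.clip(rng.normal(mean_len, sd_len), min_len, max_len))
        start = int(rng.integers(0, L))
        if circular:
            raw = doubled[start:start + length]
        else:
            raw = sequence.bases[start:start + length]
            length = len(raw)
        if length < min(min_len, L):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            raw = revcomp(raw)
        bases, n_err = _apply_errors(rng, raw, sub_rate, indel_rate)
        rid = f"{id_prefix}{i:05d}"
        reads.append(SequenceRecord(rid, bases))
        provenance[rid] = ReadProvenance(source, start, strand, len(bases),
                                         haplotype, n_err)
        total += length
        i += 1
    return reads, provenance


def plant_numt(mito: SequenceRecord, nuclear_length: int,
               fragment: tuple[int, int], seed: int = 11,
               divergence: float = 0.0
               ) -> tuple[SequenceRecord, tuple[int, int]]:
    """A random nuclear background carrying one mitochondrial fragment.

    Returns the nuclear sequence and the interval the fragment occupies on
    it. ``divergence`` mutates the inserted copy (substitutions only), as an
    aged NUMT would have accumulated.
    """
    s, e = fragment
    if not (0 <= s <= e <= len(mito)):
        raise ValueError("fragment interval outside the mitogenome")
    rng = np.random.default_rng(seed)
    frag = mito.bases[s:e]
    if divergence > 0 and frag:
        frag, _ = _apply_errors(rng, frag, divergence, 0.0)
    flank = nuclear_length - len(frag)
    left = int(rng.integers(flank // 4, 3 * flank // 4)) if flank else 0
    bases = (_random_seq(rng, left) + frag
             + _random_seq(rng, flank - left))
    rec = SequenceRecord("nuclear_truth", bases,
                         "simulated nuclear background with NUMT")
    return rec, (left, left + len(frag))


@dataclass
class HaplotypeEdit:
    """Second-haplotype edit: an insertion or k random substitutions."""

    kind: str = "insertion"      # "insertion" | "substitutions"
    position: int = 8_000
    length: int = 100            # insertion length or substitution count


def simulate_heteroplasmy(mito: SequenceRecord, edit: HaplotypeEdit,
                          frequencies: tuple[float, float] = (0.5, 0.5),
                          seed: int = 23
                          ) -> list[tuple[SequenceRecord, float]]:
    """Two mitochondrial haplotypes: the original plus one edited copy."""
    if abs(sum(frequencies) - 1.0) > 1e-9:
        raise ValueError("haplotype frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    bases = mito.bases
    if edit.kind == "insertion":
        ins = _random_seq(rng, edit.length)
        edited = bases[: edit.position] + ins + bases[edit.position:]
    elif edit.kind == "substitutions":
        positions = rng.choice(len(bases), size=edit.length, replace=False)
        blist = list(bases)
        for p in sorted(positions):
            blist[p] = "ACGT"[("ACGT".index(blist[p]) + 1
                               + int(rng.integers(0, 3))) % 4]
        edited = "".join(blist)
    else:
        raise ValueError(f"unknown edit kind {edit.kind!r}")
    hap_b = SequenceRecord("hap_B", edited, "edited haplotype")
    hap_a = SequenceRecord("hap_A", bases, "original haplotype")
    return [(hap_a, frequencies[0]), (hap_b, frequencies[1])]


def simulate_heteroplasmic_reads(haplotypes, coverage: float = 30.0,
                                 seed: int = 31, **read_kwargs
                                 ) -> tuple[list[SequenceRecord],
                                            dict[str, ReadProvenance]]:
    """Draw reads per haplotype at its stated frequency; pooled output."""
    reads, prov = [], {}
    for j, (hap, freq) in enumerate(haplotypes):
        if freq <= 0:
            continue
        r, p = simulate_reads(hap, circular=True, coverage=coverage * freq,
                              seed=seed + j, id_prefix=f"h{j}_",
                              source=hap.id, haplotype=hap.id, **read_kwargs)
        reads.extend(r)
        prov.update(p)
    return reads, prov
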