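"""Shared fixtures: synthetic truth sets and cached full pipeline runs."""

from __future__ import annotations

import pathlib

import numpy as np
import pytest

from mitoloop import io as fio
from mitoloop.config import PipelineConfig
from mitoloop.pipeline import run_from_reads
from mitoloop.simulate import (HaplotypeEdit, plant_numt,
                               simulate_heteroplasmic_reads,
                               simulate_heteroplasmy, simulate_mitogenome,
                               simulate_reads)

#: study conditions for the end-to-end fixture: metazoan-scale circle,
#: 30x long accurate reads with HiFi-like error rates
TRUTH_SEED = 7
READ_SEED = 1
GENOME_LEN = 16_500
COVERAGE = 30.0
SUB_RATE = 0.002
INDEL_RATE = 0.0005


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def truth():
    return simulate_mitogenome(length=GENOME_LEN, genetic_code_id=5,
                               seed=TRUTH_SEED)


@pytest.fixture(scope="session")
def mito_reads(truth):
    reads, prov = simulate_reads(truth.mito, circular=True, coverage=COVERAGE,
                                 sub_rate=SUB_RATE, indel_rate=INDEL_RATE,
                                 seed=READ_SEED)
    return reads, prov


def _write_reference(truth, outdir: pathlib.Path):
    fio.write_fasta([truth.mito], outdir / "reference.fasta")
    fio.write_genbank(truth.mito, truth.annotation, outdir / "reference.gb")
    return outdir / "reference.fasta", outdir / "reference.gb"


def _run(truth, reads, outdir: pathlib.Path, config=None):
    outdir.mkdir(parents=True, exist_ok=True)
    ref_fa, ref_gb = _write_reference(truth, outdir)
    fio.write_fasta(reads, outdir / "reads.fasta")
    manifest = run_from_reads(outdir / "reads.fasta", ref_fa, ref_gb,
                              config or PipelineConfig(), outdir / "run")
    return manifest, outdir / "run"


@pytest.fixture(scope="session")
def baseline_runs(truth, mito_reads, tmp_path_factory):
    """The standard 30x run, executed twice for determinism checks."""
    reads, _ = mito_reads
    root = tmp_path_factory.mktemp("baseline")
    m1, out1 = _run(truth, reads, root / "a")
    m2, out2 = _run(truth, reads, root / "b")
    return (m1, out1), (m2, out2)


@pytest.fixture(scope="session")
def errorfree_run(truth, tmp_path_factory):
    reads, _ = simulate_reads(truth.mito, circular=True, coverage=COVERAGE,
                              sub_rate=0.0, indel_rate=0.0, seed=READ_SEED)
    return _run(truth, reads, tmp_path_factory.mktemp("errorfree"))


@pytest.fixture(scope="session")
def numt_run(truth, mito_reads, tmp_path_factory):
    """Baseline reads plus a NUMT-bearing nuclear background's reads."""
    reads, _ = mito_reads
    nuclear, interval = plant_numt(truth.mito, 100_000, (1_000, 9_000),
                                   seed=11)
    nreads, nprov = simulate_reads(nuclear, circular=False, coverage=10.0,
                                   mean_len=15_000, sd_len=4_000,
                                   sub_rate=SUB_RATE, indel_rate=INDEL_RATE,
                                   seed=12, id_prefix="nread",
                                   source="nuclear")
    manifest, outdir = _run(truth, reads + nreads,
                            tmp_path_factory.mktemp("numt"))
    return manifest, outdir, nreads, nprov, interval


@pytest.fixture(scope="session")
def heteroplasmy_runs(truth, tmp_path_factory):
    """50:50 haplotypes differing by a 100 bp insertion; run twice."""
    haps = simulate_heteroplasmy(
        truth.mito, HaplotypeEdit("insertion", 8_000, 100), seed=23)
    reads, prov = simulate_heteroplasmic_reads(
        haps, coverage=COVERAGE, seed=31,
        sub_rate=SUB_RATE, indel_rate=INDEL_RATE)
    root = tmp_path_factory.mktemp("het")
    m1, out1 = _run(truth, reads, root / "a")
    m2, out2 = _run(truth, reads, root / "b")
    return haps, prov, (m1, out1), (m2, out2)
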