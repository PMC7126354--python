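"""Shared fixtures: small deterministic synthetic runs reused across tests."""

from __future__ import annotations

import pytest

from splicecall import pipeline, synth
from splicecall.config import RunConfig
from splicecall.seqio import ReferenceDB


@pytest.fixture(scope="session")
def small_genome():
    cfg = synth.SynthConfig(n_genes=12, n_contigs=2, n_decoys=4)
    return synth.generate_genome(cfg, seed=7)


@pytest.fixture(scope="session")
def small_refdb(small_genome):
    targets, _ = synth.diverge_proteins(small_genome.proteins, 0.1, seed=8)
    decoys = synth.make_decoys(synth.SynthConfig(n_decoys=4), seed=9)
    return ReferenceDB(targets=targets + decoys)


@pytest.fixture(scope="session")
def small_run(small_genome, small_refdb):
    return pipeline.predict(small_genome.contigs, small_refdb, RunConfig())


@pytest.fixture(scope="session")
def bench_genome():
    """~0.8 Mbp, 200 multi/single-exon genes across 10 contigs."""
    cfg = synth.SynthConfig(
        n_genes=200, n_contigs=10, n_decoys=50,
        min_intergenic_nt=2500, max_intergenic_nt=5500,
    )
    return synth.generate_genome(cfg, seed=11)


@pytest.fixture(scope="session")
def bench_refdb(bench_genome):
    targets, identity = synth.diverge_proteins(bench_genome.proteins, 0.2, seed=12)
    assert identity >= 0.75
    cfg = synth.SynthConfig(n_decoys=50)
    return ReferenceDB(targets=targets + synth.make_decoys(cfg, seed=13))


@pytest.fixture(scope="session")
def bench_run(bench_genome, bench_refdb):
    return pipeline.predict(bench_genome.contigs, bench_refdb, RunConfig())
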