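"""Shared fixtures: tiny hand-built models and session-scoped scenarios."""

from __future__ import annotations

import pytest

from annoweave import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    ScenarioConfig,
    Transcript,
    generate_scenario,
    run_pipeline,
)


def make_transcript(tid, gid, scaffold, exon_chain, cds_chain=(), strand="+"):
    return Transcript(
        tid,
        gid,
        tuple(GenomicInterval(scaffold, s, e, strand) for s, e in exon_chain),
        tuple(GenomicInterval(scaffold, s, e, strand) for s, e in cds_chain),
    )


def make_gene(
    gid, exon_chain, cds_chain=(), scaffold="1", strand="+", source="truth"
):
    """Single-transcript gene from an exon chain of (start, end) pairs."""
    return GeneModel(
        gid,
        (make_transcript(f"{gid}.1", gid, scaffold, exon_chain, cds_chain, strand),),
        source=source,
    )


def make_multi_gene(gid, chains, scaffold="1", strand="+", source="truth"):
    """Gene with one transcript per exon chain (no CDS)."""
    transcripts = tuple(
        make_transcript(f"{gid}.{k}", gid, scaffold, chain, (), strand)
        for k, chain in enumerate(chains, start=1)
    )
    return GeneModel(gid, transcripts, source=source)


def as_set(*models):
    return AnnotationSet(models)


@pytest.fixture(scope="session")
def default_scenario():
    """The standard study conditions: 200 genes, 10 % perturbation rates."""
    return generate_scenario(ScenarioConfig(seed=42))


@pytest.fixture(scope="session")
def default_run(default_scenario):
    scenario = default_scenario
    final, report = run_pipeline(
        scenario.v1,
        scenario.candidates,
        scenario.reads,
        hits=list(scenario.hits),
        protein_lengths=scenario.protein_lengths,
        te_intervals=list(scenario.te_intervals),
        te_hits=list(scenario.te_hits),
    )
    return scenario, final, report
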