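"""GFF3 parsing, validation, writing and derived quantities."""

import io

import numpy as np
import pytest

from annoweave import (
    AnnotationError,
    AnnotationSet,
    GenomicInterval,
    Gff3ParseError,
    ScenarioConfig,
    Transcript,
    generate_scenario,
    parse_gff3,
    protein_length,
    write_gff3,
    write_summary_tsv,
)

from conftest import make_gene, make_transcript

MINIMAL = """##gff-version 3
1\ttest\tgene\t101\t200\t.\t+\t.\tID=g1
1\ttest\tmRNA\t101\t200\t.\t+\t.\tID=g1.1;Parent=g1
1\ttest\texon\t101\t200\t.\t+\t.\tParent=g1.1
"""

TWO_ISOFORMS = """##gff-version 3
1\ttest\tgene\t101\t500\t.\t+\t.\tID=g1
1\ttest\tmRNA\t101\t500\t.\t+\t.\tID=g1.1;Parent=g1
1\ttest\texon\t101\t200\t.\t+\t.\tParent=g1.1
1\ttest\texon\t301\t500\t.\t+\t.\tParent=g1.1
1\ttest\tmRNA\t101\t500\t.\t+\t.\tID=g1.2;Parent=g1
1\ttest\texon\t101\t200\t.\t+\t.\tParent=g1.2
1\ttest\texon\t401\t500\t.\t+\t.\tParent=g1.2
"""


def test_parse_minimal_gene():
    """A gene/mRNA/exon triple becomes one model with no coding potential."""
    annotation = parse_gff3(io.StringIO(MINIMAL))
    assert len(annotation) == 1
    model = annotation.get("g1")
    assert len(model.transcripts) == 1
    transcript = model.transcripts[0]
    # 1-based inclusive 101..200 becomes 0-based half-open [100, 200)
    assert transcript.exon_chain == ((100, 200),)
    assert model.span.start == 100 and model.span.end == 200
    assert transcript.protein_length == 0


def test_parse_two_isoforms_sharing_first_exon():
    annotation = parse_gff3(io.StringIO(TWO_ISOFORMS))
    model = annotation.get("g1")
    assert len(model.transcripts) == 2
    chains = {t.id: t.exon_chain for t in model.transcripts}
    assert chains["g1.1"] == ((100, 200), (300, 500))
    assert chains["g1.2"] == ((100, 200), (400, 500))
    # gene span covers the exon union exactly
    assert (model.span.start, model.span.end) == (100, 500)


def test_implicit_transcript_for_gene_level_exons():
    """Old dialects attach exons straight to the gene line."""
    text = (
        "1\tv1\tgene\t11\t80\t.\t-\t.\tID=g2\n"
        "1\tv1\texon\t11\t40\t.\t-\t.\tParent=g2\n"
        "1\tv1\texon\t61\t80\t.\t-\t.\tParent=g2\n"
    )
    model = parse_gff3(io.StringIO(text)).get("g2")
    assert len(model.transcripts) == 1
    assert model.transcripts[0].id == "g2.t1"
    assert model.transcripts[0].exon_chain == ((10, 40), (60, 80))


@pytest.mark.parametrize(
    "text, line_no",
    [
        # exon end < start
        (
            "1\tt\tgene\t1\t100\t.\t+\t.\tID=g\n"
            "1\tt\tmRNA\t1\t100\t.\t+\t.\tID=m;Parent=g\n"
            "1\tt\texon\t90\t50\t.\t+\t.\tParent=m\n",
            3,
        ),
        # wrong column count
        ("1\tt\tgene\t1\t100\t.\t+\tID=g\n", 1),
        # non-integer coordinate
        ("1\tt\tgene\tone\t100\t.\t+\t.\tID=g\n", 1),
        # unknown Parent
        (
            "1\tt\tgene\t1\t100\t.\t+\t.\tID=g\n"
            "1\tt\texon\t1\t100\t.\t+\t.\tParent=nosuch\n",
            2,
        ),
    ],
)
def test_parse_errors_name_the_line(text, line_no):
    with pytest.raises(Gff3ParseError) as err:
        parse_gff3(io.StringIO(text))
    assert f"line {line_no}" in str(err.value)


@pytest.mark.parametrize(
    "cds_lengths, expected",
    [((300,), 100), ((100, 101), 67), ((), 0), ((1,), 0), ((4,), 1)],
)
def test_protein_length_floor_rule(cds_lengths, expected):
    """Protein length is total CDS nucleotides floor-divided by three."""
    pos, exons, cds = 0, [], []
    for length in cds_lengths or (90,):
        exons.append((pos, pos + length + 20))
        if cds_lengths:
            cds.append((pos, pos + length))
        pos += length + 120
    transcript = make_transcript("t", "g", "1", exons, cds)
    assert protein_length(transcript) == expected


@pytest.mark.parametrize(
    "bad",
    [
        # overlapping exons
        lambda: make_gene("g", [(0, 100), (50, 150)]).validate(),
        # CDS outside every exon
        lambda: make_gene("g", [(0, 100)], [(150, 180)]).validate(),
        # zero-length exon
        lambda: make_gene("g", [(10, 10)]).validate(),
        # interval with end < start
        lambda: GenomicInterval("1", 100, 50),
        # transcript claims a different parent gene
        lambda: __import__("annoweave").GeneModel(
            "g", (make_transcript("t", "other", "1", [(0, 10)]),)
        ).validate(),
    ],
)
def test_structural_invariant_violations_raise(bad):
    with pytest.raises(AnnotationError):
        bad()


def test_duplicate_gene_id_rejected():
    annotation = AnnotationSet([make_gene("g", [(0, 100)])])
    with pytest.raises(AnnotationError):
        annotation.add(make_gene("g", [(200, 300)]))


def test_write_empty_annotation_is_header_only():
    buffer = io.StringIO()
    write_gff3(AnnotationSet(), buffer)
    assert buffer.getvalue() == "##gff-version 3\n"


def test_utr_lines_emitted_for_exons_beyond_cds():
    gene = make_gene("g", [(0, 100), (200, 300)], [(40, 100), (200, 250)])
    buffer = io.StringIO()
    write_gff3(AnnotationSet([gene]), buffer)
    text = buffer.getvalue()
    assert "five_prime_UTR\t1\t40" in text
    assert "three_prime_UTR\t251\t300" in text
    # round trip ignores the derived UTR lines
    again = parse_gff3(io.StringIO(text))
    assert again.get("g").transcripts[0].cds_chain == ((40, 100), (200, 250))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_gff3_round_trip_on_random_annotations(seed):
    """parse(write(A)) reproduces ids, coordinates and hierarchy exactly."""
    scenario = generate_scenario(
        ScenarioConfig(seed=seed, n_scaffolds=2, genes_per_scaffold=15)
    )
    for annotation in (scenario.truth, scenario.v1, scenario.candidates):
        buffer = io.StringIO()
        write_gff3(annotation, buffer)
        buffer.seek(0)
        assert parse_gff3(buffer) == annotation


def test_interval_index_matches_linear_scan():
    scenario = generate_scenario(
        ScenarioConfig(seed=9, n_scaffolds=2, genes_per_scaffold=30)
    )
    annotation = scenario.truth
    rng = np.random.default_rng(1)
    models = list(annotation)
    hi = max(m.span.end for m in models) + 500
    for _ in range(200):
        scaffold = str(rng.integers(1, 3))
        start = int(rng.integers(0, hi))
        end = start + int(rng.integers(1, 5000))
        expected = sorted(
            (
                m.id
                for m in models
                if m.scaffold == scaffold and m.span.start < end and start < m.span.end
            ),
        )
        got = [m.id for m in annotation.overlapping(scaffold, start, end)]
        assert sorted(got) == expected


def test_summary_tsv_contents():
    import pandas as pd

    gene = make_gene("g", [(0, 100), (200, 300)], [(40, 100), (200, 250)], strand="-")
    buffer = io.StringIO()
    write_summary_tsv(AnnotationSet([gene]), buffer)
    buffer.seek(0)
    frame = pd.read_csv(buffer, sep="\t")
    row = frame.iloc[0]
    assert row["id"] == "g"
    assert (row["start"], row["end"]) == (1, 300)  # 1-based inclusive on disk
    assert row["strand"] == "-"
    assert row["n_transcripts"] == 1
    assert row["protein_length"] == (60 + 50) // 3
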