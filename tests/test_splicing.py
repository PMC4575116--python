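"""Splice-event enumeration, PSI and differential-splicing calls."""

import numpy as np
import pandas as pd
import pytest

from annoweave import EventCounts, differential_splicing, enumerate_events, psi
from annoweave.annotation_io import GeneModel

from conftest import make_multi_gene
from _oracles import fisher_two_sided_oracle, splice_events_bruteforce


def kinds(gene):
    return sorted((e.event_type, e.inclusion, e.exclusion) for e in enumerate_events(gene))


def test_exon_skipping_detected():
    gene = make_multi_gene(
        "g",
        [
            [(0, 100), (200, 300), (400, 500)],
            [(0, 100), (400, 500)],
        ],
    )
    events = enumerate_events(gene)
    assert [e.event_type for e in events] == ["SE"]
    assert events[0].inclusion == ((200, 300),)
    assert events[0].exclusion == ((100, 400),)
    assert events[0].anchors == (100, 400)


def test_intron_retention_detected():
    gene = make_multi_gene(
        "g",
        [
            [(0, 100), (200, 300)],
            [(0, 300)],
        ],
    )
    events = enumerate_events(gene)
    assert [e.event_type for e in events] == ["RI"]
    assert events[0].inclusion == ((0, 300),)
    assert events[0].exclusion == ((100, 200),)


def test_alternative_splice_sites_and_strand_naming():
    # introns (100, 400) and (150, 400): shared acceptor, two donors on '+'
    plus = make_multi_gene(
        "g",
        [
            [(0, 100), (400, 500)],
            [(0, 150), (400, 500)],
        ],
    )
    events = enumerate_events(plus)
    assert [e.event_type for e in events] == ["A5SS"]
    assert events[0].inclusion == ((150, 400),)  # shorter intron = longer exon
    assert events[0].exclusion == ((100, 400),)
    # the same structure transcribed on '-' has the donors at the other end
    minus = make_multi_gene(
        "g",
        [
            [(0, 100), (400, 500)],
            [(0, 150), (400, 500)],
        ],
        strand="-",
    )
    assert [e.event_type for e in enumerate_events(minus)] == ["A3SS"]

    # shared donor, two acceptors on '+'
    acceptor = make_multi_gene(
        "g",
        [
            [(0, 100), (400, 500)],
            [(0, 100), (350, 500)],
        ],
    )
    assert [e.event_type for e in enumerate_events(acceptor)] == ["A3SS"]


def test_mutually_exclusive_exons_detected():
    gene = make_multi_gene(
        "g",
        [
            [(0, 100), (200, 250), (400, 500)],
            [(0, 100), (300, 350), (400, 500)],
        ],
    )
    events = enumerate_events(gene)
    assert [e.event_type for e in events] == ["MXE"]
    assert events[0].inclusion == ((200, 250),)
    assert events[0].exclusion == ((300, 350),)
    assert events[0].anchors == (100, 400)


def test_identical_and_single_isoforms_yield_nothing():
    chain = [(0, 100), (200, 300)]
    assert enumerate_events(make_multi_gene("g", [chain, chain])) == []
    assert enumerate_events(make_multi_gene("g", [chain])) == []


def _random_gene(rng, gid) -> GeneModel:
    """2-4 isoforms derived from a shared exon skeleton by local edits."""
    n_exons = int(rng.integers(3, 9))
    bounds = []
    pos = 0
    for _ in range(n_exons):
        start = pos + int(rng.integers(60, 200))
        end = start + int(rng.integers(60, 200))
        bounds.append([start, end])
        pos = end
    chains = []
    for _ in range(int(rng.integers(2, 5))):
        chain = [list(b) for b in bounds]
        # maybe skip an internal exon
        if len(chain) > 2 and rng.random() < 0.5:
            del chain[int(rng.integers(1, len(chain) - 1))]
        # maybe retain an intron (merge adjacent exons)
        if len(chain) > 1 and rng.random() < 0.4:
            j = int(rng.integers(0, len(chain) - 1))
            chain[j][1] = chain[j + 1][1]
            del chain[j + 1]
        # maybe nudge a donor or acceptor into the intron
        if len(chain) > 1 and rng.random() < 0.6:
            j = int(rng.integers(0, len(chain) - 1))
            gap = chain[j + 1][0] - chain[j][1]
            shift = int(rng.integers(0, max(1, gap // 2)))
            if rng.random() < 0.5:
                chain[j][1] += shift
            else:
                chain[j + 1][0] -= shift
        chains.append([tuple(x) for x in chain])
    strand = "+" if rng.random() < 0.5 else "-"
    return make_multi_gene(gid, chains, strand=strand)


def test_enumeration_matches_bruteforce_on_random_genes():
    rng = np.random.default_rng(17)
    for i in range(150):
        gene = _random_gene(rng, f"g{i}")
        assert enumerate_events(gene) == splice_events_bruteforce(gene)


@pytest.mark.parametrize(
    "inc, exc, expected",
    [(0, 10, 0.0), (10, 10, 0.5), (30, 10, 0.75), (10, 0, 1.0)],
)
def test_psi_values(inc, exc, expected):
    assert psi(inc, exc) == pytest.approx(expected)


def test_psi_normalizers_and_undefined():
    # twice the inclusion length halves its effective weight
    assert psi(20, 10, inclusion_norm=2.0, exclusion_norm=1.0) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        psi(0, 0)


def _counts(rows, conditions=None):
    """rows: event_id -> {sample: (inc, exc)}"""
    conditions = conditions or {"wt1": "WT", "wt2": "WT", "hs1": "HS", "hs2": "HS"}
    samples = list(conditions)
    inc = pd.DataFrame(
        {s: [rows[e][s][0] for e in rows] for s in samples}, index=list(rows)
    )
    exc = pd.DataFrame(
        {s: [rows[e][s][1] for e in rows] for s in samples}, index=list(rows)
    )
    return EventCounts(inc, exc, conditions)


def test_identical_counts_not_significant():
    counts = _counts({"g1:SE:x": {s: (40, 40) for s in ("wt1", "wt2", "hs1", "hs2")}})
    calls = differential_splicing(counts, "WT", "HS")
    row = calls.iloc[0]
    assert row["delta_psi"] == 0.0
    assert not row["significant"]


def test_planted_psi_shift_called_and_p_matches_oracle():
    counts = _counts(
        {
            "g1:SE:x": {
                "wt1": (90, 10),
                "wt2": (90, 10),
                "hs1": (10, 90),
                "hs2": (10, 90),
            }
        }
    )
    calls = differential_splicing(counts, "WT", "HS")
    row = calls.iloc[0]
    assert row["significant"]
    assert row["psi_a"] == pytest.approx(0.9)
    assert row["psi_b"] == pytest.approx(0.1)
    oracle = fisher_two_sided_oracle([[180, 20], [20, 180]])
    assert row["p_value"] == pytest.approx(oracle, abs=1e-10)


def test_fisher_p_matches_hypergeometric_oracle_randomized():
    rng = np.random.default_rng(23)
    rows = {}
    for i in range(50):
        rows[f"g{i}:SE:x"] = {
            s: (int(rng.integers(0, 200)), int(rng.integers(0, 200)))
            for s in ("wt1", "wt2", "hs1", "hs2")
        }
    counts = _counts(rows)
    calls = differential_splicing(counts, "WT", "HS")
    inc_a, exc_a = counts.pooled("WT")
    inc_b, exc_b = counts.pooled("HS")
    for event_id, row in calls.iterrows():
        oracle = fisher_two_sided_oracle(
            [
                [int(inc_a[event_id]), int(exc_a[event_id])],
                [int(inc_b[event_id]), int(exc_b[event_id])],
            ]
        )
        assert row["p_value"] == pytest.approx(oracle, abs=1e-10)


def test_bh_fdr_monotone_in_sorted_p():
    rng = np.random.default_rng(29)
    rows = {}
    for i in range(80):
        shift = int(rng.integers(0, 60))
        rows[f"g{i}:SE:x"] = {
            "wt1": (100, 100),
            "wt2": (100, 100),
            "hs1": (100 + shift, 100 - shift),
            "hs2": (100, 100),
        }
    calls = differential_splicing(_counts(rows), "WT", "HS").sort_values("p_value")
    fdr = calls["fdr"].to_numpy()
    assert np.all(np.diff(fdr) >= -1e-12)
    # significance is monotone in p at fixed delta direction: every
    # significant event has p below any non-significant event with
    # comparable |delta|
    assert calls["fdr"].min() >= calls["p_value"].min()


def test_extreme_expression_ratio_excluded():
    rows = {
        "quiet:SE:x": {s: (50, 50) for s in ("wt1", "wt2", "hs1", "hs2")},
        "loud:SE:x": {
            "wt1": (90, 10),
            "wt2": (90, 10),
            "hs1": (10, 90),
            "hs2": (10, 90),
        },
    }
    fpkm = {
        "loud": {"WT": 2e5, "HS": 10.0},  # 20,000-fold w/ pseudocount ~ excluded
        "quiet": {"WT": 10.0, "HS": 12.0},
    }
    calls = differential_splicing(
        _counts(rows),
        "WT",
        "HS",
        gene_fpkm=fpkm,
        gene_of_event={"quiet:SE:x": "quiet", "loud:SE:x": "loud"},
    )
    assert list(calls.index) == ["quiet:SE:x"]


def test_zero_read_condition_skipped():
    rows = {
        "g1:SE:x": {"wt1": (0, 0), "wt2": (0, 0), "hs1": (10, 5), "hs2": (5, 10)},
        "g2:SE:x": {s: (20, 20) for s in ("wt1", "wt2", "hs1", "hs2")},
    }
    calls = differential_splicing(_counts(rows), "WT", "HS")
    assert list(calls.index) == ["g2:SE:x"]
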