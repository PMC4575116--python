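"""Overlap arithmetic, change-component classification and redundancy."""

import numpy as np
import pytest

from annoweave import (
    AnnotationSet,
    build_overlap_graph,
    classify_components,
    find_redundant,
    overlap_fraction,
)
from annoweave.interval_engine import OverlapEdge

from conftest import as_set, make_gene, make_multi_gene
from _oracles import overlap_graph_bruteforce


def test_overlap_fraction_of_shorter_model():
    a = make_gene("a", [(100, 200)])
    b = make_gene("b", [(150, 250)])
    assert overlap_fraction(a, b) == pytest.approx(0.5)  # 50 nt / shorter 100


def test_overlap_fraction_identity_and_disjoint():
    a = make_gene("a", [(100, 200)])
    assert overlap_fraction(a, make_gene("b", [(100, 200)])) == 1.0
    assert overlap_fraction(a, make_gene("c", [(300, 400)])) == 0.0
    assert overlap_fraction(a, make_gene("d", [(100, 200)], scaffold="2")) == 0.0


def test_overlap_fraction_strand_handling():
    a = make_gene("a", [(100, 200)], strand="+")
    b = make_gene("b", [(100, 200)], strand="-")
    assert overlap_fraction(a, b) == 0.0
    assert overlap_fraction(a, b, same_strand=False) == 1.0
    # unstranded models overlap regardless
    c = make_gene("c", [(100, 200)], strand=".")
    assert overlap_fraction(a, c) == 1.0


def test_exon_union_mode_ignores_introns():
    a = make_gene("a", [(0, 100), (900, 1000)])  # span 1000, exons 200
    b = make_gene("b", [(400, 600)])  # inside a's intron
    assert overlap_fraction(a, b, mode="span") == 1.0
    assert overlap_fraction(a, b, mode="exon_union") == 0.0


def test_threshold_is_inclusive():
    """A pair at exactly the threshold overlap is an edge; just below is not."""
    a = make_gene("a", [(0, 100)])
    at = make_gene("at", [(70, 170)])  # overlap 30 of shorter 100
    below = make_gene("below", [(71, 171)])  # overlap 29
    edges = build_overlap_graph(as_set(a), as_set(at, below), threshold=0.30)
    assert [(e.model_a, e.model_b) for e in edges] == [("a", "at")]


def test_overlap_graph_matches_all_pairs_scan():
    rng = np.random.default_rng(11)
    def random_set(prefix, n):
        models = []
        for i in range(n):
            scaffold = str(rng.integers(1, 3))
            start = int(rng.integers(0, 20000))
            length = int(rng.integers(50, 2000))
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(
                make_gene(f"{prefix}{i}", [(start, start + length)], scaffold=scaffold, strand=strand)
            )
        return AnnotationSet(models)

    set_a, set_b = random_set("a", 60), random_set("b", 60)
    assert build_overlap_graph(set_a, set_b, 0.30) == overlap_graph_bruteforce(
        set_a, set_b, 0.30
    )


def edge(a, b):
    return OverlapEdge(a, b, 1, 1.0)


def test_split_and_merge_components():
    components = classify_components(
        [edge("v1a", "v2a"), edge("v1a", "v2b"), edge("v1b", "v2c"), edge("v1c", "v2c")],
        ["v1a", "v1b", "v1c", "v1d"],
        ["v2a", "v2b", "v2c", "v2d"],
    )
    kinds = {tuple(sorted(c.v1_members)): c.kind for c in components}
    assert kinds[("v1a",)] == "split"
    assert kinds[("v1b", "v1c")] == "merge"
    assert kinds[("v1d",)] == "v1_only"
    assert {c.kind for c in components if not c.v1_members} == {"v2_only"}


def test_component_conservation_and_relabel_invariance():
    rng = np.random.default_rng(5)
    v1_ids = [f"x{i}" for i in range(30)]
    v2_ids = [f"y{i}" for i in range(30)]
    edges = [
        edge(v1_ids[rng.integers(0, 30)], v2_ids[rng.integers(0, 30)])
        for _ in range(40)
    ]
    components = classify_components(edges, v1_ids, v2_ids)
    assert sum(len(c.v1_members) for c in components) == len(v1_ids)
    assert sum(len(c.v2_members) for c in components) == len(v2_ids)

    # shuffling edge order and renaming ids leaves the partition intact
    relabel = {gid: f"z_{gid}" for gid in v1_ids + v2_ids}
    shuffled = [edges[i] for i in rng.permutation(len(edges))]
    renamed = [
        OverlapEdge(relabel[e.model_a], relabel[e.model_b], e.overlap_nt, e.fraction_of_shorter)
        for e in shuffled
    ]
    components2 = classify_components(
        renamed, [relabel[g] for g in v1_ids], [relabel[g] for g in v2_ids]
    )
    original = {
        (frozenset(c.v1_members), frozenset(c.v2_members), c.kind) for c in components
    }
    mapped_back = {
        (
            frozenset(g[2:] for g in c.v1_members),
            frozenset(g[2:] for g in c.v2_members),
            c.kind,
        )
        for c in components2
    }
    assert original == mapped_back


def test_component_rejects_shared_ids():
    with pytest.raises(ValueError, match="both sides"):
        classify_components([], ["a", "b"], ["b", "c"])


def test_redundant_exact_duplicate_dropped_by_source_priority():
    keep = make_gene("new", [(0, 100), (200, 300)], source="version2")
    drop = make_gene("old", [(0, 100), (200, 300)], source="version1")
    pairs = find_redundant(as_set(drop, keep))
    assert pairs == [("new", "old")]


def test_identical_span_different_chains_not_redundant():
    a = make_gene("a", [(0, 300)])
    b = make_gene("b", [(0, 100), (200, 300)])
    assert find_redundant(as_set(a, b)) == []
    assert find_redundant(AnnotationSet()) == []


def test_subset_of_exon_chains_is_redundant():
    """A model whose transcripts all recur in a richer model is dropped."""
    rich = make_multi_gene("rich", [[(0, 100), (200, 300)], [(0, 100), (250, 300)]])
    poor = make_multi_gene("poor", [[(0, 100), (200, 300)]])
    pairs = find_redundant(as_set(rich, poor), source_priority=())
    assert pairs == [("poor", "rich")] or pairs == [("rich", "poor")]
    # different strands are never redundant
    flipped = make_multi_gene("flip", [[(0, 100), (200, 300)]], strand="-")
    assert find_redundant(as_set(poor, flipped)) == []


def test_dropping_redundant_models_leaves_none():
    models = [
        make_gene("a", [(0, 100)], source="version1"),
        make_gene("b", [(0, 100)], source="version2"),
        make_gene("c", [(0, 100)], source="augustus"),
    ]
    annotation = as_set(*models)
    pairs = find_redundant(annotation)
    for _, dropped in pairs:
        annotation.remove(dropped)
    assert find_redundant(annotation) == []
    assert annotation.ids() == ["b"]  # version2 wins
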