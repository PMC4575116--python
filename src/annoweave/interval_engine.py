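"""Overlap arithmetic between gene-model sets.

Implements the >=30 %-of-the-shorter-model overlap rule used to relate two
annotations, the bipartite overlap graph it induces, connected-component
classification of annotation changes (one-to-one, split, merge, complex,
one-sided), and exact-structure redundancy detection.

Overlap is computed on gene genomic extents (spans) by default; an
exon-union mode is available for callers that want intron-free lengths.
Overlap between models on different scaffolds is zero, and by default models
on opposite strands do not overlap either (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .annotation_io import AnnotationSet, GeneModel

__all__ = [
    "OverlapEdge",
    "ChangeComponent",
    "COMPONENT_KINDS",
    "overlap_nt",
    "overlap_fraction",
    "build_overlap_graph",
    "classify_components",
    "component_kind",
    "find_redundant",
    "edges_to_tsv",
    "components_to_tsv",
]

COMPONENT_KINDS = ("one_to_one", "split", "merge", "complex", "v1_only", "v2_only")

#: preference order when deciding which of two redundant models to keep.
DEFAULT_SOURCE_PRIORITY = ("version2", "version1", "augustus", "cufflinks", "truth")


@dataclass(frozen=True, order=True)
class OverlapEdge:
    """An overlap between one model of set A and one of set B."""

    model_a: str
    model_b: str
    overlap_nt: int
    fraction_of_shorter: float


@dataclass(frozen=True)
class ChangeComponent:
    """A connected component of the bipartite v1/v2 overlap graph."""

    v1_members: frozenset[str]
    v2_members: frozenset[str]
    kind: str

    def sorted_v1(self) -> tuple[str, ...]:
        return tuple(sorted(self.v1_members))

    def sorted_v2(self) -> tuple[str, ...]:
        return tuple(sorted(self.v2_members))


def component_kind(n_v1: int, n_v2: int) -> str:
    """Kind label from the member counts on each side."""
    if n_v1 == 0 and n_v2 == 0:
        raise ValueError("empty component")
    if n_v1 == 0:
        return "v2_only"
    if n_v2 == 0:
        return "v1_only"
    if n_v1 == 1 and n_v2 == 1:
        return "one_to_one"
    if n_v1 == 1:
        return "split"
    if n_v2 == 1:
        return "merge"
    return "complex"


# ---------------------------------------------------------------------------
# overlap computation
# ---------------------------------------------------------------------------


def _merged_exon_union(model: GeneModel) -> list[tuple[int, int]]:
    segments = sorted(
        (e.start, e.end) for t in model.transcripts for e in t.exons
    )
    merged: list[list[int]] = []
    for start, end in segments:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def _model_length(model: GeneModel, mode: str) -> int:
    if mode == "span":
        return model.span.length
    if mode == "exon_union":
        return sum(e - s for s, e in _merged_exon_union(model))
    raise ValueError(f"unknown overlap mode {mode!r}")


def overlap_nt(a: GeneModel, b: GeneModel, mode: str = "span") -> int:
    """Shared nucleotides between two models under the given length mode."""
    if a.scaffold != b.scaffold:
        return 0
    if mode == "span":
        return a.span.overlap_nt(b.span)
    if mode == "exon_union":
        ua, ub = _merged_exon_union(a), _merged_exon_union(b)
        total = i = j = 0
        while i < len(ua) and j < len(ub):
            s = max(ua[i][0], ub[j][0])
            e = min(ua[i][1], ub[j][1])
            if s < e:
                total += e - s
            if ua[i][1] <= ub[j][1]:
                i += 1
            else:
                j += 1
        return total
    raise ValueError(f"unknown overlap mode {mode!r}")


def overlap_fraction(
    a: GeneModel,
    b: GeneModel,
    mode: str = "span",
    same_strand: bool = True,
) -> float:
    """Overlap as a fraction of the shorter model's length, in [0, 1]."""
    if a.scaffold != b.scaffold:
        return 0.0
    if same_strand and a.strand != b.strand and "." not in (a.strand, b.strand):
        return 0.0
    shared = overlap_nt(a, b, mode=mode)
    if shared == 0:
        return 0.0
    shorter = min(_model_length(a, mode), _model_length(b, mode))
    return shared / shorter


def build_overlap_graph(
    set_a: AnnotationSet,
    set_b: AnnotationSet,
    threshold: float = 0.30,
    mode: str = "span",
    same_strand: bool = True,
) -> list[OverlapEdge]:
    """All (a, b) pairs whose overlap fraction meets the threshold (rule is >=).

    Candidate pairs come from the interval index of ``set_b``; the result is
    identical to the all-pairs scan and is returned in sorted order.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    edges: list[OverlapEdge] = []
    for a in set_a:
        span = a.span
        for b in set_b.overlapping(a.scaffold, span.start, span.end):
            fraction = overlap_fraction(a, b, mode=mode, same_strand=same_strand)
            if fraction >= threshold:
                edges.append(
                    OverlapEdge(a.id, b.id, overlap_nt(a, b, mode=mode), fraction)
                )
    return sorted(edges)


# ---------------------------------------------------------------------------
# change-component classification
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, items: Iterable):
        self.parent = {item: item for item in items}

    def find(self, item):
        root = item
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[item] != root:  # path compression
            self.parent[item], item = root, self.parent[item]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller tagged id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def classify_components(
    edges: Sequence[OverlapEdge],
    v1_ids: Iterable[str],
    v2_ids: Iterable[str],
) -> list[ChangeComponent]:
    """Connected components of the bipartite overlap graph, labeled by kind.

    Every id appears in exactly one component; ids without edges form
    singleton ``v1_only``/``v2_only`` components.  An id present on both
    sides, or an edge endpoint outside the declared id sets, is an error.
    """
    v1_set, v2_set = set(v1_ids), set(v2_ids)
    shared = v1_set & v2_set
    if shared:
        raise ValueError(
            "ids present on both sides: " + ", ".join(sorted(shared)[:10])
        )
    nodes = [("1", gid) for gid in v1_set] + [("2", gid) for gid in v2_set]
    uf = _UnionFind(nodes)
    for edge in edges:
        if edge.model_a not in v1_set:
            raise ValueError(f"edge endpoint {edge.model_a} not among v1 ids")
        if edge.model_b not in v2_set:
            raise ValueError(f"edge endpoint {edge.model_b} not among v2 ids")
        uf.union(("1", edge.model_a), ("2", edge.model_b))

    groups: dict[tuple, list[tuple]] = {}
    for node in nodes:
        groups.setdefault(uf.find(node), []).append(node)

    components = []
    for members in groups.values():
        v1_members = frozenset(gid for side, gid in members if side == "1")
        v2_members = frozenset(gid for side, gid in members if side == "2")
        components.append(
            ChangeComponent(
                v1_members,
                v2_members,
                component_kind(len(v1_members), len(v2_members)),
            )
        )
    return sorted(components, key=lambda c: (c.sorted_v1(), c.sorted_v2()))


# ---------------------------------------------------------------------------
# redundancy
# ---------------------------------------------------------------------------


def find_redundant(
    annotation: AnnotationSet,
    source_priority: Sequence[str] = DEFAULT_SOURCE_PRIORITY,
) -> list[tuple[str, str]]:
    """Deterministic (kept, dropped) pairs of structurally redundant models.

    Two models are redundant when they share scaffold and strand and the
    exon-chain set of the model with fewer transcripts is contained in the
    other's (exact coordinates).  The keeper is chosen by source priority,
    ties broken by lexicographically smaller id; dropping every ``dropped``
    id leaves no redundant pair behind.
    """
    rank = {source: i for i, source in enumerate(source_priority)}

    def keep_order(model: GeneModel):
        return (rank.get(model.source, len(source_priority)), model.id)

    pairs: list[tuple[str, str]] = []
    kept: dict[tuple[str, str], list[GeneModel]] = {}
    for model in sorted(annotation, key=keep_order):
        chains = model.exon_chains()
        span = model.span
        group = kept.setdefault((model.scaffold, model.strand), [])
        keeper = None
        for other in group:
            other_span = other.span
            if other_span.end <= span.start or span.end <= other_span.start:
                continue
            other_chains = other.exon_chains()
            if chains <= other_chains or other_chains <= chains:
                keeper = other
                break
        if keeper is None:
            group.append(model)
        else:
            pairs.append((keeper.id, model.id))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------


def edges_to_tsv(edges: Sequence[OverlapEdge], path) -> None:
    pd.DataFrame(
        [
            {
                "model_a": e.model_a,
                "model_b": e.model_b,
                "overlap_nt": e.overlap_nt,
                "fraction_of_shorter": e.fraction_of_shorter,
            }
            for e in edges
        ],
        columns=["model_a", "model_b", "overlap_nt", "fraction_of_shorter"],
    ).to_csv(path, sep="\t", index=False)


def components_to_tsv(components: Sequence[ChangeComponent], path) -> None:
    pd.DataFrame(
        [
            {
                "v1_ids": ",".join(c.sorted_v1()),
                "v2_ids": ",".join(c.sorted_v2()),
                "kind": c.kind,
            }
            for c in components
        ],
        columns=["v1_ids", "v2_ids", "kind"],
    ).to_csv(path, sep="\t", index=False)
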