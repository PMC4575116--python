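"""The end-to-end annotation update pipeline.

Given a legacy annotation (v1), a candidate model set, read-support
evidence, protein similarity hits and TE intervals, the pipeline:

1. selects candidates that are expressed (>=5 supporting reads) or overlap a
   legacy model at >=30 % of the shorter model;
2. rescues legacy models that overlap no selected model but are expressed or
   have an ortholog in at least one declared relative species;
3. flags legacy/updated protein pairs whose length difference is an outlier
   (outside mean +/- 1 SD) and replaces the updated model with its legacy
   counterpart(s) when both outgroup orthologs side with the legacy length;
4. removes structurally redundant models;
5. classifies surviving models as TE-coding or protein-coding;
6. classifies the v1 -> v2 change components (one-to-one / split / merge /
   complex / removed / added) and tallies unchanged vs updated models;
7. assigns systematic position-ordered identifiers
   (``<prefix><scaffold><G|U><number>``, numbering in steps of 10).

Every stage is deterministic for fixed inputs and configuration, and the
report satisfies the count identity

``n_final = n_selected_new + n_rescued_v1 - n_replaced_v2 + n_replacing_v1
- n_redundant_removed``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

from .annotation_io import AnnotationSet, GeneModel
from .evidence import ReadAlignmentSet, is_expressed, support_table
from .homology import (
    LengthArbitration,
    OrthologTable,
    SimilarityHit,
    arbitrate_length,
    build_ortholog_table,
    length_difference_outliers,
)
from .interval_engine import (
    ChangeComponent,
    build_overlap_graph,
    classify_components,
    find_redundant,
    overlap_fraction,
)
from .te_classify import TEClassification, TEInterval, classify_annotation

__all__ = [
    "ReconciliationConfig",
    "ReconciliationReport",
    "PipelineError",
    "select_new_models",
    "rescue_v1_models",
    "apply_arbitration",
    "assign_gene_ids",
    "rename_annotation",
    "run_pipeline",
]

#: suffix given to legacy models that re-enter the updated set (rescue or
#: arbitration), so that the change graph never sees one id on both sides.
REINTRODUCED_SUFFIX = ".r"

DEFAULT_SPECIES = ("Athaliana", "Crubella", "Brapa", "Sparvula", "Aalpina")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class ReconciliationConfig:
    """Thresholds and conventions of the update procedure.

    Defaults encode the published procedure where it states them: 30 %
    overlap of the shorter model, five supporting reads, RBH e-value cutoff
    0.001, +/- one standard deviation for length outliers, and identifiers
    incremented by 10 starting at 10.
    """

    overlap_threshold: float = 0.30
    min_support_reads: int = 5
    rbh_max_e: float = 0.001
    sd_multiplier: float = 1.0
    same_strand_overlap: bool = True
    overlap_mode: str = "span"
    te_e_threshold: float = 0.001
    id_prefix: str = "AL"
    id_start: int = 10
    id_step: int = 10
    id_pad_width: int = 5
    n_anchored_scaffolds: int = 8
    arbitration_species: tuple[str, str] = ("Athaliana", "Crubella")

    def __post_init__(self) -> None:
        for name in (
            "overlap_threshold",
            "min_support_reads",
            "rbh_max_e",
            "sd_multiplier",
            "id_start",
            "id_step",
            "id_pad_width",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must be in (0, 1]")


@dataclass
class ReconciliationReport:
    """The change ledger of one pipeline run."""

    n_selected_new: int = 0
    n_rescued_v1: int = 0
    n_replaced_v2: int = 0
    n_replacing_v1: int = 0
    n_redundant_removed: int = 0
    n_final: int = 0
    change_components: list[ChangeComponent] = field(default_factory=list)
    n_unchanged: int = 0
    n_updated: int = 0
    n_removed: int = 0
    n_added: int = 0
    id_map: dict[str, str] = field(default_factory=dict)
    rename_map: dict[str, str] = field(default_factory=dict)
    arbitrations: list[LengthArbitration] = field(default_factory=list)
    te_classifications: dict[str, TEClassification] = field(default_factory=dict)
    n_te: int = 0
    n_protein_coding: int = 0
    stage_counts: dict[str, int] = field(default_factory=dict)

    def count_identity_holds(self) -> bool:
        return self.n_final == (
            self.n_selected_new
            + self.n_rescued_v1
            - self.n_replaced_v2
            + self.n_replacing_v1
            - self.n_redundant_removed
        )

    def removed_v1_ids(self) -> list[str]:
        return sorted(
            gid
            for c in self.change_components
            if c.kind == "v1_only"
            for gid in c.v1_members
        )

    def added_v2_ids(self) -> list[str]:
        return sorted(
            gid
            for c in self.change_components
            if c.kind == "v2_only"
            for gid in c.v2_members
        )

    def components_of_kind(self, kind: str) -> list[ChangeComponent]:
        return [c for c in self.change_components if c.kind == kind]

    def te_gene_ids(self) -> list[str]:
        return sorted(
            gid for gid, cls in self.te_classifications.items() if cls.is_te
        )

    def to_dict(self) -> dict:
        return {
            "n_selected_new": self.n_selected_new,
            "n_rescued_v1": self.n_rescued_v1,
            "n_replaced_v2": self.n_replaced_v2,
            "n_replacing_v1": self.n_replacing_v1,
            "n_redundant_removed": self.n_redundant_removed,
            "n_final": self.n_final,
            "n_unchanged": self.n_unchanged,
            "n_updated": self.n_updated,
            "n_removed": self.n_removed,
            "n_added": self.n_added,
            "n_te": self.n_te,
            "n_protein_coding": self.n_protein_coding,
            "count_identity_holds": self.count_identity_holds(),
            "change_components": [
                {
                    "v1_ids": list(c.sorted_v1()),
                    "v2_ids": list(c.sorted_v2()),
                    "kind": c.kind,
                }
                for c in self.change_components
            ],
            "arbitrations": [
                {
                    "v1_id": a.v1_id,
                    "v2_id": a.v2_id,
                    "len_v1": a.len_v1,
                    "len_v2": a.len_v2,
                    "outlier": a.outlier,
                    "decision": a.decision,
                }
                for a in self.arbitrations
            ],
            "id_map": self.id_map,
            "stage_counts": self.stage_counts,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------


def _overlaps_any(
    model: GeneModel,
    other: AnnotationSet,
    cfg: ReconciliationConfig,
) -> bool:
    span = model.span
    for candidate in other.overlapping(model.scaffold, span.start, span.end):
        fraction = overlap_fraction(
            model,
            candidate,
            mode=cfg.overlap_mode,
            same_strand=cfg.same_strand_overlap,
        )
        if fraction >= cfg.overlap_threshold:
            return True
    return False


def select_new_models(
    candidates: AnnotationSet,
    v1: AnnotationSet,
    support: Mapping[str, int],
    cfg: ReconciliationConfig,
) -> AnnotationSet:
    """Candidates that are expressed OR overlap a legacy model at threshold."""
    selected = AnnotationSet()
    for model in candidates:
        if is_expressed(support.get(model.id, 0), cfg.min_support_reads):
            selected.add(model, validate=False)
        elif _overlaps_any(model, v1, cfg):
            selected.add(model, validate=False)
    return selected


def rescue_v1_models(
    v1: AnnotationSet,
    selected: AnnotationSet,
    support: Mapping[str, int],
    orthologs: OrthologTable,
    cfg: ReconciliationConfig,
) -> AnnotationSet:
    """Legacy models with no overlap to any selected model but with evidence.

    Evidence is either expression (>= ``min_support_reads``) or an ortholog
    in at least one of the declared relative species.  An empty species list
    is an error: the rescue rule would silently degenerate.
    """
    if not orthologs.species:
        raise ValueError("ortholog table declares no species")
    rescued = AnnotationSet()
    for model in v1:
        if _overlaps_any(model, selected, cfg):
            continue
        if is_expressed(support.get(model.id, 0), cfg.min_support_reads) or (
            orthologs.has_ortholog(model.id)
        ):
            rescued.add(model, validate=False)
    return rescued


def _reintroduce(model: GeneModel) -> GeneModel:
    """Copy a legacy model under a fresh id for insertion into the new set."""
    new_id = model.id + REINTRODUCED_SUFFIX
    return dc_replace(
        model,
        id=new_id,
        transcripts=tuple(
            dc_replace(t, gene_id=new_id) for t in model.transcripts
        ),
    )


def _components_between(
    v1: AnnotationSet,
    current: AnnotationSet,
    cfg: ReconciliationConfig,
) -> list[ChangeComponent]:
    """Change components between two sets, tolerating shared id namespaces.

    ``classify_components`` rejects an id on both sides (it cannot tell the
    sides apart from an edge list alone); here edge endpoints are known by
    construction, so colliding v2 ids are tagged internally and untagged in
    the result.  This is what makes re-running the pipeline on its own
    output well defined.
    """
    edges = build_overlap_graph(
        v1,
        current,
        threshold=cfg.overlap_threshold,
        mode=cfg.overlap_mode,
        same_strand=cfg.same_strand_overlap,
    )
    if not set(v1.ids()) & set(current.ids()):
        return classify_components(edges, v1.ids(), current.ids())
    tag = "\t"  # ids are tab-free (they come from tab-separated formats)
    tagged = [dc_replace(e, model_b=tag + e.model_b) for e in edges]
    components = classify_components(
        tagged, v1.ids(), [tag + gid for gid in current.ids()]
    )
    return [
        ChangeComponent(
            c.v1_members,
            frozenset(gid[len(tag) :] for gid in c.v2_members),
            c.kind,
        )
        for c in components
    ]


def _v2_singleton_pairs(
    v1: AnnotationSet,
    current: AnnotationSet,
    cfg: ReconciliationConfig,
) -> tuple[list[tuple[str, str]], dict[str, tuple[str, ...]]]:
    """(v1_id, v2_id) protein-comparison pairs from components with one v2 member.

    Returns the sorted pair list and, per v2 id, the full v1 membership of
    its component (a replacement re-introduces all of them).
    """
    components = _components_between(v1, current, cfg)
    pairs: list[tuple[str, str]] = []
    v1_members_of: dict[str, tuple[str, ...]] = {}
    for component in components:
        if len(component.v2_members) != 1 or not component.v1_members:
            continue
        (v2_id,) = component.v2_members
        v1_members_of[v2_id] = component.sorted_v1()
        for v1_id in component.sorted_v1():
            pairs.append((v1_id, v2_id))
    return sorted(pairs), v1_members_of


def apply_arbitration(
    current: AnnotationSet,
    v1: AnnotationSet,
    orthologs: OrthologTable,
    cfg: ReconciliationConfig,
) -> tuple[AnnotationSet, list[LengthArbitration], int, int]:
    """Replace length-outlier updated models whose orthologs side with v1.

    Pairs come from overlap components with a single updated member, so a
    replaced updated model re-introduces every legacy member of its
    component.  Returns (updated set, decision log, n_replaced, n_replacing).
    """
    pairs, v1_members_of = _v2_singleton_pairs(v1, current, cfg)
    result = current.copy()
    records: list[LengthArbitration] = []
    if len(pairs) < 2:
        return result, records, 0, 0

    length_pairs = [
        (
            v1_id,
            v2_id,
            v1.get(v1_id).protein_length,
            current.get(v2_id).protein_length,
        )
        for v1_id, v2_id in pairs
    ]
    outliers = length_difference_outliers(length_pairs, cfg.sd_multiplier)

    to_replace: set[str] = set()
    for v1_id, v2_id, len_v1, len_v2 in length_pairs:
        # a re-introduced legacy model is its own pair partner; leave it be
        if v2_id == v1_id + REINTRODUCED_SUFFIX:
            records.append(
                LengthArbitration(v1_id, v2_id, len_v1, len_v2, False, "keep_v2")
            )
            continue
        if (v1_id, v2_id) not in outliers:
            records.append(
                LengthArbitration(v1_id, v2_id, len_v1, len_v2, False, "keep_v2")
            )
            continue
        ortholog_lengths = tuple(
            orthologs.ortholog_length(v1_id, species)
            for species in cfg.arbitration_species
        )
        decision = arbitrate_length(len_v1, len_v2, ortholog_lengths)
        records.append(
            LengthArbitration(v1_id, v2_id, len_v1, len_v2, True, decision)
        )
        if decision == "replace_with_v1":
            to_replace.add(v2_id)

    n_replaced = 0
    n_replacing = 0
    for v2_id in sorted(to_replace):
        result.remove(v2_id)
        n_replaced += 1
        for v1_id in v1_members_of[v2_id]:
            reintroduced = _reintroduce(v1.get(v1_id))
            if reintroduced.id not in result:
                result.add(reintroduced, validate=False)
                n_replacing += 1
    return result, records, n_replaced, n_replacing


_SCAFFOLD_NUMBER = re.compile(r"(\d+)$")


def scaffold_number(scaffold: str) -> int:
    """Trailing integer of a scaffold name ('scaffold_3' or '3' -> 3)."""
    match = _SCAFFOLD_NUMBER.search(scaffold)
    if match is None:
        raise ValueError(f"scaffold name {scaffold!r} has no trailing number")
    return int(match.group(1))


def assign_gene_ids(
    final: AnnotationSet,
    anchored_scaffolds: set[str],
    cfg: ReconciliationConfig,
) -> dict[str, str]:
    """Systematic ids ordered by position: prefix + scaffold + G/U + number.

    Numbering restarts per scaffold at ``id_start`` and increments by
    ``id_step``; anchored scaffolds get 'G', unanchored 'U'.  Position ties
    break by earlier end then lexicographic source id.
    """
    mapping: dict[str, str] = {}
    assigned: set[str] = set()
    by_scaffold: dict[str, list[GeneModel]] = {}
    for model in final:
        by_scaffold.setdefault(model.scaffold, []).append(model)
    for scaffold in sorted(by_scaffold, key=lambda s: (scaffold_number(s), s)):
        number = scaffold_number(scaffold)
        letter = "G" if scaffold in anchored_scaffolds else "U"
        models = sorted(
            by_scaffold[scaffold], key=lambda m: (m.span.start, m.span.end, m.id)
        )
        for index, model in enumerate(models):
            locus = cfg.id_start + index * cfg.id_step
            new_id = f"{cfg.id_prefix}{number}{letter}{locus:0{cfg.id_pad_width}d}"
            if new_id in assigned:
                raise RuntimeError(f"duplicate assigned gene id {new_id}")
            assigned.add(new_id)
            mapping[model.id] = new_id
    return mapping


def rename_annotation(final: AnnotationSet, mapping: Mapping[str, str]) -> AnnotationSet:
    """Apply an id map; transcripts are renumbered ``<gene>.<n>``."""
    renamed = AnnotationSet()
    for model in final:
        new_id = mapping[model.id]
        transcripts = tuple(
            dc_replace(t, id=f"{new_id}.{k}", gene_id=new_id)
            for k, t in enumerate(model.transcripts, start=1)
        )
        renamed.add(
            dc_replace(model, id=new_id, transcripts=transcripts, source="version2"),
            validate=False,
        )
    return renamed


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def _structurally_identical(a: GeneModel, b: GeneModel) -> bool:
    """Same span and the same set of exon chains (coordinates only)."""
    return (
        a.scaffold == b.scaffold
        and a.strand == b.strand
        and (a.span.start, a.span.end) == (b.span.start, b.span.end)
        and a.exon_chains() == b.exon_chains()
    )


def run_pipeline(
    v1: AnnotationSet,
    candidates: AnnotationSet,
    evidence: Mapping[str, int] | ReadAlignmentSet,
    hits: Sequence[SimilarityHit] = (),
    protein_lengths: Mapping[str, int] | None = None,
    te_intervals: Sequence[TEInterval] = (),
    te_hits: Sequence[SimilarityHit] = (),
    cfg: ReconciliationConfig | None = None,
    focal_species: str = "Alyrata",
    species: Sequence[str] = DEFAULT_SPECIES,
) -> tuple[AnnotationSet, ReconciliationReport]:
    """Run select -> rescue -> arbitrate -> dedup -> TE -> classify -> rename.

    ``evidence`` is either a precomputed model -> supporting-read-count
    mapping or a :class:`ReadAlignmentSet` (counted over both input sets).
    Returns the renamed final annotation and the reconciliation report; any
    stage error propagates as :class:`PipelineError` naming the stage.
    """
    cfg = cfg or ReconciliationConfig()
    report = ReconciliationReport()

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise PipelineError(f"stage '{name}': {exc}") from exc

    def _support() -> Mapping[str, int]:
        if isinstance(evidence, ReadAlignmentSet):
            table = support_table(v1, evidence)
            table.update(support_table(candidates, evidence))
            return table
        return evidence

    support = stage("evidence", _support)
    orthologs = stage(
        "orthology",
        lambda: build_ortholog_table(
            hits, focal_species, species, protein_lengths or {}, cfg.rbh_max_e
        ),
    )

    selected = stage(
        "select", lambda: select_new_models(candidates, v1, support, cfg)
    )
    report.n_selected_new = len(selected)

    rescued = stage(
        "rescue", lambda: rescue_v1_models(v1, selected, support, orthologs, cfg)
    )
    report.n_rescued_v1 = len(rescued)

    working = selected.copy()
    for model in rescued:
        working.add(_reintroduce(model), validate=False)

    working, arbitrations, n_replaced, n_replacing = stage(
        "arbitrate", lambda: apply_arbitration(working, v1, orthologs, cfg)
    )
    report.arbitrations = arbitrations
    report.n_replaced_v2 = n_replaced
    report.n_replacing_v1 = n_replacing

    def _dedup():
        redundant = find_redundant(working)
        for _, dropped in redundant:
            working.remove(dropped)
        return len(redundant)

    report.n_redundant_removed = stage("deduplicate", _dedup)
    report.n_final = len(working)

    report.te_classifications = stage(
        "te_classify",
        lambda: classify_annotation(working, te_intervals, te_hits, cfg.te_e_threshold),
    )
    report.n_te = sum(1 for c in report.te_classifications.values() if c.is_te)
    report.n_protein_coding = report.n_final - report.n_te

    report.change_components = stage(
        "change_classify", lambda: _components_between(v1, working, cfg)
    )
    unchanged_v1: set[str] = set()
    for component in report.change_components:
        if component.kind == "one_to_one":
            (v1_id,) = component.v1_members
            (v2_id,) = component.v2_members
            if _structurally_identical(v1.get(v1_id), working.get(v2_id)):
                unchanged_v1.add(v1_id)
    report.n_removed = len(report.removed_v1_ids())
    report.n_added = len(report.added_v2_ids())
    report.n_unchanged = len(unchanged_v1)
    report.n_updated = len(v1) - report.n_removed - report.n_unchanged

    def _assign():
        anchored = {
            scaffold
            for scaffold in working.scaffolds()
            if scaffold_number(scaffold) <= cfg.n_anchored_scaffolds
        }
        return assign_gene_ids(working, anchored, cfg)

    report.rename_map = stage("assign_ids", _assign)
    final = stage("rename", lambda: rename_annotation(working, report.rename_map))

    # total old -> new id map: every v1 id resolves to its successor(s) or
    # "removed"; models without a v1 predecessor map from their new id to
    # "added"
    id_map: dict[str, str] = {}
    for component in report.change_components:
        new_ids = sorted(report.rename_map[v2_id] for v2_id in component.v2_members)
        for v1_id in component.sorted_v1():
            id_map[v1_id] = ",".join(new_ids) if new_ids else "removed"
        if not component.v1_members:
            for v2_id in component.sorted_v2():
                id_map[report.rename_map[v2_id]] = "added"
    report.id_map = id_map

    report.stage_counts = {
        "selected": report.n_selected_new,
        "rescued": report.n_rescued_v1,
        "replaced_v2": report.n_replaced_v2,
        "replacing_v1": report.n_replacing_v1,
        "redundant_removed": report.n_redundant_removed,
        "final": report.n_final,
        "te": report.n_te,
        "protein_coding": report.n_protein_coding,
        "unchanged": report.n_unchanged,
        "updated": report.n_updated,
        "removed": report.n_removed,
        "added": report.n_added,
    }
    return final, report
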