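"""Transposable-element gene classification.

A gene model is called TE-coding when (a) a TE annotated as complete lies
entirely within the gene's coding region (first to last CDS base of any
transcript), (b) the whole gene span is contained in a single TE interval,
or (c) the gene has a similarity hit to a declared set of known TE genes at
or below an e-value threshold.  Each reason is recorded so downstream
reports can show why a gene was reclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import pandas as pd

from .annotation_io import AnnotationSet, GeneModel
from .homology import SimilarityHit

__all__ = [
    "TEInterval",
    "TEClassification",
    "classify_te",
    "classify_annotation",
    "partition_annotation",
    "read_te_bed",
    "write_te_bed",
    "read_te_gff3",
    "classifications_to_tsv",
]

TE_REASONS = ("complete_te_in_cds", "spanned_by_te", "te_gene_similarity")


@dataclass(frozen=True, order=True)
class TEInterval:
    """A TE annotation interval with a completeness flag."""

    scaffold: str
    start: int
    end: int
    strand: str = "."
    family: str = "unknown"
    complete: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid TE interval {self.scaffold}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class TEClassification:
    gene_id: str
    is_te: bool
    reasons: frozenset[str]

    def __post_init__(self) -> None:
        if self.is_te != bool(self.reasons):
            raise ValueError("is_te must equal 'reasons non-empty'")
        unknown = self.reasons - set(TE_REASONS)
        if unknown:
            raise ValueError(f"unknown TE reasons: {', '.join(sorted(unknown))}")


def _cds_extents(model: GeneModel) -> list[tuple[int, int]]:
    """Genomic [first, last) CDS extent per transcript that has a CDS."""
    extents = []
    for transcript in model.transcripts:
        if transcript.cds:
            extents.append((transcript.cds[0].start, transcript.cds[-1].end))
    return extents


def classify_te(
    model: GeneModel,
    te_intervals: Iterable[TEInterval],
    te_hits: Iterable[SimilarityHit] = (),
    e_threshold: float = 0.001,
) -> TEClassification:
    """Classify one gene model against TE intervals and TE-gene hits."""
    reasons: set[str] = set()
    span = model.span
    extents = _cds_extents(model)
    for te in te_intervals:
        if te.scaffold != model.scaffold:
            continue
        if te.complete and any(
            lo <= te.start and te.end <= hi for lo, hi in extents
        ):
            reasons.add("complete_te_in_cds")
        if te.start <= span.start and span.end <= te.end:
            reasons.add("spanned_by_te")
    for hit in te_hits:
        if hit.query_id == model.id and hit.e_value <= e_threshold:
            reasons.add("te_gene_similarity")
            break
    return TEClassification(model.id, bool(reasons), frozenset(reasons))


def classify_annotation(
    annotation: AnnotationSet,
    te_intervals: Sequence[TEInterval],
    te_hits: Sequence[SimilarityHit] = (),
    e_threshold: float = 0.001,
) -> dict[str, TEClassification]:
    """TE classification for every gene, with TEs bucketed per scaffold."""
    by_scaffold: dict[str, list[TEInterval]] = {}
    for te in te_intervals:
        by_scaffold.setdefault(te.scaffold, []).append(te)
    hits_by_gene: dict[str, list[SimilarityHit]] = {}
    for hit in te_hits:
        hits_by_gene.setdefault(hit.query_id, []).append(hit)
    return {
        model.id: classify_te(
            model,
            by_scaffold.get(model.scaffold, ()),
            hits_by_gene.get(model.id, ()),
            e_threshold,
        )
        for model in annotation
    }


def partition_annotation(
    annotation: AnnotationSet,
    classifications: Mapping[str, TEClassification],
) -> tuple[AnnotationSet, AnnotationSet]:
    """Split an annotation into (protein_coding, te_coding) disjoint sets."""
    missing = [m.id for m in annotation if m.id not in classifications]
    if missing:
        raise ValueError(
            "missing TE classification for: " + ", ".join(sorted(missing)[:10])
        )
    protein_coding, te_coding = AnnotationSet(), AnnotationSet()
    for model in annotation:
        if classifications[model.id].is_te:
            te_coding.add(model, validate=False)
        else:
            protein_coding.add(model, validate=False)
    return protein_coding, te_coding


# ---------------------------------------------------------------------------
# I/O: BED6+2 (family, complete) and GFF3
# ---------------------------------------------------------------------------

_TRUTHY = {"1", "true", "True", "TRUE", "yes"}


def read_te_bed(path: Union[str, Path, IO[str]]) -> list[TEInterval]:
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["scaffold", "start", "end", "name", "score", "strand", "family", "complete"],
        dtype={"scaffold": str, "start": int, "end": int},
    )
    return [
        TEInterval(
            row.scaffold,
            row.start,
            row.end,
            row.strand if row.strand in ("+", "-") else ".",
            str(row.family),
            str(row.complete) in _TRUTHY,
        )
        for row in frame.itertuples(index=False)
    ]


def write_te_bed(te_intervals: Sequence[TEInterval], path: Union[str, Path, IO[str]]) -> None:
    pd.DataFrame(
        [
            (
                te.scaffold,
                te.start,
                te.end,
                f"{te.family}_{i}",
                0,
                te.strand,
                te.family,
                int(te.complete),
            )
            for i, te in enumerate(sorted(te_intervals))
        ],
    ).to_csv(path, sep="\t", index=False, header=False)


def read_te_gff3(path: Union[str, Path, IO[str]]) -> list[TEInterval]:
    """TE intervals from GFF3; family/complete come from the attribute column."""
    out: list[TEInterval] = []
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"expected 9 columns in TE GFF3, got {len(fields)}")
            attrs = dict(
                part.split("=", 1) for part in fields[8].split(";") if "=" in part
            )
            out.append(
                TEInterval(
                    fields[0],
                    int(fields[3]) - 1,
                    int(fields[4]),
                    fields[6] if fields[6] in ("+", "-") else ".",
                    attrs.get("family", fields[2]),
                    attrs.get("complete", "false") in _TRUTHY,
                )
            )
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    return out


def classifications_to_tsv(
    classifications: Mapping[str, TEClassification], path: Union[str, Path, IO[str]]
) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": gene,
                "is_te": int(cls.is_te),
                "reasons": ",".join(sorted(cls.reasons)),
            }
            for gene, cls in sorted(classifications.items())
        ],
        columns=["gene_id", "is_te", "reasons"],
    ).to_csv(path, sep="\t", index=False)
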