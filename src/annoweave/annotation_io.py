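"""GFF3 gene-model I/O and the hierarchical containers used across the package.

On disk GFF3 coordinates are 1-based inclusive; in memory every interval is
0-based half-open.  The conversion happens only inside :func:`parse_gff3` and
:func:`write_gff3`, so overlap arithmetic elsewhere never has to reason about
inclusive endpoints.

The object model is a three-level hierarchy:

``AnnotationSet`` -> ``GeneModel`` -> ``Transcript`` -> exon / CDS
``GenomicInterval``\\ s.

A gene's span is always derived from the union of its transcript exons, and a
transcript's protein length is derived from its CDS chain (``total CDS nt // 3``,
stop codon not treated specially).  Genes written without explicit mRNA
children are given a single implicit transcript, which covers the older GFF
dialects that attach exons directly to the gene line.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Union

import pandas as pd
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

__all__ = [
    "AnnotationError",
    "Gff3ParseError",
    "GenomicInterval",
    "Transcript",
    "GeneModel",
    "AnnotationSet",
    "parse_gff3",
    "write_gff3",
    "protein_length",
    "write_summary_tsv",
]

STRANDS = ("+", "-", ".")

#: feature types assembled into gene models; anything else (UTRs, chromosome
#: lines, ...) is derivable or out of scope and silently skipped on parse.
_GENE_TYPES = ("gene",)
_TRANSCRIPT_TYPES = ("mRNA", "transcript")
_EXON_TYPES = ("exon",)
_CDS_TYPES = ("CDS",)


class AnnotationError(ValueError):
    """A gene-model record violates a structural invariant."""


class Gff3ParseError(AnnotationError):
    """A GFF3 line could not be interpreted; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a scaffold."""

    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise AnnotationError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_nt(self, other: "GenomicInterval") -> int:
        """Number of shared nucleotides; 0 for different scaffolds."""
        if self.scaffold != other.scaffold:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start <= other.start
            and other.end <= self.end
        )


def _as_sorted_intervals(segments: Iterable[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    return tuple(sorted(segments, key=lambda s: (s.start, s.end)))


@dataclass(frozen=True)
class Transcript:
    """One isoform: an exon chain plus an optional CDS chain."""

    id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", _as_sorted_intervals(self.exons))
        object.__setattr__(self, "cds", _as_sorted_intervals(self.cds))

    # -- derived structure ------------------------------------------------
    @property
    def scaffold(self) -> str:
        return self.exons[0].scaffold

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.scaffold, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def exon_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((e.start, e.end) for e in self.exons)

    @property
    def cds_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((c.start, c.end) for c in self.cds)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for left, right in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.scaffold, left.end, right.start, self.strand))
        return tuple(out)

    @property
    def protein_length(self) -> int:
        """Amino-acid count: total CDS nucleotides floor-divided by three."""
        return sum(c.length for c in self.cds) // 3

    def validate(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.id}: no exons")
        for seg in self.exons + self.cds:
            if seg.length <= 0:
                raise AnnotationError(
                    f"transcript {self.id}: zero-length segment at "
                    f"{seg.scaffold}:{seg.start}-{seg.end}"
                )
            if seg.scaffold != self.scaffold or seg.strand != self.strand:
                raise AnnotationError(
                    f"transcript {self.id}: segments disagree on scaffold/strand"
                )
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start < left.end:
                raise AnnotationError(
                    f"transcript {self.id}: overlapping exons "
                    f"{left.start}-{left.end} and {right.start}-{right.end}"
                )
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise AnnotationError(
                    f"transcript {self.id}: CDS {c.start}-{c.end} not contained "
                    "in any exon"
                )


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with one or more transcripts, tagged with its source set."""

    id: str
    transcripts: tuple[Transcript, ...]
    source: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "transcripts", tuple(self.transcripts))

    @property
    def scaffold(self) -> str:
        return self.transcripts[0].scaffold

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.exons[0].start for t in self.transcripts)
        end = max(t.exons[-1].end for t in self.transcripts)
        return GenomicInterval(self.scaffold, start, end, self.strand)

    @property
    def protein_length(self) -> int:
        """Longest protein over the gene's transcripts (0 without CDS)."""
        return max((t.protein_length for t in self.transcripts), default=0)

    def exon_chains(self) -> frozenset[tuple[tuple[int, int], ...]]:
        return frozenset(t.exon_chain for t in self.transcripts)

    def validate(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.id}: no transcripts")
        for t in self.transcripts:
            t.validate()
            if t.gene_id != self.id:
                raise AnnotationError(
                    f"gene {self.id}: transcript {t.id} claims parent {t.gene_id}"
                )
            if t.scaffold != self.scaffold or t.strand != self.strand:
                raise AnnotationError(
                    f"gene {self.id}: transcripts disagree on scaffold/strand"
                )


def protein_length(transcript: Transcript) -> int:
    """Amino-acid count of a transcript: floor(total CDS nt / 3)."""
    return transcript.protein_length


class AnnotationSet:
    """A collection of gene models with a per-scaffold interval index.

    Iteration order is deterministic: (scaffold, span start, span end, id).
    ``overlapping`` answers span-overlap queries via an interval tree and is
    testable against a linear scan.
    """

    def __init__(self, models: Iterable[GeneModel] = (), validate: bool = True):
        self._models: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for model in models:
            self.add(model, validate=validate)

    # -- mutation ---------------------------------------------------------
    def add(self, model: GeneModel, validate: bool = True) -> None:
        if model.id in self._models:
            raise AnnotationError(f"duplicate gene id {model.id}")
        if validate:
            model.validate()
        self._models[model.id] = model
        span = model.span
        self._trees.setdefault(model.scaffold, IntervalTree()).addi(
            span.start, span.end, model.id
        )

    def remove(self, gene_id: str) -> GeneModel:
        model = self._models.pop(gene_id)
        span = model.span
        self._trees[model.scaffold].removei(span.start, span.end, model.id)
        return model

    # -- access -----------------------------------------------------------
    def get(self, gene_id: str) -> GeneModel:
        return self._models[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._models

    def __len__(self) -> int:
        return len(self._models)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(
            sorted(
                self._models.values(),
                key=lambda m: (m.scaffold, m.span.start, m.span.end, m.id),
            )
        )

    def ids(self) -> list[str]:
        return sorted(self._models)

    def scaffolds(self) -> list[str]:
        return sorted(self._trees)

    def overlapping(self, scaffold: str, start: int, end: int) -> list[GeneModel]:
        """All models whose span overlaps [start, end) on a scaffold."""
        tree = self._trees.get(scaffold)
        if tree is None:
            return []
        hits = [self._models[iv.data] for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda m: (m.span.start, m.span.end, m.id))

    def copy(self) -> "AnnotationSet":
        return AnnotationSet(self._models.values(), validate=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self._models == other._models

    def structurally_equal(self, other: "AnnotationSet") -> bool:
        """Coordinate-level equality that ignores gene/transcript ids and sources."""
        if len(self) != len(other):
            return False

        def key(ann: "AnnotationSet"):
            return sorted(
                (
                    m.scaffold,
                    m.strand,
                    tuple(sorted((t.exon_chain, t.cds_chain) for t in m.transcripts)),
                )
                for m in ann
            )

        return key(self) == key(other)


# ---------------------------------------------------------------------------
# GFF3 parsing
# ---------------------------------------------------------------------------

PathOrHandle = Union[str, Path, IO[str]]


def _open_text(path: PathOrHandle, mode: str):
    if isinstance(path, (str, Path)):
        return open(path, mode), True
    return path, False


def parse_gff3(path: PathOrHandle) -> AnnotationSet:
    """Read a GFF3 file into an :class:`AnnotationSet`.

    gene/mRNA/exon/CDS features are assembled by their ID/Parent attributes;
    UTR and unrelated feature lines are skipped.  Malformed lines (wrong column
    count, non-integer or reversed coordinates, unknown ``Parent``) raise a
    :class:`Gff3ParseError` naming the line number.  Parents may appear after
    their children.
    """
    handle, close = _open_text(path, "r")
    genes: dict[str, tuple] = {}  # id -> (feature, line_no, source)
    mrnas: dict[str, tuple] = {}  # id -> (feature, line_no, parent_ids)
    parts: list[tuple] = []  # (kind, feature, line_no, parent_ids)
    order: list[str] = []  # gene ids in file order

    try:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3ParseError(
                    f"expected 9 tab-separated columns, got {len(fields)}", line_no
                )
            try:
                feature = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise Gff3ParseError(f"unparseable GFF3 line ({exc})", line_no) from exc
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise Gff3ParseError("non-integer coordinates", line_no) from exc
            if start > end:
                raise Gff3ParseError(f"start {start} > end {end}", line_no)

            ftype = feature.featuretype
            attrs = feature.attributes
            if ftype in _GENE_TYPES:
                fid = attrs.get("ID", [None])[0]
                if fid is None:
                    raise Gff3ParseError("gene feature without ID attribute", line_no)
                if fid in genes:
                    raise Gff3ParseError(f"duplicate gene ID {fid}", line_no)
                genes[fid] = (feature, line_no)
                order.append(fid)
            elif ftype in _TRANSCRIPT_TYPES:
                fid = attrs.get("ID", [None])[0]
                if fid is None:
                    raise Gff3ParseError("mRNA feature without ID attribute", line_no)
                parents = attrs.get("Parent", [])
                if not parents:
                    raise Gff3ParseError(f"mRNA {fid} without Parent", line_no)
                mrnas[fid] = (feature, line_no, tuple(parents))
            elif ftype in _EXON_TYPES or ftype in _CDS_TYPES:
                parents = attrs.get("Parent", [])
                if not parents:
                    raise Gff3ParseError(f"{ftype} feature without Parent", line_no)
                kind = "exon" if ftype in _EXON_TYPES else "cds"
                parts.append((kind, feature, line_no, tuple(parents)))
            # other feature types: derivable (UTRs) or out of scope; skip
    finally:
        if close:
            handle.close()

    # resolve mRNA -> gene
    gene_children: dict[str, list[str]] = {gid: [] for gid in genes}
    for tid, (feature, line_no, parents) in mrnas.items():
        for parent in parents:
            if parent not in genes:
                raise Gff3ParseError(f"unknown Parent {parent} for mRNA {tid}", line_no)
            gene_children[parent].append(tid)

    # attach exon/CDS segments to transcripts (or implicitly to genes)
    tx_segments: dict[str, dict[str, list[GenomicInterval]]] = {
        tid: {"exon": [], "cds": []} for tid in mrnas
    }
    implicit_segments: dict[str, dict[str, list[GenomicInterval]]] = {}
    for kind, feature, line_no, parents in parts:
        iv = GenomicInterval(
            feature.seqid,
            feature.start - 1,
            feature.end,
            feature.strand if feature.strand in STRANDS else ".",
        )
        for parent in parents:
            if parent in tx_segments:
                tx_segments[parent][kind].append(iv)
            elif parent in genes:
                implicit_segments.setdefault(parent, {"exon": [], "cds": []})[
                    kind
                ].append(iv)
            else:
                raise Gff3ParseError(
                    f"unknown Parent {parent} for {kind} feature", line_no
                )

    def _feature_interval(feature) -> GenomicInterval:
        return GenomicInterval(
            feature.seqid,
            feature.start - 1,
            feature.end,
            feature.strand if feature.strand in STRANDS else ".",
        )

    annotation = AnnotationSet()
    for gid in order:
        gene_feature, gene_line = genes[gid]
        transcripts: list[Transcript] = []
        for tid in gene_children[gid]:
            mrna_feature, _, _ = mrnas[tid]
            exons = tx_segments[tid]["exon"]
            cds = tx_segments[tid]["cds"]
            if not exons:
                # exon-less mRNA: treat its own extent as a single exon
                exons = [_feature_interval(mrna_feature)]
            transcripts.append(Transcript(tid, gid, tuple(exons), tuple(cds)))
        if gid in implicit_segments or not transcripts:
            segs = implicit_segments.get(gid, {"exon": [], "cds": []})
            exons = segs["exon"] or [_feature_interval(gene_feature)]
            transcripts.append(
                Transcript(f"{gid}.t1", gid, tuple(exons), tuple(segs["cds"]))
            )
        model = GeneModel(gid, tuple(transcripts), source=gene_feature.source or "unknown")
        try:
            annotation.add(model)
        except AnnotationError as exc:
            raise Gff3ParseError(str(exc), gene_line) from exc
    return annotation


# ---------------------------------------------------------------------------
# GFF3 writing
# ---------------------------------------------------------------------------


def _cds_phases(transcript: Transcript) -> dict[GenomicInterval, int]:
    """GFF3 phase per CDS segment, walking the CDS 5'->3'."""
    segments = list(transcript.cds)
    if transcript.strand == "-":
        segments = segments[::-1]
    phases = {}
    consumed = 0
    for seg in segments:
        phases[seg] = (3 - consumed % 3) % 3
        consumed += seg.length
    return phases


def _utr_segments(transcript: Transcript) -> list[tuple[str, GenomicInterval]]:
    """Derive five_prime/three_prime UTR intervals from exons minus the CDS extent."""
    if not transcript.cds:
        return []
    cds_lo = transcript.cds[0].start
    cds_hi = transcript.cds[-1].end
    left_kind = "five_prime_UTR" if transcript.strand != "-" else "three_prime_UTR"
    right_kind = "three_prime_UTR" if transcript.strand != "-" else "five_prime_UTR"
    out = []
    for exon in transcript.exons:
        if exon.start < cds_lo:
            out.append(
                (
                    left_kind,
                    GenomicInterval(
                        exon.scaffold, exon.start, min(exon.end, cds_lo), exon.strand
                    ),
                )
            )
        if exon.end > cds_hi:
            out.append(
                (
                    right_kind,
                    GenomicInterval(
                        exon.scaffold, max(exon.start, cds_hi), exon.end, exon.strand
                    ),
                )
            )
    return out


def write_gff3(
    annotation: AnnotationSet, path: PathOrHandle, emit_utrs: bool = True
) -> None:
    """Write an annotation as GFF3, sorted by scaffold then start position.

    Exon and CDS lines are always emitted; UTR lines are derived from the
    exon/CDS difference when ``emit_utrs`` is set.  ``parse_gff3`` of the
    output reconstructs the annotation exactly (round-trip identity).
    """
    handle, close = _open_text(path, "w")

    def row(scaffold, source, ftype, iv: GenomicInterval, strand, attrs, phase="."):
        handle.write(
            "\t".join(
                [
                    scaffold,
                    source,
                    ftype,
                    str(iv.start + 1),
                    str(iv.end),
                    ".",
                    strand,
                    str(phase),
                    attrs,
                ]
            )
            + "\n"
        )

    try:
        handle.write("##gff-version 3\n")
        for model in annotation:
            source = model.source or "unknown"
            span = model.span
            row(model.scaffold, source, "gene", span, model.strand, f"ID={model.id}")
            for t in model.transcripts:
                row(
                    model.scaffold,
                    source,
                    "mRNA",
                    t.span,
                    model.strand,
                    f"ID={t.id};Parent={model.id}",
                )
                for exon in t.exons:
                    row(
                        model.scaffold,
                        source,
                        "exon",
                        exon,
                        model.strand,
                        f"Parent={t.id}",
                    )
                phases = _cds_phases(t)
                for cds in t.cds:
                    row(
                        model.scaffold,
                        source,
                        "CDS",
                        cds,
                        model.strand,
                        f"Parent={t.id}",
                        phase=phases[cds],
                    )
                if emit_utrs:
                    for kind, iv in _utr_segments(t):
                        row(model.scaffold, source, kind, iv, model.strand, f"Parent={t.id}")
    finally:
        if close:
            handle.close()


def write_summary_tsv(annotation: AnnotationSet, path: PathOrHandle) -> None:
    """Per-gene summary table (coordinates 1-based inclusive, as on disk)."""
    rows = [
        {
            "id": m.id,
            "scaffold": m.scaffold,
            "start": m.span.start + 1,
            "end": m.span.end,
            "strand": m.strand,
            "n_transcripts": len(m.transcripts),
            "protein_length": m.protein_length,
        }
        for m in annotation
    ]
    pd.DataFrame(
        rows,
        columns=[
            "id",
            "scaffold",
            "start",
            "end",
            "strand",
            "n_transcripts",
            "protein_length",
        ],
    ).to_csv(path, sep="\t", index=False)
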