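"""Expression evidence: read support, the >=5-read expression rule, FPKM and
threshold-based differential-expression calls.

A gene model counts a read as supporting when the aligned interval overlaps
at least one exonic nucleotide of any of its transcripts; each read counts at
most once per model, and reads are counted strand-agnostically (the data this
models is strand-unspecific).  A model with five or more supporting reads is
"expressed", irrespective of its length.

The differential-expression caller is a deliberately simple stand-in for
isoform-deconvolution methods: per gene, a two-sided Fisher exact test of
pooled counts (gene vs rest of library, condition A vs B), with the fold
change computed on mean FPKM after adding a pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation_io import AnnotationSet, GeneModel

__all__ = [
    "ReadAlignment",
    "ReadAlignmentSet",
    "count_supporting_reads",
    "support_table",
    "is_expressed",
    "exon_union_length",
    "exon_length_table",
    "fpkm",
    "differential_genes",
    "read_support_tsv",
    "write_support_tsv",
]

CONDITIONS = ("WT", "HS", "REC")


@dataclass(frozen=True, order=True)
class ReadAlignment:
    """One aligned read reduced to its genomic interval and sample of origin."""

    scaffold: str
    start: int
    end: int
    sample_id: str = "pooled"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid read interval {self.scaffold}:{self.start}-{self.end}"
            )


class ReadAlignmentSet:
    """Aligned-read intervals indexed per scaffold for exon-overlap queries."""

    def __init__(
        self,
        records: Iterable[ReadAlignment],
        samples: Sequence[str] | None = None,
    ):
        self.records: tuple[ReadAlignment, ...] = tuple(records)
        if samples is not None:
            declared = set(samples)
            unknown = {r.sample_id for r in self.records} - declared
            if unknown:
                raise ValueError(
                    "sample ids not in the declared sample table: "
                    + ", ".join(sorted(unknown))
                )
            self.samples: tuple[str, ...] = tuple(samples)
        else:
            self.samples = tuple(sorted({r.sample_id for r in self.records}))
        self._trees: dict[str, IntervalTree] = {}
        for idx, record in enumerate(self.records):
            self._trees.setdefault(record.scaffold, IntervalTree()).addi(
                record.start, record.end, idx
            )

    def __len__(self) -> int:
        return len(self.records)

    def overlapping_indices(self, scaffold: str, start: int, end: int) -> set[int]:
        tree = self._trees.get(scaffold)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    # -- BED3+sample I/O --------------------------------------------------
    @classmethod
    def from_bed(
        cls, path: Union[str, Path, IO[str]], samples: Sequence[str] | None = None
    ) -> "ReadAlignmentSet":
        frame = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["scaffold", "start", "end", "sample_id"],
            dtype={"scaffold": str, "start": int, "end": int, "sample_id": str},
        )
        records = [
            ReadAlignment(row.scaffold, row.start, row.end, row.sample_id)
            for row in frame.itertuples(index=False)
        ]
        return cls(records, samples=samples)

    def to_bed(self, path: Union[str, Path, IO[str]]) -> None:
        pd.DataFrame(
            [(r.scaffold, r.start, r.end, r.sample_id) for r in self.records],
            columns=["scaffold", "start", "end", "sample_id"],
        ).to_csv(path, sep="\t", index=False, header=False)


def count_supporting_reads(model: GeneModel, alignments: ReadAlignmentSet) -> int:
    """Reads overlapping >=1 nt of any exon of any transcript, each once."""
    indices: set[int] = set()
    for transcript in model.transcripts:
        for exon in transcript.exons:
            indices |= alignments.overlapping_indices(
                exon.scaffold, exon.start, exon.end
            )
    return len(indices)


def support_table(
    annotation: AnnotationSet, alignments: ReadAlignmentSet
) -> dict[str, int]:
    """Supporting-read count for every model in the annotation (default 0)."""
    return {m.id: count_supporting_reads(m, alignments) for m in annotation}


def is_expressed(count: int, min_reads: int = 5) -> bool:
    """The expression rule: ``count >= min_reads`` (default five reads)."""
    if count < 0:
        raise ValueError(f"negative read count {count}")
    return count >= min_reads


def exon_union_length(model: GeneModel) -> int:
    """Length of the union of all exons of all transcripts of a gene."""
    segments = sorted((e.start, e.end) for t in model.transcripts for e in t.exons)
    total = 0
    cur_start, cur_end = segments[0]
    for start, end in segments[1:]:
        if start <= cur_end:
            cur_end = max(cur_end, end)
        else:
            total += cur_end - cur_start
            cur_start, cur_end = start, end
    return total + (cur_end - cur_start)


def exon_length_table(annotation: AnnotationSet) -> dict[str, int]:
    return {m.id: exon_union_length(m) for m in annotation}


# ---------------------------------------------------------------------------
# FPKM and differential expression
# ---------------------------------------------------------------------------


def fpkm(counts: pd.DataFrame, exon_lengths: Mapping[str, int]) -> pd.DataFrame:
    """FPKM(g, s) = count(g, s) * 1e9 / (library_size(s) * exon_length(g)).

    ``counts`` is genes x samples; library size is the column sum.  A missing
    or non-positive exon length, or an empty library, is an error naming the
    offender.
    """
    lengths = []
    for gene in counts.index:
        length = exon_lengths.get(gene, 0)
        if length <= 0:
            raise ValueError(f"gene {gene}: non-positive exon length {length}")
        lengths.append(length)
    library = counts.sum(axis=0)
    empty = library[library <= 0]
    if len(empty):
        raise ValueError(f"empty library for sample(s): {', '.join(empty.index)}")
    scaled = counts.div(library, axis=1).div(pd.Series(lengths, index=counts.index), axis=0)
    return scaled * 1e9


def _condition_columns(
    counts: pd.DataFrame, conditions: Mapping[str, str], condition: str
) -> list[str]:
    columns = [s for s in counts.columns if conditions.get(s) == condition]
    if not columns:
        raise ValueError(f"no samples with condition {condition!r}")
    return columns


def differential_genes(
    counts: pd.DataFrame,
    conditions: Mapping[str, str],
    cond_a: str,
    cond_b: str,
    p_threshold: float = 0.01,
    min_log2fc: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene differential-expression calls between two conditions.

    Returns a frame indexed by gene with ``log2fc`` (condition B over A, on
    pseudocounted library-normalized means), ``p_value`` (two-sided Fisher
    exact on pooled counts, gene vs rest of library) and ``significant``
    (p < threshold AND |log2fc| strictly greater than ``min_log2fc``).
    """
    cols_a = _condition_columns(counts, conditions, cond_a)
    cols_b = _condition_columns(counts, conditions, cond_b)
    library = counts.sum(axis=0)

    # per-sample normalized abundance with pseudocount; exon length cancels
    # from the ratio of within-gene means, so FPKM fold change reduces to this
    norm = (counts + pseudocount).div(library + pseudocount, axis=1)
    mean_a = norm[cols_a].mean(axis=1)
    mean_b = norm[cols_b].mean(axis=1)
    log2fc = np.log2(mean_b / mean_a)

    pooled_a = counts[cols_a].sum(axis=1).astype(int)
    pooled_b = counts[cols_b].sum(axis=1).astype(int)
    total_a = int(pooled_a.sum())
    total_b = int(pooled_b.sum())
    p_values = []
    for gene in counts.index:
        ga, gb = int(pooled_a[gene]), int(pooled_b[gene])
        table = [[ga, total_a - ga], [gb, total_b - gb]]
        p_values.append(stats.fisher_exact(table, alternative="two-sided")[1])

    frame = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p_values,
        },
        index=counts.index,
    )
    frame["significant"] = (frame["p_value"] < p_threshold) & (
        frame["log2fc"].abs() > min_log2fc
    )
    return frame


# ---------------------------------------------------------------------------
# support-table I/O
# ---------------------------------------------------------------------------


def read_support_tsv(path: Union[str, Path, IO[str]]) -> dict[str, int]:
    frame = pd.read_csv(path, sep="\t", dtype={"model_id": str, "supporting_reads": int})
    return dict(zip(frame["model_id"], frame["supporting_reads"]))


def write_support_tsv(table: Mapping[str, int], path: Union[str, Path, IO[str]]) -> None:
    pd.DataFrame(
        sorted(table.items()), columns=["model_id", "supporting_reads"]
    ).to_csv(path, sep="\t", index=False)
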