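"""Reciprocal-best-hit orthology and protein-length arbitration.

Orthologs between two species are called as reciprocal best hits (RBH) over
pairwise protein similarity records at an e-value cutoff (default 0.001).
Real aligner output is ingested as a 6-column TSV (a declared subset of
BLAST outfmt-6 semantics); for synthetic data a shared-k-mer scorer produces
hits with a monotone pseudo e-value, so tests need no external aligner.

Length arbitration implements the rule used to vet updated gene models
against their predecessors: pairs whose signed protein-length difference
falls outside mean +/- 1 sample SD of the difference distribution are
outliers, and an outlier's updated model is replaced with the legacy model
only when both outgroup ortholog lengths are strictly closer to the legacy
protein length.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityHit",
    "OrthologTable",
    "LengthArbitration",
    "reciprocal_best_hits",
    "kmer_similarity",
    "length_difference_outliers",
    "arbitrate_length",
    "build_ortholog_table",
    "read_hits_tsv",
    "write_hits_tsv",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DECISIONS = ("keep_v2", "replace_with_v1", "no_orthologs")


@dataclass(frozen=True, order=True)
class SimilarityHit:
    """One best-HSP-collapsed pairwise protein similarity record."""

    query_id: str
    subject_id: str
    query_species: str
    subject_species: str
    score: float
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative e-value {self.e_value}")


@dataclass(frozen=True)
class LengthArbitration:
    """The decision record for one legacy/updated protein pair."""

    v1_id: str
    v2_id: str
    len_v1: int
    len_v2: int
    outlier: bool
    decision: str


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------


def _best_subjects(
    hits: Iterable[SimilarityHit],
    query_species: str,
    subject_species: str,
    max_e: float,
) -> dict[str, str]:
    """Best subject per query: highest score, ties to the smallest subject id."""
    best: dict[str, SimilarityHit] = {}
    for hit in hits:
        if hit.query_species != query_species or hit.subject_species != subject_species:
            continue
        if hit.e_value > max_e:
            continue
        current = best.get(hit.query_id)
        if (
            current is None
            or hit.score > current.score
            or (hit.score == current.score and hit.subject_id < current.subject_id)
        ):
            best[hit.query_id] = hit
    return {query: hit.subject_id for query, hit in best.items()}


def reciprocal_best_hits(
    hits: Sequence[SimilarityHit],
    species_a: str,
    species_b: str,
    max_e: float = 0.001,
) -> list[tuple[str, str]]:
    """Ortholog pairs (a, b): mutually best hits at e-value <= ``max_e``.

    Equivalent to the brute-force double argmax; ties are broken by higher
    score then lexicographically smallest subject id, and the output is
    sorted.  Swapping the species arguments mirrors every pair.
    """
    forward = _best_subjects(hits, species_a, species_b, max_e)
    backward = _best_subjects(hits, species_b, species_a, max_e)
    pairs = [
        (query, subject)
        for query, subject in forward.items()
        if backward.get(subject) == query
    ]
    return sorted(pairs)


# ---------------------------------------------------------------------------
# k-mer stand-in scorer
# ---------------------------------------------------------------------------


def kmer_similarity(seq_a: str, seq_b: str, k: int = 4) -> tuple[int, float]:
    """Shared-k-mer count and a pseudo e-value ``exp(-score)``.

    The score is the multiset intersection of the two sequences' k-mer
    spectra, so identical sequences of length ``n`` score ``n - k + 1`` and
    the pseudo e-value decreases monotonically with the score (score 0 gives
    e-value 1).  Sequences shorter than ``k`` are an error.
    """
    if len(seq_a) < k or len(seq_b) < k:
        raise ValueError(f"sequences must be at least k={k} residues long")
    kmers_a = Counter(seq_a[i : i + k] for i in range(len(seq_a) - k + 1))
    kmers_b = Counter(seq_b[i : i + k] for i in range(len(seq_b) - k + 1))
    score = sum((kmers_a & kmers_b).values())
    return score, math.exp(-score)


# ---------------------------------------------------------------------------
# protein-length outliers and arbitration
# ---------------------------------------------------------------------------


def length_difference_outliers(
    pairs: Sequence[tuple[str, str, int, int]],
    sd_multiplier: float = 1.0,
) -> set[tuple[str, str]]:
    """Pairs whose length difference lies outside mean +/- SD of all differences.

    ``pairs`` are (v1_id, v2_id, len_v1, len_v2) records; the difference is
    ``len_v2 - len_v1`` and the SD is the sample SD (n - 1).  "Outside" is
    strict, so a degenerate distribution (SD 0) flags nothing.  Fewer than
    two pairs cannot define a distribution and raise.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs to form a difference distribution")
    diffs = np.array([len_v2 - len_v1 for _, _, len_v1, len_v2 in pairs], dtype=float)
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    low, high = mean - sd_multiplier * sd, mean + sd_multiplier * sd
    return {
        (v1_id, v2_id)
        for (v1_id, v2_id, len_v1, len_v2), d in zip(pairs, diffs)
        if d < low or d > high
    }


def arbitrate_length(
    v1_len: int,
    v2_len: int,
    ortholog_lengths: Sequence[Optional[int]],
) -> str:
    """Decide an outlier pair's fate from two outgroup ortholog lengths.

    ``replace_with_v1`` requires both ortholog lengths present and both
    strictly closer to the legacy length; a missing ortholog yields
    ``no_orthologs``; anything else keeps the updated model (exact ties are
    resolved conservatively in favor of the new annotation).
    """
    if len(ortholog_lengths) != 2:
        raise ValueError("arbitration expects exactly two outgroup lengths")
    if any(length is None for length in ortholog_lengths):
        return "no_orthologs"
    if all(
        abs(length - v1_len) < abs(length - v2_len) for length in ortholog_lengths
    ):
        return "replace_with_v1"
    return "keep_v2"


# ---------------------------------------------------------------------------
# ortholog table
# ---------------------------------------------------------------------------


class OrthologTable:
    """Per-gene orthologs: gene -> species -> (ortholog id, protein length)."""

    def __init__(
        self,
        mapping: Mapping[str, Mapping[str, tuple[str, int]]],
        species: Sequence[str],
    ):
        self.species: tuple[str, ...] = tuple(species)
        self._table: dict[str, dict[str, tuple[str, int]]] = {
            gene: dict(per_species) for gene, per_species in mapping.items()
        }

    def has_ortholog(self, gene_id: str, species: str | None = None) -> bool:
        entry = self._table.get(gene_id, {})
        if species is None:
            return bool(entry)
        return species in entry

    def ortholog(self, gene_id: str, species: str) -> tuple[str, int] | None:
        return self._table.get(gene_id, {}).get(species)

    def ortholog_length(self, gene_id: str, species: str) -> int | None:
        entry = self.ortholog(gene_id, species)
        return None if entry is None else entry[1]

    def n_species_with_ortholog(self, gene_id: str) -> int:
        return len(self._table.get(gene_id, {}))

    def genes(self) -> list[str]:
        return sorted(self._table)

    def to_tsv(self, path: Union[str, Path, IO[str]]) -> None:
        rows = [
            {
                "gene_id": gene,
                "species": species,
                "ortholog_id": ortholog_id,
                "ortholog_protein_length": length,
            }
            for gene in sorted(self._table)
            for species, (ortholog_id, length) in sorted(self._table[gene].items())
        ]
        pd.DataFrame(
            rows,
            columns=["gene_id", "species", "ortholog_id", "ortholog_protein_length"],
        ).to_csv(path, sep="\t", index=False)


def build_ortholog_table(
    hits: Sequence[SimilarityHit],
    focal_species: str,
    species: Sequence[str],
    protein_lengths: Mapping[str, int],
    max_e: float = 0.001,
) -> OrthologTable:
    """RBH orthologs of every focal-species gene against each listed species.

    ``protein_lengths`` maps ortholog protein ids to amino-acid lengths;
    orthologs without a recorded length get length 0.
    """
    if not species:
        raise ValueError("empty species list")
    table: dict[str, dict[str, tuple[str, int]]] = {}
    for other in species:
        for gene, ortholog in reciprocal_best_hits(hits, focal_species, other, max_e):
            table.setdefault(gene, {})[other] = (
                ortholog,
                int(protein_lengths.get(ortholog, 0)),
            )
    return OrthologTable(table, species)


# ---------------------------------------------------------------------------
# hits TSV I/O
# ---------------------------------------------------------------------------

_HITS_COLUMNS = [
    "query_id",
    "subject_id",
    "query_species",
    "subject_species",
    "score",
    "e_value",
]


def read_hits_tsv(path: Union[str, Path, IO[str]]) -> list[SimilarityHit]:
    frame = pd.read_csv(path, sep="\t", dtype={c: str for c in _HITS_COLUMNS[:4]})
    missing = set(_HITS_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"hits table missing columns: {', '.join(sorted(missing))}")
    return [
        SimilarityHit(
            row.query_id,
            row.subject_id,
            row.query_species,
            row.subject_species,
            float(row.score),
            float(row.e_value),
        )
        for row in frame.itertuples(index=False)
    ]


def write_hits_tsv(
    hits: Sequence[SimilarityHit], path: Union[str, Path, IO[str]]
) -> None:
    pd.DataFrame(
        [
            (h.query_id, h.subject_id, h.query_species, h.subject_species, h.score, h.e_value)
            for h in hits
        ],
        columns=_HITS_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
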