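"""Alternative-splicing event enumeration and differential splicing calls.

Events are found by pairwise comparison of a gene's isoforms and classified
into the five canonical types:

SE
    exon skipping: an internal exon of one isoform is absent from the other
    while both flanking introns' outer splice sites are shared.
RI
    intron retention: an intron of one isoform lies strictly inside an exon
    of the other.
A5SS / A3SS
    alternative donor / acceptor: two introns share one boundary, differ at
    the other, and the exons at the differing boundary overlap; the name is
    assigned on the transcribed strand (donor = 5').
MXE
    mutually exclusive exons: two non-overlapping internal exons, each
    private to one isoform, sharing both outer flanking splice sites.

Differential splicing between two conditions uses pooled inclusion and
exclusion read counts per event: a two-sided Fisher exact test, Benjamini-
Hochberg FDR across tested events, and a minimum |delta PSI|.  Events on
genes whose expression differs 10,000-fold or more between the conditions
are excluded before testing, mirroring the false-positive control used with
junction-count methods.  This caller is a stand-in for likelihood-based
models; it makes no attempt to model replicate dispersion (replicates are
pooled within condition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation_io import GeneModel, Transcript

__all__ = [
    "EVENT_TYPES",
    "SpliceEvent",
    "EventCounts",
    "enumerate_events",
    "psi",
    "differential_splicing",
    "events_to_tsv",
]

logger = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "RI", "A5SS", "A3SS", "MXE")

Coords = tuple[tuple[int, int], ...]


@dataclass(frozen=True, order=True)
class SpliceEvent:
    """A classified event: inclusion/exclusion interval forms plus anchors."""

    gene_id: str
    event_type: str
    inclusion: Coords
    exclusion: Coords
    anchors: tuple[int, ...]

    @property
    def event_id(self) -> str:
        def fmt(coords: Coords) -> str:
            return ",".join(f"{s}-{e}" for s, e in coords)

        return f"{self.gene_id}:{self.event_type}:{fmt(self.inclusion)}^{fmt(self.exclusion)}"


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def _exons(t: Transcript) -> list[tuple[int, int]]:
    return [(e.start, e.end) for e in t.exons]


def _introns(t: Transcript) -> list[tuple[int, int]]:
    return [(i.start, i.end) for i in t.introns]


def _pair_events(gene_id: str, strand: str, ta: Transcript, tb: Transcript) -> set[SpliceEvent]:
    events: set[SpliceEvent] = set()
    minus = strand == "-"

    for t1, t2 in ((ta, tb), (tb, ta)):
        ex1, ex2 = _exons(t1), _exons(t2)
        in2 = set(_introns(t2))
        ex2_set = set(ex2)

        # SE: internal exon of t1, flanking outer splice sites joined in t2
        for i in range(1, len(ex1) - 1):
            donor = ex1[i - 1][1]
            acceptor = ex1[i + 1][0]
            exon = ex1[i]
            if (donor, acceptor) in in2 and exon not in ex2_set:
                events.add(
                    SpliceEvent(gene_id, "SE", (exon,), ((donor, acceptor),), (donor, acceptor))
                )

        # RI: intron of t1 strictly interior to an exon of t2
        for intron in _introns(t1):
            for exon in ex2:
                if exon[0] < intron[0] and intron[1] < exon[1]:
                    events.add(
                        SpliceEvent(gene_id, "RI", (exon,), (intron,), intron)
                    )

    # A5SS / A3SS: intron pairs sharing exactly one boundary, with the exons
    # at the differing boundary overlapping
    exon_starting_a = {e[0]: e for e in _exons(ta)}
    exon_starting_b = {e[0]: e for e in _exons(tb)}
    exon_ending_a = {e[1]: e for e in _exons(ta)}
    exon_ending_b = {e[1]: e for e in _exons(tb)}

    def overlaps(x: tuple[int, int], y: tuple[int, int]) -> bool:
        return max(x[0], y[0]) < min(x[1], y[1])

    for ia in _introns(ta):
        for ib in _introns(tb):
            if ia == ib:
                continue
            if ia[0] == ib[0] and ia[1] != ib[1]:
                # shared left boundary; right boundary is the acceptor on '+'
                xa, xb = exon_starting_a.get(ia[1]), exon_starting_b.get(ib[1])
                if xa and xb and overlaps(xa, xb):
                    short, long = sorted((ia, ib), key=lambda iv: iv[1] - iv[0])
                    kind = "A5SS" if minus else "A3SS"
                    events.add(SpliceEvent(gene_id, kind, (short,), (long,), (ia[0],)))
            elif ia[1] == ib[1] and ia[0] != ib[0]:
                xa, xb = exon_ending_a.get(ia[0]), exon_ending_b.get(ib[0])
                if xa and xb and overlaps(xa, xb):
                    short, long = sorted((ia, ib), key=lambda iv: iv[1] - iv[0])
                    kind = "A3SS" if minus else "A5SS"
                    events.add(SpliceEvent(gene_id, kind, (short,), (long,), (ia[1],)))

    # MXE: private, non-overlapping internal exons sharing both outer flanks
    exa, exb = _exons(ta), _exons(tb)
    set_a, set_b = set(exa), set(exb)
    for i in range(1, len(exa) - 1):
        e1 = exa[i]
        d1, a1 = exa[i - 1][1], exa[i + 1][0]
        for j in range(1, len(exb) - 1):
            e2 = exb[j]
            d2, a2 = exb[j - 1][1], exb[j + 1][0]
            if d1 != d2 or a1 != a2:
                continue
            if e1 in set_b or e2 in set_a:
                continue
            if max(e1[0], e2[0]) < min(e1[1], e2[1]):  # overlapping: not MXE
                continue
            first, second = sorted((e1, e2))
            events.add(SpliceEvent(gene_id, "MXE", (first,), (second,), (d1, a1)))
    return events


def enumerate_events(gene: GeneModel) -> list[SpliceEvent]:
    """All splicing events between any two isoforms, deduplicated and sorted.

    Single-isoform genes yield an empty list.
    """
    transcripts = gene.transcripts
    if len(transcripts) < 2:
        return []
    events: set[SpliceEvent] = set()
    for i in range(len(transcripts)):
        for j in range(i + 1, len(transcripts)):
            events |= _pair_events(gene.id, gene.strand, transcripts[i], transcripts[j])
    return sorted(events)


# ---------------------------------------------------------------------------
# inclusion levels
# ---------------------------------------------------------------------------


def psi(
    inclusion_reads: float,
    exclusion_reads: float,
    inclusion_norm: float = 1.0,
    exclusion_norm: float = 1.0,
) -> float:
    """Inclusion level: normalized inclusion over normalized total, in [0, 1]."""
    if inclusion_reads < 0 or exclusion_reads < 0:
        raise ValueError("negative read counts")
    if inclusion_reads + exclusion_reads == 0:
        raise ValueError("PSI undefined for zero inclusion and exclusion reads")
    inc = inclusion_reads / inclusion_norm
    exc = exclusion_reads / exclusion_norm
    return inc / (inc + exc)


@dataclass
class EventCounts:
    """Per-event, per-sample inclusion/exclusion read counts with conditions."""

    inclusion: pd.DataFrame  # events x samples
    exclusion: pd.DataFrame  # events x samples
    conditions: Mapping[str, str]  # sample -> condition

    def __post_init__(self) -> None:
        if not self.inclusion.index.equals(self.exclusion.index) or not (
            self.inclusion.columns.equals(self.exclusion.columns)
        ):
            raise ValueError("inclusion/exclusion tables must share index and columns")
        if (self.inclusion.values < 0).any() or (self.exclusion.values < 0).any():
            raise ValueError("negative event counts")
        missing = [s for s in self.inclusion.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without condition label: {', '.join(missing)}")

    def samples_for(self, condition: str) -> list[str]:
        columns = [s for s in self.inclusion.columns if self.conditions[s] == condition]
        if not columns:
            raise ValueError(f"no samples with condition {condition!r}")
        return columns

    def pooled(self, condition: str) -> tuple[pd.Series, pd.Series]:
        """Replicate-pooled (inclusion, exclusion) counts for one condition."""
        columns = self.samples_for(condition)
        return (
            self.inclusion[columns].sum(axis=1),
            self.exclusion[columns].sum(axis=1),
        )

    def event_ids(self) -> list[str]:
        return list(self.inclusion.index)


# ---------------------------------------------------------------------------
# differential splicing
# ---------------------------------------------------------------------------


def differential_splicing(
    counts: EventCounts,
    cond_a: str,
    cond_b: str,
    gene_fpkm: Mapping[str, Mapping[str, float]] | None = None,
    gene_of_event: Mapping[str, str] | None = None,
    p_threshold: float = 0.01,
    fdr_threshold: float = 0.01,
    min_delta_psi: float = 0.0001,
    max_fold_change: float = 1e4,
    fpkm_pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential-splicing calls between two conditions.

    Per event the pooled 2x2 table (inclusion/exclusion x condition) is
    tested with a two-sided Fisher exact test; FDR is Benjamini-Hochberg
    across tested events.  ``significant`` requires p < ``p_threshold``,
    FDR < ``fdr_threshold`` and |delta PSI| strictly above ``min_delta_psi``.
    When ``gene_fpkm`` is supplied, events on genes with a pseudocounted
    expression ratio of ``max_fold_change`` or more are excluded before
    testing; events with no reads at all in a condition are skipped with a
    log entry.
    """
    inc_a, exc_a = counts.pooled(cond_a)
    inc_b, exc_b = counts.pooled(cond_b)

    if gene_of_event is None:
        gene_of_event = {
            event_id: event_id.split(":", 1)[0] for event_id in counts.event_ids()
        }

    rows = []
    for event_id in counts.event_ids():
        gene = gene_of_event.get(event_id)
        if gene_fpkm is not None and gene in gene_fpkm:
            fa = gene_fpkm[gene].get(cond_a, 0.0) + fpkm_pseudocount
            fb = gene_fpkm[gene].get(cond_b, 0.0) + fpkm_pseudocount
            if max(fa / fb, fb / fa) >= max_fold_change:
                logger.info(
                    "event %s excluded: %.0f-fold gene expression difference",
                    event_id,
                    max(fa / fb, fb / fa),
                )
                continue
        ia, ea = int(inc_a[event_id]), int(exc_a[event_id])
        ib, eb = int(inc_b[event_id]), int(exc_b[event_id])
        if ia + ea == 0 or ib + eb == 0:
            logger.info("event %s skipped: no reads in one condition", event_id)
            continue
        psi_a = psi(ia, ea)
        psi_b = psi(ib, eb)
        p_value = stats.fisher_exact([[ia, ea], [ib, eb]], alternative="two-sided")[1]
        rows.append(
            {
                "event_id": event_id,
                "gene_id": gene,
                "psi_a": psi_a,
                "psi_b": psi_b,
                "delta_psi": psi_b - psi_a,
                "p_value": p_value,
            }
        )

    frame = pd.DataFrame(
        rows,
        columns=["event_id", "gene_id", "psi_a", "psi_b", "delta_psi", "p_value"],
    ).set_index("event_id")
    if len(frame):
        frame["fdr"] = multipletests(frame["p_value"].values, method="fdr_bh")[1]
    else:
        frame["fdr"] = pd.Series(dtype=float)
    frame["significant"] = (
        (frame["p_value"] < p_threshold)
        & (frame["fdr"] < fdr_threshold)
        & (frame["delta_psi"].abs() > min_delta_psi)
    )
    return frame.sort_index()


def events_to_tsv(events: Sequence[SpliceEvent], path) -> None:
    def fmt(coords: Coords) -> str:
        return ",".join(f"{s}-{e}" for s, e in coords)

    pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "event_type": e.event_type,
                "inclusion": fmt(e.inclusion),
                "exclusion": fmt(e.exclusion),
                "anchors": ",".join(map(str, e.anchors)),
            }
            for e in events
        ],
        columns=["gene_id", "event_type", "inclusion", "exclusion", "anchors"],
    ).to_csv(path, sep="\t", index=False)
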