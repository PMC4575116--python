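"""Seeded synthetic scenarios with a machine-readable truth ledger.

A scenario emulates everything the annotation-update pipeline consumes:

* a *truth* annotation: a toy multi-scaffold genome of well-separated gene
  models with UTRs, CDS chains and (for a fraction of multi-exon genes) a
  second isoform that skips an exon or retains an intron;
* a perturbed *legacy* annotation: per gene the generator may fuse it with
  its neighbour (one legacy model that the update must split), cut it at an
  intron (two legacy models that the update must merge), keep it intact
  while its candidate copy is CDS-truncated (a protein-length outlier whose
  outgroup orthologs retain the true length), drop it (the update re-adds
  it from evidence), keep it only in the legacy set (rescued via orthology),
  or strip its UTRs; short unexpressed spurious models are added on both
  sides;
* Poisson read evidence over six samples (WT/HS/REC in duplicate), with a
  fraction of heat-responsive genes;
* toy protein sequences and reciprocal similarity hits for up to five
  relative species, with ortholog protein lengths jittered around truth;
* TE intervals (complete TEs planted in the CDS of designated TE genes or
  spanning them, plus incomplete decoys) and TE-gene similarity hits;
* binomial inclusion/exclusion read counts for every planted splice event,
  with condition-dependent PSI for a fraction of events.

Each sub-stage draws from its own seed-derived stream, so adding a stage
never reshuffles earlier draws, and a fixed seed reproduces the scenario
byte for byte.  The truth ledger records what was planted so every pipeline
stage can be scored exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import AnnotationSet, GeneModel, GenomicInterval, Transcript
from .evidence import ReadAlignment, ReadAlignmentSet
from .homology import SimilarityHit, kmer_similarity, AMINO_ACIDS
from .reconcile import ReconciliationReport, REINTRODUCED_SUFFIX
from .splicing import EventCounts, SpliceEvent
from .te_classify import TEInterval

__all__ = [
    "SPECIES_POOL",
    "SAMPLES",
    "ScenarioConfig",
    "GeneFate",
    "PlantedEvent",
    "TruthLedger",
    "Scenario",
    "Score",
    "generate_scenario",
    "ledger_score",
    "simulate_null_splicing",
]

SPECIES_POOL = ("Athaliana", "Crubella", "Brapa", "Sparvula", "Aalpina")

#: (sample_id, condition, replicate) for the six-sample design
SAMPLES = (
    ("WT_1", "WT", 1),
    ("WT_2", "WT", 2),
    ("HS_1", "HS", 1),
    ("HS_2", "HS", 2),
    ("REC_1", "REC", 1),
    ("REC_2", "REC", 2),
)

TE_FAMILIES = ("Copia", "Gypsy", "LINE", "Helitron")

_READ_LENGTH = 96

# stage keys for seed-derived substreams (order is part of the contract)
_STAGES = {
    "layout": 0,
    "isoforms": 1,
    "te": 2,
    "fates": 3,
    "expression": 4,
    "legacy": 5,
    "spurious": 6,
    "reads": 7,
    "orthology": 8,
    "splicing": 9,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the generator; defaults are the standard study conditions."""

    seed: int
    n_scaffolds: int = 2
    genes_per_scaffold: int = 100
    exons_per_gene: tuple[int, int] = (1, 6)
    split_rate: float = 0.10  # neighbour pairs fused in the legacy set
    merge_rate: float = 0.10  # genes cut in two in the legacy set
    truncate_rate: float = 0.10  # candidate CDS truncated, legacy intact
    drop_rate: float = 0.05  # gene absent from the legacy set
    orphan_rate: float = 0.05  # gene absent from candidates; rescued via orthology
    spurious_rate: float = 0.10  # short unexpressed extras per side
    utr_loss_rate: float = 0.30  # intact legacy copies stripped of UTRs
    te_gene_fraction: float = 0.05
    mean_reads: float = 60.0  # Poisson mean supporting reads per expressed gene
    fraction_unexpressed: float = 0.10
    heat_response_fraction: float = 0.10
    heat_response_fold: float = 8.0
    alt_isoform_fraction: float = 0.30
    differential_splicing_fraction: float = 0.30
    reads_per_event: int = 500
    ortholog_presence: float = 0.80
    ortholog_length_sd: float = 3.0
    n_species: int = 5

    def __post_init__(self) -> None:
        rates = {
            "split_rate": self.split_rate,
            "merge_rate": self.merge_rate,
            "truncate_rate": self.truncate_rate,
            "drop_rate": self.drop_rate,
            "orphan_rate": self.orphan_rate,
            "spurious_rate": self.spurious_rate,
            "utr_loss_rate": self.utr_loss_rate,
            "te_gene_fraction": self.te_gene_fraction,
            "fraction_unexpressed": self.fraction_unexpressed,
            "heat_response_fraction": self.heat_response_fraction,
            "alt_isoform_fraction": self.alt_isoform_fraction,
            "differential_splicing_fraction": self.differential_splicing_fraction,
            "ortholog_presence": self.ortholog_presence,
        }
        for name, value in rates.items():
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        fate_total = (
            self.split_rate
            + self.merge_rate
            + self.truncate_rate
            + self.drop_rate
            + self.orphan_rate
        )
        if fate_total > 1:
            raise ValueError(
                f"perturbation rates sum to {fate_total:.2f} > 1 per gene"
            )
        lo, hi = self.exons_per_gene
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid exons_per_gene range {self.exons_per_gene}")
        if not 1 <= self.n_species <= len(SPECIES_POOL):
            raise ValueError(f"n_species must be in [1, {len(SPECIES_POOL)}]")
        if self.n_scaffolds < 1 or self.genes_per_scaffold < 1:
            raise ValueError("need at least one scaffold and one gene")

    @property
    def species(self) -> tuple[str, ...]:
        return SPECIES_POOL[: self.n_species]


@dataclass
class GeneFate:
    """What happened to one truth gene on the way into the legacy annotation."""

    gene_id: str
    fate: str  # intact | fused | cut | truncated | dropped | orphan
    legacy_ids: tuple[str, ...]
    is_te: bool
    expressed: bool
    true_protein_length: int
    ortholog_lengths: dict[str, int] = field(default_factory=dict)


@dataclass
class PlantedEvent:
    event_id: str
    gene_id: str
    event_type: str
    psi: dict[str, float]  # condition -> true inclusion level
    differential: bool


@dataclass
class TruthLedger:
    """Everything the generator planted, keyed for exact scoring."""

    genes: dict[str, GeneFate]
    fused: dict[str, tuple[str, str]]  # legacy id -> fused truth gene pair
    cut: dict[str, tuple[str, str]]  # truth id -> its two legacy halves
    dropped: tuple[str, ...]
    orphans: tuple[str, ...]
    spurious_v1: tuple[str, ...]
    spurious_candidates: tuple[str, ...]
    te_genes: frozenset[str]
    events: tuple[PlantedEvent, ...]

    def legacy_ids(self) -> set[str]:
        ids = set(self.spurious_v1)
        for fate in self.genes.values():
            ids.update(fate.legacy_ids)
        return ids

    def to_json(self, path) -> None:
        payload = {
            "genes": {gid: asdict(fate) for gid, fate in sorted(self.genes.items())},
            "fused": {k: list(v) for k, v in sorted(self.fused.items())},
            "cut": {k: list(v) for k, v in sorted(self.cut.items())},
            "dropped": list(self.dropped),
            "orphans": list(self.orphans),
            "spurious_v1": list(self.spurious_v1),
            "spurious_candidates": list(self.spurious_candidates),
            "te_genes": sorted(self.te_genes),
            "events": [asdict(e) for e in self.events],
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)


@dataclass
class Scenario:
    """A complete synthetic input bundle plus its truth ledger."""

    config: ScenarioConfig
    truth: AnnotationSet
    v1: AnnotationSet
    candidates: AnnotationSet
    reads: ReadAlignmentSet
    hits: tuple[SimilarityHit, ...]
    protein_lengths: dict[str, int]
    proteins: dict[str, str]
    te_intervals: tuple[TEInterval, ...]
    te_hits: tuple[SimilarityHit, ...]
    event_counts: EventCounts | None
    planted_events: tuple[SpliceEvent, ...]
    ledger: TruthLedger
    samples: tuple[tuple[str, str, int], ...] = SAMPLES

    @property
    def sample_conditions(self) -> dict[str, str]:
        return {sid: cond for sid, cond, _ in self.samples}


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _rng(cfg_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, _STAGES[stage]])


def _clip_chain(
    chain: Sequence[GenomicInterval], exons: Sequence[GenomicInterval]
) -> tuple[GenomicInterval, ...]:
    """Intersect a CDS chain with an exon chain."""
    out = []
    for seg in chain:
        for exon in exons:
            start = max(seg.start, exon.start)
            end = min(seg.end, exon.end)
            if start < end:
                out.append(
                    GenomicInterval(seg.scaffold, start, end, seg.strand)
                )
    return tuple(out)


def _single_transcript_model(
    gene_id: str,
    exons: Sequence[GenomicInterval],
    cds: Sequence[GenomicInterval],
    source: str,
) -> GeneModel:
    transcript = Transcript(f"{gene_id}.1", gene_id, tuple(exons), tuple(cds))
    return GeneModel(gene_id, (transcript,), source=source)


def _copy_as(model: GeneModel, new_id: str, source: str, primary_only: bool = True) -> GeneModel:
    transcripts = model.transcripts[:1] if primary_only else model.transcripts
    renamed = tuple(
        Transcript(f"{new_id}.{k}", new_id, t.exons, t.cds)
        for k, t in enumerate(transcripts, start=1)
    )
    return GeneModel(new_id, renamed, source=source)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    letters = rng.integers(0, len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[i] for i in letters)


def _mutate_protein(
    rng: np.random.Generator, seq: str, target_length: int, rate: float = 0.05
) -> str:
    out = list(seq)
    n_mut = rng.binomial(len(out), rate)
    positions = rng.choice(len(out), size=min(n_mut, len(out)), replace=False)
    for pos in positions:
        out[pos] = AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
    if target_length < len(out):
        out = out[:target_length]
    elif target_length > len(out):
        out.extend(
            AMINO_ACIDS[rng.integers(0, len(AMINO_ACIDS))]
            for _ in range(target_length - len(out))
        )
    return "".join(out)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Build a complete scenario; deterministic for a fixed seed."""
    # ---- stage: layout -- truth gene bodies ------------------------------
    rng = _rng(cfg.seed, "layout")
    truth = AnnotationSet()
    gene_order: dict[str, list[str]] = {}  # scaffold -> gene ids in position order
    strands: dict[str, str] = {}
    last_end: dict[str, int] = {}
    for s in range(cfg.n_scaffolds):
        scaffold = str(s + 1)
        gene_order[scaffold] = []
        cursor = 1000
        for i in range(cfg.genes_per_scaffold):
            gid = f"G{scaffold}_{i:04d}"
            lo, hi = cfg.exons_per_gene
            n_exons = int(rng.integers(lo, hi + 1))
            exon_lens = rng.integers(150, 400, size=n_exons)
            intron_lens = rng.integers(60, 250, size=max(0, n_exons - 1))
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = cursor
            for k in range(n_exons):
                exons.append(
                    GenomicInterval(scaffold, pos, pos + int(exon_lens[k]), strand)
                )
                pos = exons[-1].end + (int(intron_lens[k]) if k < n_exons - 1 else 0)
            utr5 = int(rng.integers(10, 60))
            utr3 = int(rng.integers(10, 60))
            if n_exons == 1:
                max_utr = (exons[0].length - 90) // 2
                utr5, utr3 = min(utr5, max_utr), min(utr3, max_utr)
            else:
                utr5 = min(utr5, exons[0].length - 30)
                utr3 = min(utr3, exons[-1].length - 30)
            cds_lo = exons[0].start + utr5
            cds_hi = exons[-1].end - utr3
            cds = _clip_chain(
                [GenomicInterval(scaffold, cds_lo, cds_hi, strand)], exons
            )
            truth.add(_single_transcript_model(gid, exons, cds, "truth"))
            gene_order[scaffold].append(gid)
            strands[gid] = strand
            cursor = exons[-1].end + int(rng.integers(300, 900))
            last_end[scaffold] = exons[-1].end

    # ---- stage: isoforms -- planted splice events ------------------------
    rng = _rng(cfg.seed, "isoforms")
    planted_events: list[SpliceEvent] = []
    event_gene: dict[str, str] = {}
    for scaffold in sorted(gene_order):
        for gid in gene_order[scaffold]:
            model = truth.get(gid)
            primary = model.transcripts[0]
            n_exons = len(primary.exons)
            if n_exons < 2 or rng.random() >= cfg.alt_isoform_fraction:
                continue
            exons = list(primary.exons)
            if n_exons >= 3 and rng.random() < 0.5:
                # exon skipping: second isoform lacks an internal exon
                k = int(rng.integers(1, n_exons - 1))
                skipped = exons[k]
                alt_exons = exons[:k] + exons[k + 1 :]
                donor, acceptor = exons[k - 1].end, exons[k + 1].start
                event = SpliceEvent(
                    gid,
                    "SE",
                    ((skipped.start, skipped.end),),
                    ((donor, acceptor),),
                    (donor, acceptor),
                )
            else:
                # intron retention: second isoform keeps an intron as exon
                j = int(rng.integers(0, n_exons - 1))
                retained = GenomicInterval(
                    scaffold, exons[j].start, exons[j + 1].end, primary.strand
                )
                alt_exons = exons[:j] + [retained] + exons[j + 2 :]
                intron = (exons[j].end, exons[j + 1].start)
                event = SpliceEvent(
                    gid,
                    "RI",
                    ((retained.start, retained.end),),
                    (intron,),
                    intron,
                )
            alt_cds = _clip_chain(primary.cds, alt_exons)
            alt = Transcript(f"{gid}.2", gid, tuple(alt_exons), alt_cds)
            truth.remove(gid)
            truth.add(GeneModel(gid, (primary, alt), source="truth"))
            planted_events.append(event)
            event_gene[event.event_id] = gid

    # ---- stage: te -- TE genes and intervals -----------------------------
    rng = _rng(cfg.seed, "te")
    all_gene_ids = sorted(truth.ids())
    n_te = int(round(cfg.te_gene_fraction * len(all_gene_ids)))
    te_genes = frozenset(
        rng.choice(all_gene_ids, size=n_te, replace=False).tolist()
    ) if n_te else frozenset()
    te_intervals: list[TEInterval] = []
    te_hits: list[SimilarityHit] = []
    for n, gid in enumerate(sorted(te_genes)):
        model = truth.get(gid)
        family = TE_FAMILIES[int(rng.integers(0, len(TE_FAMILIES)))]
        primary = model.transcripts[0]
        cds_lo, cds_hi = primary.cds[0].start, primary.cds[-1].end
        if rng.random() < 0.5 and cds_hi - cds_lo >= 100:
            start = cds_lo + 5
            end = min(cds_hi - 5, start + max(80, (cds_hi - cds_lo) // 2))
            te_intervals.append(
                TEInterval(model.scaffold, start, end, model.strand, family, True)
            )
        else:
            span = model.span
            te_intervals.append(
                TEInterval(
                    model.scaffold,
                    max(0, span.start - 50),
                    span.end + 50,
                    model.strand,
                    family,
                    True,
                )
            )
        if rng.random() < 0.5:
            te_hits.append(
                SimilarityHit(gid, f"AtTE_{n:03d}", "Alyrata", "Athaliana_TE", 200.0, 1e-8)
            )
    # incomplete decoy TEs inside gene bodies: trigger no rule
    for scaffold in sorted(gene_order):
        for _ in range(cfg.genes_per_scaffold // 5):
            gid = gene_order[scaffold][int(rng.integers(0, len(gene_order[scaffold])))]
            span = truth.get(gid).span
            length = int(rng.integers(100, 300))
            start = span.start + 5
            end = min(span.end - 5, start + length)
            if end > start:
                family = TE_FAMILIES[int(rng.integers(0, len(TE_FAMILIES)))]
                te_intervals.append(
                    TEInterval(scaffold, start, end, ".", family, False)
                )

    # ---- stage: fates ----------------------------------------------------
    rng = _rng(cfg.seed, "fates")
    fates: dict[str, str] = {}
    fused_pairs: list[tuple[str, str]] = []
    thresholds = np.cumsum(
        [cfg.split_rate, cfg.merge_rate, cfg.truncate_rate, cfg.drop_rate, cfg.orphan_rate]
    )
    for scaffold in sorted(gene_order):
        order = gene_order[scaffold]
        i = 0
        while i < len(order):
            gid = order[i]
            if gid in te_genes:
                fates[gid] = "intact"
                i += 1
                continue
            u = rng.random()
            if u < thresholds[0]:
                nxt = order[i + 1] if i + 1 < len(order) else None
                if (
                    nxt is not None
                    and nxt not in te_genes
                    and strands[nxt] == strands[gid]
                ):
                    fates[gid] = "fused"
                    fates[nxt] = "fused_tail"
                    fused_pairs.append((gid, nxt))
                    i += 2
                    continue
                fates[gid] = "intact"
            elif u < thresholds[1]:
                if len(truth.get(gid).transcripts[0].exons) >= 2:
                    fates[gid] = "cut"
                else:
                    fates[gid] = "intact"
            elif u < thresholds[2]:
                fates[gid] = "truncated"
            elif u < thresholds[3]:
                fates[gid] = "dropped"
            elif u < thresholds[4]:
                fates[gid] = "orphan"
            else:
                fates[gid] = "intact"
            i += 1

    # ---- stage: expression ----------------------------------------------
    rng = _rng(cfg.seed, "expression")
    expressed: dict[str, bool] = {}
    for gid in all_gene_ids:
        expressed[gid] = bool(rng.random() < 1 - cfg.fraction_unexpressed)
        if fates[gid] == "dropped":
            expressed[gid] = True  # an added gene must be discoverable
        elif fates[gid] == "orphan":
            expressed[gid] = False  # rescue must go through orthology

    # ---- stage: legacy -- build the v1 annotation -----------------------
    rng = _rng(cfg.seed, "legacy")
    v1 = AnnotationSet()
    ledger_genes: dict[str, GeneFate] = {}
    fused: dict[str, tuple[str, str]] = {}
    cut: dict[str, tuple[str, str]] = {}
    legacy_of: dict[str, tuple[str, ...]] = {}
    counters: dict[str, int] = {}

    def next_legacy_id(scaffold: str) -> str:
        counters[scaffold] = counters.get(scaffold, 0) + 1
        return f"L{scaffold}_{counters[scaffold]:04d}"

    for scaffold in sorted(gene_order):
        for gid in gene_order[scaffold]:
            fate = fates[gid]
            model = truth.get(gid)
            primary = model.transcripts[0]
            if fate == "fused":
                partner = dict(fused_pairs)[gid]
                partner_primary = truth.get(partner).transcripts[0]
                lid = next_legacy_id(scaffold)
                exons = primary.exons + partner_primary.exons
                cds = primary.cds + partner_primary.cds
                v1.add(_single_transcript_model(lid, exons, cds, "version1"))
                fused[lid] = (gid, partner)
                legacy_of[gid] = (lid,)
                legacy_of[partner] = (lid,)
            elif fate == "fused_tail":
                continue
            elif fate == "cut":
                k = int(rng.integers(0, len(primary.exons) - 1))
                lid_a, lid_b = next_legacy_id(scaffold), next_legacy_id(scaffold)
                left, right = primary.exons[: k + 1], primary.exons[k + 1 :]
                v1.add(
                    _single_transcript_model(
                        lid_a, left, _clip_chain(primary.cds, left), "version1"
                    )
                )
                v1.add(
                    _single_transcript_model(
                        lid_b, right, _clip_chain(primary.cds, right), "version1"
                    )
                )
                cut[gid] = (lid_a, lid_b)
                legacy_of[gid] = (lid_a, lid_b)
            elif fate == "dropped":
                legacy_of[gid] = ()
            else:  # intact, truncated, orphan
                lid = next_legacy_id(scaffold)
                copy = _copy_as(model, lid, "version1")
                if fate == "intact" and rng.random() < cfg.utr_loss_rate:
                    t = copy.transcripts[0]
                    if t.cds:
                        lo, hi = t.cds[0].start, t.cds[-1].end
                        stripped = _clip_chain(
                            t.exons, [GenomicInterval(scaffold, lo, hi, t.strand)]
                        )
                        copy = _single_transcript_model(lid, stripped, t.cds, "version1")
                v1.add(copy)
                legacy_of[gid] = (lid,)
            ledger_genes[gid] = GeneFate(
                gene_id=gid,
                fate={"fused_tail": "fused"}.get(fate, fate),
                legacy_ids=legacy_of.get(gid, ()),
                is_te=gid in te_genes,
                expressed=expressed[gid],
                true_protein_length=primary.protein_length,
            )
    # fused tails share their lead's legacy id; record them now
    for lead, tail in fused_pairs:
        ledger_genes[tail] = GeneFate(
            gene_id=tail,
            fate="fused",
            legacy_ids=legacy_of[tail],
            is_te=tail in te_genes,
            expressed=expressed[tail],
            true_protein_length=truth.get(tail).transcripts[0].protein_length,
        )

    # ---- candidates (truth-derived; no randomness) -----------------------
    candidates = AnnotationSet()
    for gid in all_gene_ids:
        fate = fates[gid]
        if fate == "orphan":
            continue  # only the legacy set knows this gene
        model = truth.get(gid)
        if fate == "truncated":
            primary = model.transcripts[0]
            total = sum(c.length for c in primary.cds)
            keep = max(30, int(0.3 * total))
            kept, acc = [], 0
            for seg in primary.cds:
                if acc >= keep:
                    break
                take = min(seg.length, keep - acc)
                kept.append(
                    GenomicInterval(seg.scaffold, seg.start, seg.start + take, seg.strand)
                )
                acc += take
            candidates.add(
                _single_transcript_model(gid, primary.exons, kept, "augustus")
            )
        else:
            candidates.add(_copy_as(model, gid, "augustus", primary_only=False))

    # ---- stage: spurious -------------------------------------------------
    rng = _rng(cfg.seed, "spurious")
    spurious_v1: list[str] = []
    spurious_candidates: list[str] = []
    n_spur = int(round(cfg.spurious_rate * cfg.genes_per_scaffold))
    for scaffold in sorted(gene_order):
        tail = last_end[scaffold] + 1000
        for j in range(n_spur):
            length = int(rng.integers(150, 450))
            exon = GenomicInterval(scaffold, tail, tail + length, "+")
            sid = f"LS{scaffold}_{j:03d}"
            v1.add(_single_transcript_model(sid, [exon], [exon], "version1"))
            spurious_v1.append(sid)
            tail += length + 600
            length = int(rng.integers(150, 450))
            exon = GenomicInterval(scaffold, tail, tail + length, "+")
            cid = f"CS{scaffold}_{j:03d}"
            candidates.add(_single_transcript_model(cid, [exon], [exon], "augustus"))
            spurious_candidates.append(cid)
            tail += length + 600

    # ---- stage: reads ----------------------------------------------------
    rng = _rng(cfg.seed, "reads")
    records: list[ReadAlignment] = []
    sample_ids = [sid for sid, _, _ in SAMPLES]
    for gid in all_gene_ids:
        if not expressed[gid]:
            continue
        responsive = bool(rng.random() < cfg.heat_response_fraction)
        model = truth.get(gid)
        exons = model.transcripts[0].exons
        weights = np.array([e.length for e in exons], dtype=float)
        weights /= weights.sum()
        per_sample = []
        for sid, cond, _ in SAMPLES:
            lam = cfg.mean_reads / len(SAMPLES)
            if responsive and cond == "HS":
                lam *= cfg.heat_response_fold
            per_sample.append(int(rng.poisson(lam)))
        if sum(per_sample) < 5:  # expressed genes always clear the 5-read rule
            per_sample[0] += 5 - sum(per_sample)
        for sid, n_reads in zip(sample_ids, per_sample):
            for _ in range(n_reads):
                exon = exons[int(rng.choice(len(exons), p=weights))]
                if exon.length <= _READ_LENGTH:
                    start, end = exon.start, exon.end
                else:
                    start = int(rng.integers(exon.start, exon.end - _READ_LENGTH + 1))
                    end = start + _READ_LENGTH
                records.append(ReadAlignment(model.scaffold, start, end, sid))
    reads = ReadAlignmentSet(records, samples=sample_ids)

    # ---- stage: orthology ------------------------------------------------
    rng = _rng(cfg.seed, "orthology")
    hits: list[SimilarityHit] = []
    protein_lengths: dict[str, int] = {}
    proteins: dict[str, str] = {}
    previous_ortholog: dict[str, str] = {}  # species -> last ortholog id
    species = cfg.species
    for gid in all_gene_ids:
        fate = fates[gid]
        if fate not in ("intact", "truncated", "orphan") or gid in te_genes:
            continue
        (lid,) = legacy_of[gid]
        plen = ledger_genes[gid].true_protein_length
        seq = _random_protein(rng, plen)
        proteins[lid] = seq
        protein_lengths[lid] = plen
        present = [bool(rng.random() < cfg.ortholog_presence) for _ in species]
        if fate == "orphan" and not any(present):
            present[0] = True
        for sp, here in zip(species, present):
            if not here:
                continue
            olen = max(10, plen + int(round(rng.normal(0, cfg.ortholog_length_sd))))
            oid = f"{sp}_{gid}"
            oseq = _mutate_protein(rng, seq, olen)
            score, e_value = kmer_similarity(seq, oseq)
            hits.append(SimilarityHit(lid, oid, "Alyrata", sp, float(score), e_value))
            hits.append(SimilarityHit(oid, lid, sp, "Alyrata", float(score), e_value))
            proteins[oid] = oseq
            protein_lengths[oid] = olen
            ledger_genes[gid].ortholog_lengths[sp] = olen
            # occasional weaker decoy hit to a neighbour's ortholog
            if sp in previous_ortholog and rng.random() < 0.3:
                decoy_score = max(1.0, score / 2)
                hits.append(
                    SimilarityHit(
                        lid,
                        previous_ortholog[sp],
                        "Alyrata",
                        sp,
                        decoy_score,
                        math.exp(-decoy_score),
                    )
                )
            previous_ortholog[sp] = oid

    # ---- stage: splicing -------------------------------------------------
    rng = _rng(cfg.seed, "splicing")
    ledger_events: list[PlantedEvent] = []
    event_counts: EventCounts | None = None
    if planted_events:
        planted_events.sort()
        inclusion = {}
        exclusion = {}
        for event in planted_events:
            base = float(rng.uniform(0.25, 0.75))
            differential = bool(rng.random() < cfg.differential_splicing_fraction)
            if differential:
                delta = 0.35 * (1 if rng.random() < 0.5 else -1)
                psi_hs = float(np.clip(base + delta, 0.05, 0.95))
            else:
                psi_hs = base
            psi_by_cond = {"WT": base, "HS": psi_hs, "REC": base}
            inc_row, exc_row = [], []
            for sid, cond, _ in SAMPLES:
                inc = int(rng.binomial(cfg.reads_per_event, psi_by_cond[cond]))
                inc_row.append(inc)
                exc_row.append(cfg.reads_per_event - inc)
            inclusion[event.event_id] = inc_row
            exclusion[event.event_id] = exc_row
            ledger_events.append(
                PlantedEvent(
                    event.event_id,
                    event_gene[event.event_id],
                    event.event_type,
                    psi_by_cond,
                    differential,
                )
            )
        index = [e.event_id for e in planted_events]
        event_counts = EventCounts(
            pd.DataFrame.from_dict(inclusion, orient="index", columns=sample_ids).loc[index],
            pd.DataFrame.from_dict(exclusion, orient="index", columns=sample_ids).loc[index],
            {sid: cond for sid, cond, _ in SAMPLES},
        )

    ledger = TruthLedger(
        genes=ledger_genes,
        fused=fused,
        cut=cut,
        dropped=tuple(sorted(g for g, f in fates.items() if f == "dropped")),
        orphans=tuple(sorted(g for g, f in fates.items() if f == "orphan")),
        spurious_v1=tuple(spurious_v1),
        spurious_candidates=tuple(spurious_candidates),
        te_genes=te_genes,
        events=tuple(ledger_events),
    )
    return Scenario(
        config=cfg,
        truth=truth,
        v1=v1,
        candidates=candidates,
        reads=reads,
        hits=tuple(hits),
        protein_lengths=protein_lengths,
        proteins=proteins,
        te_intervals=tuple(sorted(te_intervals)),
        te_hits=tuple(te_hits),
        event_counts=event_counts,
        planted_events=tuple(planted_events),
        ledger=ledger,
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Score:
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int


def _score(predicted: set, truth: set) -> Score:
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    return Score(precision, recall, tp, fp, fn)


def _strip_reintroduced(gene_id: str) -> str:
    if gene_id.endswith(REINTRODUCED_SUFFIX):
        return gene_id[: -len(REINTRODUCED_SUFFIX)]
    return gene_id


def ledger_score(
    report: ReconciliationReport, ledger: TruthLedger
) -> dict[str, Score]:
    """Precision/recall of the report against the planted truth, per category.

    Categories: ``split`` and ``merge`` (component membership must match the
    planted fusion/cut exactly), ``removed`` (legacy-only ids vs planted
    spurious models), ``added`` (new-only ids vs planted dropped genes) and
    ``te`` (TE-classified ids vs planted TE genes).  Component member ids
    unknown to the ledger are an error.
    """
    known_v1 = ledger.legacy_ids()
    known_v2 = (
        set(ledger.genes)
        | set(ledger.spurious_candidates)
        | {lid + REINTRODUCED_SUFFIX for lid in known_v1}
    )
    unknown: list[str] = []
    for component in report.change_components:
        unknown.extend(g for g in component.v1_members if g not in known_v1)
        unknown.extend(g for g in component.v2_members if g not in known_v2)
    if unknown:
        raise ValueError("ids unknown to the ledger: " + ", ".join(sorted(set(unknown))))

    predicted_split = {
        (frozenset(c.v1_members), frozenset(c.v2_members))
        for c in report.components_of_kind("split")
    }
    truth_split = {
        (frozenset({lid}), frozenset(pair)) for lid, pair in ledger.fused.items()
    }
    predicted_merge = {
        (frozenset(c.v1_members), frozenset(c.v2_members))
        for c in report.components_of_kind("merge")
    }
    truth_merge = {
        (frozenset(lids), frozenset({gid})) for gid, lids in ledger.cut.items()
    }
    return {
        "split": _score(predicted_split, truth_split),
        "merge": _score(predicted_merge, truth_merge),
        "removed": _score(set(report.removed_v1_ids()), set(ledger.spurious_v1)),
        "added": _score(set(report.added_v2_ids()), set(ledger.dropped)),
        "te": _score(set(report.te_gene_ids()), set(ledger.te_genes)),
    }


# ---------------------------------------------------------------------------
# null splicing simulation
# ---------------------------------------------------------------------------


def simulate_null_splicing(
    n_events: int = 1000,
    reads_per_event: int = 500,
    seed: int = 0,
) -> EventCounts:
    """Event counts with identical true PSI in every condition (a null set)."""
    rng = np.random.default_rng([seed, 97])
    sample_ids = [sid for sid, _, _ in SAMPLES]
    inclusion, exclusion, index = [], [], []
    for i in range(n_events):
        true_psi = float(rng.uniform(0.2, 0.8))
        inc_row = [int(rng.binomial(reads_per_event, true_psi)) for _ in SAMPLES]
        inclusion.append(inc_row)
        exclusion.append([reads_per_event - inc for inc in inc_row])
        index.append(f"NG{i:04d}:SE:null")
    return EventCounts(
        pd.DataFrame(inclusion, index=index, columns=sample_ids),
        pd.DataFrame(exclusion, index=index, columns=sample_ids),
        {sid: cond for sid, cond, _ in SAMPLES},
    )
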