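"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity by the most literal route available
(all-pairs scans, double argmax, exhaustive pattern matching, hypergeometric
summation) without sharing code paths with the package internals.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from annoweave.interval_engine import OverlapEdge, overlap_fraction, overlap_nt
from annoweave.splicing import SpliceEvent


def overlap_graph_bruteforce(set_a, set_b, threshold, mode="span", same_strand=True):
    """All-pairs overlap scan, no interval index."""
    edges = []
    for a in set_a:
        for b in set_b:
            fraction = overlap_fraction(a, b, mode=mode, same_strand=same_strand)
            if fraction >= threshold:
                edges.append(OverlapEdge(a.id, b.id, overlap_nt(a, b, mode=mode), fraction))
    return sorted(edges)


def rbh_bruteforce(hits, species_a, species_b, max_e):
    """Double argmax with the higher-score / smaller-subject-id tie rule."""

    def best(query_species, subject_species):
        per_query: dict[str, list] = {}
        for h in hits:
            if (
                h.query_species == query_species
                and h.subject_species == subject_species
                and h.e_value <= max_e
            ):
                per_query.setdefault(h.query_id, []).append(h)
        out = {}
        for query, candidates in per_query.items():
            ranked = sorted(candidates, key=lambda h: (-h.score, h.subject_id))
            out[query] = ranked[0].subject_id
        return out

    forward = best(species_a, species_b)
    backward = best(species_b, species_a)
    return sorted(
        (q, s) for q, s in forward.items() if backward.get(s) == q
    )


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher exact p as an explicit hypergeometric pmf sum."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = stats.hypergeom(n, row1, col1)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    ks = np.arange(lo, hi + 1)
    pmf = rv.pmf(ks)
    p_obs = rv.pmf(a)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


# ---------------------------------------------------------------------------
# exhaustive splice-event enumeration
# ---------------------------------------------------------------------------


def _chain(t):
    return [(e.start, e.end) for e in t.exons]


def _gaps(chain):
    return [(chain[i][1], chain[i + 1][0]) for i in range(len(chain) - 1)]


def splice_events_bruteforce(gene) -> list[SpliceEvent]:
    """Re-derive every event by scanning all exon/intron combinations.

    Flanking splice sites are located through intron membership rather than
    positional adjacency, so this follows a different route than the
    package's enumerator.
    """
    transcripts = gene.transcripts
    events: set[SpliceEvent] = set()
    minus = gene.strand == "-"
    for x in range(len(transcripts)):
        for y in range(x + 1, len(transcripts)):
            pair = (transcripts[x], transcripts[y])
            for t1, t2 in (pair, pair[::-1]):
                ex1, ex2 = _chain(t1), _chain(t2)
                in1, in2 = _gaps(ex1), _gaps(ex2)

                # SE: an exon of t1 bounded by introns (d, start) and
                # (end, a) in t1, with (d, a) spliced in one piece in t2
                for exon in ex1:
                    lefts = [i for i in in1 if i[1] == exon[0]]
                    rights = [i for i in in1 if i[0] == exon[1]]
                    for left in lefts:
                        for right in rights:
                            if (left[0], right[1]) in in2 and exon not in ex2:
                                events.add(
                                    SpliceEvent(
                                        gene.id,
                                        "SE",
                                        (exon,),
                                        ((left[0], right[1]),),
                                        (left[0], right[1]),
                                    )
                                )

                # RI: intron of t1 strictly inside an exon of t2
                for intron in in1:
                    for exon in ex2:
                        if exon[0] < intron[0] and intron[1] < exon[1]:
                            events.add(
                                SpliceEvent(gene.id, "RI", (exon,), (intron,), intron)
                            )

            # alternative donor/acceptor: unordered intron pairs sharing one
            # boundary, with overlapping exons at the differing boundary
            t1, t2 = pair
            ex1, ex2 = _chain(t1), _chain(t2)
            in1, in2 = _gaps(ex1), _gaps(ex2)
            for i1 in in1:
                for i2 in in2:
                    if i1 == i2:
                        continue
                    if i1[0] == i2[0] and i1[1] != i2[1]:
                        down1 = [e for e in ex1 if e[0] == i1[1]]
                        down2 = [e for e in ex2 if e[0] == i2[1]]
                        if any(
                            max(a[0], b[0]) < min(a[1], b[1])
                            for a in down1
                            for b in down2
                        ):
                            short, long = sorted(
                                (i1, i2), key=lambda iv: iv[1] - iv[0]
                            )
                            kind = "A5SS" if minus else "A3SS"
                            events.add(
                                SpliceEvent(gene.id, kind, (short,), (long,), (i1[0],))
                            )
                    elif i1[1] == i2[1] and i1[0] != i2[0]:
                        up1 = [e for e in ex1 if e[1] == i1[0]]
                        up2 = [e for e in ex2 if e[1] == i2[0]]
                        if any(
                            max(a[0], b[0]) < min(a[1], b[1])
                            for a in up1
                            for b in up2
                        ):
                            short, long = sorted(
                                (i1, i2), key=lambda iv: iv[1] - iv[0]
                            )
                            kind = "A3SS" if minus else "A5SS"
                            events.add(
                                SpliceEvent(gene.id, kind, (short,), (long,), (i1[1],))
                            )

            # MXE: exclusive non-overlapping exons whose flanking introns
            # (found by membership) share both outer boundaries
            for e1 in ex1:
                for e2 in ex2:
                    if e1 in ex2 or e2 in ex1:
                        continue
                    if max(e1[0], e2[0]) < min(e1[1], e2[1]):
                        continue
                    flanks1 = [
                        (left[0], right[1])
                        for left in in1
                        if left[1] == e1[0]
                        for right in in1
                        if right[0] == e1[1]
                    ]
                    flanks2 = [
                        (left[0], right[1])
                        for left in in2
                        if left[1] == e2[0]
                        for right in in2
                        if right[0] == e2[1]
                    ]
                    for f1 in flanks1:
                        if f1 in flanks2:
                            first, second = sorted((e1, e2))
                            events.add(
                                SpliceEvent(gene.id, "MXE", (first,), (second,), f1)
                            )
    return sorted(events)
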