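"""Detection and classification of alternative-splicing events.

Four event classes are recognised from filtered junction evidence plus
per-base coverage:

* IR    — intron retention: an intron both spliced (junction observed) and
          retained (>= 1x coverage across its full length).
* A3SS  — one donor (5' splice site) joined to two alternative acceptors.
* A5SS  — one acceptor (3' splice site) joined to two alternative donors.
* ES    — exon skipping: a junction removing >= 1 complete internal exon,
          with both flanking inclusion junctions observed.

Events with more than two alternative sites are counted pairwise: a donor
spliced to k acceptors yields k(k-1)/2 A3SS events, so every event has
exactly two isoforms and a well-defined long-isoform frequency.

Each event carries a canonical identity key that is a pure function of
(type, chrom, strand, anchor coordinates), so events match across
individuals by key.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .coverage import CoverageTrack
from .genome_model import GeneModel, Intron, derive_introns
from .junction_io import JunctionEvidence, JunctionKey

log = logging.getLogger(__name__)

EVENT_TYPES = ["A3SS", "A5SS", "IR", "ES"]


@dataclass(frozen=True)
class ASEvent:
    """A classified AS event with a cross-individual identity key.

    Anchor layout by type (all coordinates 0-based half-open):

    * IR:   (intron_start, intron_end)
    * A3SS/A5SS: (shared_site, alt_site_1, alt_site_2) with alt sites sorted
    * ES:   (excl_start, excl_end, exon_start, exon_end,
             incl1_start, incl1_end, incl2_start, incl2_end)
    """

    event_type: str
    chrom: str
    strand: str
    anchors: tuple[int, ...]
    gene_id: str | None = field(compare=False, default=None)

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type}")
        if self.event_type in ("A3SS", "A5SS"):
            _, a1, a2 = self.anchors
            if a1 == a2:
                raise ValueError("alternative sites must differ")
        if self.event_type == "ES":
            xs, xe, es, ee = self.anchors[:4]
            if not (xs < es and ee < xe):
                raise ValueError("exclusion junction must strictly contain the skipped exon")

    @property
    def key(self) -> str:
        return f"{self.event_type}:{self.chrom}:{self.strand}:" + "-".join(
            map(str, self.anchors)
        )

    @property
    def anchor_span(self) -> tuple[int, int]:
        return (min(self.anchors), max(self.anchors))

    def with_gene(self, gene_id: str | None) -> "ASEvent":
        return ASEvent(self.event_type, self.chrom, self.strand, self.anchors, gene_id)


@dataclass
class EventCatalog:
    """All events detected in one individual."""

    individual_id: str
    events: list[ASEvent]

    def __post_init__(self) -> None:
        keys = [e.key for e in self.events]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate event keys in catalog")
        self.events.sort(key=lambda e: e.key)

    @property
    def type_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in EVENT_TYPES}
        for e in self.events:
            counts[e.event_type] += 1
        return counts

    @property
    def as_gene_count(self) -> int:
        """Distinct genes with at least one event (unassigned events excluded)."""
        return len({e.gene_id for e in self.events if e.gene_id is not None})


def alt_ss_junctions(event: ASEvent) -> tuple[JunctionKey, JunctionKey]:
    """The two junction keys of an A3SS/A5SS event, in anchor order.

    The shared site is the donor for A3SS and the acceptor for A5SS; on the
    '+' strand the donor is the intron start, on '-' the intron end.
    """
    shared, a1, a2 = event.anchors
    shared_at_start = (event.event_type == "A3SS") == (event.strand == "+")
    if shared_at_start:
        return (
            (event.chrom, event.strand, shared, a1),
            (event.chrom, event.strand, shared, a2),
        )
    return (
        (event.chrom, event.strand, a1, shared),
        (event.chrom, event.strand, a2, shared),
    )


def detect_alt_ss(junctions: Sequence[JunctionEvidence]) -> list[ASEvent]:
    """Alternative 3'/5' splice-site events from a filtered junction set.

    Junctions sharing a donor with k distinct acceptors yield k(k-1)/2 A3SS
    events (pairwise convention); sharing an acceptor likewise yields A5SS
    events. Donor/acceptor roles are strand-aware.
    """
    by_start: dict[tuple[str, str, int], set[int]] = defaultdict(set)
    by_end: dict[tuple[str, str, int], set[int]] = defaultdict(set)
    events: list[ASEvent] = []
    for j in junctions:
        if j.strand not in ("+", "-"):
            log.warning("unstranded junction %s skipped in alt-SS detection", j.key)
            continue
        by_start[(j.chrom, j.strand, j.intron_start)].add(j.intron_end)
        by_end[(j.chrom, j.strand, j.intron_end)].add(j.intron_start)
    for (chrom, strand, shared), alts in by_start.items():
        # shared intron start: donor on '+' (-> A3SS), acceptor on '-' (-> A5SS)
        etype = "A3SS" if strand == "+" else "A5SS"
        for a1, a2 in combinations(sorted(alts), 2):
            events.append(ASEvent(etype, chrom, strand, (shared, a1, a2)))
    for (chrom, strand, shared), alts in by_end.items():
        etype = "A5SS" if strand == "+" else "A3SS"
        for a1, a2 in combinations(sorted(alts), 2):
            events.append(ASEvent(etype, chrom, strand, (shared, a1, a2)))
    return events


def detect_ir(
    candidate_introns: Iterable[Intron],
    junctions: Sequence[JunctionEvidence],
    coverage: CoverageTrack,
) -> list[ASEvent]:
    """Intron-retention events.

    An intron is retained iff every base has depth >= 1 *and* the spliced
    junction exactly matching it passed the support filter (``junctions``
    is the filtered set), both in the same individual.
    """
    passed = {j.key for j in junctions}
    events = []
    seen: set[tuple] = set()
    for intron in candidate_introns:
        if intron.key in seen:
            continue
        seen.add(intron.key)
        if intron.key not in passed:
            continue
        if coverage.is_fully_covered(intron.chrom, intron.start, intron.end, min_depth=1.0):
            events.append(
                ASEvent("IR", intron.chrom, intron.strand, (intron.start, intron.end))
            )
    return events


def junction_implied_introns(junctions: Sequence[JunctionEvidence]) -> list[Intron]:
    """Treat each observed junction's removed interval as a (novel) intron."""
    return [
        Intron(j.chrom, j.strand, j.intron_start, j.intron_end, annotated=False)
        for j in junctions
    ]


def detect_es(
    junctions: Sequence[JunctionEvidence], genes: Mapping[str, GeneModel]
) -> list[ASEvent]:
    """Exon-skipping events.

    A filtered junction whose removed interval contains >= 1 complete
    internal exon of a same-strand transcript is an exclusion junction; a
    skipped exon is reported when both of its flanking inclusion junctions
    (the transcript's adjacent introns) are also in the filtered set. One
    event per (exclusion junction, skipped exon).
    """
    passed = {j.key for j in junctions}
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gid, g in genes.items():
        s, e = g.span
        trees[g.chrom].addi(s, e, gid)
    events: dict[str, ASEvent] = {}
    for j in junctions:
        for hit in trees[j.chrom].overlap(j.intron_start, j.intron_end):
            g = genes[hit.data]
            if g.strand != j.strand:
                continue
            for exons in g.transcripts.values():
                for k in range(1, len(exons) - 1):
                    es_, ee = exons[k]
                    if not (j.intron_start < es_ and ee < j.intron_end):
                        continue
                    i1 = (g.chrom, g.strand, exons[k - 1][1], es_)
                    i2 = (g.chrom, g.strand, ee, exons[k + 1][0])
                    if i1 in passed and i2 in passed:
                        ev = ASEvent(
                            "ES",
                            g.chrom,
                            g.strand,
                            (
                                j.intron_start,
                                j.intron_end,
                                es_,
                                ee,
                                i1[2],
                                i1[3],
                                i2[2],
                                i2[3],
                            ),
                        )
                        events.setdefault(ev.key, ev)
    return list(events.values())


def assign_genes(
    events: Iterable[ASEvent], genes: Mapping[str, GeneModel]
) -> list[ASEvent]:
    """Assign each event to the gene whose collapsed span contains its
    anchor span; smallest containing span wins, ties broken by gene id."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gid, g in genes.items():
        s, e = g.span
        trees[g.chrom].addi(s, e, gid)
    out = []
    for ev in events:
        s, e = ev.anchor_span
        hits = [
            h for h in trees[ev.chrom].overlap(s, e) if h.begin <= s and e <= h.end
        ]
        if hits:
            hits.sort(key=lambda h: (h.end - h.begin, h.data))
            out.append(ev.with_gene(hits[0].data))
        else:
            out.append(ev.with_gene(None))
    return out


def build_catalog(
    individual_id: str,
    junctions: Sequence[JunctionEvidence],
    coverage: CoverageTrack | None,
    genes: Mapping[str, GeneModel],
) -> EventCatalog:
    """Union of the three detectors for one individual, deduplicated by key.

    ``junctions`` must already be support-filtered. When ``coverage`` is
    None, IR detection is skipped with a warning.
    """
    events: dict[str, ASEvent] = {}
    for ev in detect_alt_ss(junctions):
        events.setdefault(ev.key, ev)
    for ev in detect_es(junctions, genes):
        events.setdefault(ev.key, ev)
    if coverage is None:
        log.warning("%s: no coverage supplied; IR detection skipped", individual_id)
    else:
        candidates = [i for g in genes.values() for i in derive_introns(g)]
        candidates += junction_implied_introns(junctions)
        for ev in detect_ir(candidates, junctions, coverage):
            events.setdefault(ev.key, ev)
    assigned = assign_genes(events.values(), genes)
    return EventCatalog(individual_id, assigned)


# ---------------------------------------------------------------------------
# Cross-individual presence and conservation summaries
# ---------------------------------------------------------------------------


def presence_matrix(catalogs: Sequence[EventCatalog]) -> tuple[pd.DataFrame, pd.Series]:
    """Event-key x individual boolean presence matrix plus a key->type map."""
    if not catalogs:
        raise ValueError("no catalogs supplied")
    individuals = [c.individual_id for c in catalogs]
    if len(set(individuals)) != len(individuals):
        raise ValueError("duplicate individual ids")
    types: dict[str, str] = {}
    data: dict[str, set[str]] = defaultdict(set)
    for c in catalogs:
        for ev in c.events:
            types[ev.key] = ev.event_type
            data[ev.key].add(c.individual_id)
    keys = sorted(data)
    mat = pd.DataFrame(
        [[ind in data[k] for ind in individuals] for k in keys],
        index=pd.Index(keys, name="event_key"),
        columns=individuals,
    )
    return mat, pd.Series({k: types[k] for k in keys}, name="event_type")


def type_shares(counts: Mapping[str, int]) -> pd.DataFrame:
    """Per-type event totals and percentage shares of the overall total."""
    total = sum(counts.values())
    rows = [
        {"event_type": t, "n_events": counts.get(t, 0),
         "share_pct": 100.0 * counts.get(t, 0) / total if total else 0.0}
        for t in EVENT_TYPES
    ]
    rows.append({"event_type": "Total", "n_events": total, "share_pct": 100.0 if total else 0.0})
    return pd.DataFrame(rows)


def conservation_percentage(n_subset: int, n_total: int) -> float:
    """Percent of events in a conservation bin, e.g. 12851 of 27902 -> 46.06."""
    if n_total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * n_subset / n_total


def conservation_summary(
    presence: pd.DataFrame, types: pd.Series, min_shared: int = 15
) -> pd.DataFrame:
    """Per-type counts of events found in exactly 1, >= min_shared, and all
    N individuals, with percentages relative to each type's total."""
    n = presence.shape[1]
    shared = presence.sum(axis=1)
    rows = []
    for t in EVENT_TYPES + ["Total"]:
        sel = types.index if t == "Total" else types.index[types == t]
        sh = shared.loc[sel]
        total = len(sel)
        n1 = int((sh == 1).sum())
        nk = int((sh >= min_shared).sum())
        nn = int((sh == n).sum())
        rows.append(
            {
                "event_type": t,
                "n_events": total,
                "n_in_1": n1,
                f"n_in_ge_{min_shared}": nk,
                f"n_in_{n}": nn,
                "pct_in_1": conservation_percentage(n1, total) if total else 0.0,
                f"pct_in_ge_{min_shared}": conservation_percentage(nk, total) if total else 0.0,
                f"pct_in_{n}": conservation_percentage(nn, total) if total else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    grand = df.loc[df["event_type"] == "Total", "n_events"].iloc[0]
    df["share_pct"] = [
        100.0 * v / grand if grand else 0.0 for v in df["n_events"]
    ]
    return df


def catalogs_to_frame(catalogs: Sequence[EventCatalog]) -> pd.DataFrame:
    """Long table of all events across catalogs (one row per event per
    individual)."""
    rows = []
    for c in catalogs:
        for ev in c.events:
            rows.append(
                {
                    "individual_id": c.individual_id,
                    "event_key": ev.key,
                    "event_type": ev.event_type,
                    "chrom": ev.chrom,
                    "strand": ev.strand,
                    "anchors": ",".join(map(str, ev.anchors)),
                    "gene_id": ev.gene_id if ev.gene_id is not None else "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "event_key",
            "event_type",
            "chrom",
            "strand",
            "anchors",
            "gene_id",
        ],
    )


def frame_to_events(df: pd.DataFrame) -> dict[str, list[ASEvent]]:
    """Inverse of :func:`catalogs_to_frame`, grouped by individual."""
    out: dict[str, list[ASEvent]] = defaultdict(list)
    for row in df.itertuples(index=False):
        anchors = tuple(int(x) for x in str(row.anchors).split(","))
        gene = row.gene_id if isinstance(row.gene_id, str) and row.gene_id else None
        out[row.individual_id].append(
            ASEvent(row.event_type, row.chrom, row.strand, anchors, gene)
        )
    return dict(out)
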