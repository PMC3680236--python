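"""Two-isoform quantification of AS events from junction reads.

Every event has a Long (L, inclusion) and a Short (S, exclusion) isoform:

* IR   — L is the intron-retained form; S the spliced form.
* ES   — L includes the skipped exon; S skips it.
* A3SS/A5SS — L is the alternative producing the longer mature transcript,
  i.e. the junction with the *shorter* intron.

The Isoform(L) frequency is inclusion / (inclusion + exclusion); with
inclusion 12 and exclusion 4 this is 12 / (12+4) = 75%. When both counts
are zero the frequency is undefined (None/NaN) and is propagated, never
imputed as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .as_events import ASEvent, EventCatalog, alt_ss_junctions
from .coverage import CoverageTrack
from .junction_io import JunctionEvidence, JunctionKey


@dataclass(frozen=True)
class IsoformQuant:
    """Inclusion/exclusion support for one event in one individual."""

    event_key: str
    individual_id: str
    inclusion_count: int
    exclusion_count: int

    def __post_init__(self) -> None:
        if self.inclusion_count < 0 or self.exclusion_count < 0:
            raise ValueError("isoform counts must be non-negative")

    @property
    def l_frequency(self) -> float | None:
        return l_frequency(self.inclusion_count, self.exclusion_count)


def l_frequency(inclusion: int, exclusion: int) -> float | None:
    """Long-isoform frequency, or None when no informative reads exist."""
    total = inclusion + exclusion
    if total == 0:
        return None
    return inclusion / total


def assign_long_isoform(event: ASEvent) -> tuple[JunctionKey | None, JunctionKey | None]:
    """(L junction, S junction) for an event.

    For A3SS/A5SS, L is the junction with the shorter intron. For IR the L
    isoform has no junction (it is the unspliced form): returns
    (None, spliced junction). For ES returns (None, exclusion junction);
    the two inclusion junctions are handled by the counting rule.
    """
    if event.event_type in ("A3SS", "A5SS"):
        j1, j2 = alt_ss_junctions(event)
        len1 = j1[3] - j1[2]
        len2 = j2[3] - j2[2]
        return (j1, j2) if len1 < len2 else (j2, j1)
    if event.event_type == "IR":
        s, e = event.anchors
        return (None, (event.chrom, event.strand, s, e))
    # ES
    xs, xe = event.anchors[:2]
    return (None, (event.chrom, event.strand, xs, xe))


def es_inclusion_junctions(event: ASEvent) -> tuple[JunctionKey, JunctionKey]:
    if event.event_type != "ES":
        raise ValueError("not an ES event")
    _, _, _, _, i1s, i1e, i2s, i2e = event.anchors
    return (
        (event.chrom, event.strand, i1s, i1e),
        (event.chrom, event.strand, i2s, i2e),
    )


def junction_count_map(junctions: Sequence[JunctionEvidence]) -> dict[JunctionKey, int]:
    """Junction key -> read count for one individual's (unfiltered) evidence."""
    counts: dict[JunctionKey, int] = {}
    for j in junctions:
        counts[j.key] = counts.get(j.key, 0) + j.read_count
    return counts


def count_supporting_reads(
    event: ASEvent,
    junction_counts: Mapping[JunctionKey, int],
    coverage: CoverageTrack | None = None,
) -> tuple[int, int]:
    """(inclusion_count, exclusion_count) for one event in one individual.

    * A3SS/A5SS: read counts of the L and S junctions.
    * ES: inclusion = floor of the mean of the two inclusion-junction
      counts; exclusion = exclusion-junction count.
    * IR: inclusion = floor of the mean depth at the two exon-intron
      boundary bases (first and last intron base); exclusion = spliced
      junction count. Boundary depth is used instead of intron-body density
      so both counts are commensurate junction-like read counts, directly
      usable in 2x2 contingency tables; intron-body coverage would scale
      with intron length. Requires ``coverage``.

    Missing evidence yields zero counts (frequency then undefined).
    """
    if event.event_type in ("A3SS", "A5SS"):
        lj, sj = assign_long_isoform(event)
        return junction_counts.get(lj, 0), junction_counts.get(sj, 0)
    if event.event_type == "ES":
        i1, i2 = es_inclusion_junctions(event)
        _, sj = assign_long_isoform(event)
        incl = math.floor(
            (junction_counts.get(i1, 0) + junction_counts.get(i2, 0)) / 2
        )
        return incl, junction_counts.get(sj, 0)
    # IR
    if coverage is None:
        raise ValueError("IR quantification requires coverage")
    s, e = event.anchors
    d1 = coverage.depth(event.chrom, s)
    d2 = coverage.depth(event.chrom, e - 1)
    incl = math.floor((d1 + d2) / 2)
    _, sj = assign_long_isoform(event)
    return incl, junction_counts.get(sj, 0)


def quantify_catalog(
    events: Sequence[ASEvent],
    individual_id: str,
    junctions: Sequence[JunctionEvidence],
    coverage: CoverageTrack | None = None,
) -> list[IsoformQuant]:
    """Quantify a set of events against one individual's evidence.

    ``junctions`` should be the full (unfiltered) evidence for the
    individual so that events detected elsewhere can still be quantified
    here even with sub-threshold support.
    """
    counts = junction_count_map(junctions)
    out = []
    for ev in events:
        cov = coverage if ev.event_type == "IR" else None
        if ev.event_type == "IR" and coverage is None:
            incl, excl = 0, 0
        else:
            incl, excl = count_supporting_reads(ev, counts, cov)
        out.append(IsoformQuant(ev.key, individual_id, incl, excl))
    return out


def quant_frame(quants: Sequence[IsoformQuant]) -> pd.DataFrame:
    """Long quantification table with an ``l_frequency`` column (NaN when
    undefined)."""
    rows = [
        {
            "event_key": q.event_key,
            "individual_id": q.individual_id,
            "inclusion_count": q.inclusion_count,
            "exclusion_count": q.exclusion_count,
            "l_frequency": float("nan") if q.l_frequency is None else q.l_frequency,
        }
        for q in quants
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "event_key",
            "individual_id",
            "inclusion_count",
            "exclusion_count",
            "l_frequency",
        ],
    )
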