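"""Splice-junction evidence: I/O, support filtering, known/novel labelling.

A junction is identified across individuals by (chrom, strand, intron_start,
intron_end) — the genomic interval removed by splicing, 0-based half-open.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_model import GeneModel, annotated_intron_set

log = logging.getLogger(__name__)

JunctionKey = tuple[str, str, int, int]

#: Column order of the tab-delimited junction dialect.
TSV_COLUMNS = [
    "chrom",
    "intron_start",
    "intron_end",
    "strand",
    "read_count",
    "distinct_positions",
    "min_overhang",
]


@dataclass(frozen=True)
class JunctionEvidence:
    """One observed splice junction for one individual.

    ``distinct_positions`` counts distinct alignment start coordinates among
    supporting reads (guards against duplicated read stacks);
    ``min_overhang`` is the smaller of the maximal left/right anchor lengths
    across supporting reads.
    """

    chrom: str
    strand: str
    intron_start: int
    intron_end: int
    read_count: int
    distinct_positions: int
    min_overhang: int
    individual_id: str = ""

    def __post_init__(self) -> None:
        if self.intron_end <= self.intron_start:
            raise ValueError(
                f"junction end must exceed start: {self.intron_start}-{self.intron_end}"
            )
        if self.read_count < 0 or self.distinct_positions < 0 or self.min_overhang < 0:
            raise ValueError("junction counts must be non-negative")
        if self.distinct_positions > self.read_count:
            raise ValueError("distinct_positions cannot exceed read_count")

    @property
    def key(self) -> JunctionKey:
        return (self.chrom, self.strand, self.intron_start, self.intron_end)


@dataclass(frozen=True)
class FilterConfig:
    """Junction support thresholds.

    Defaults implement the support rule used for the population survey:
    at least two supporting reads, at a non-repetitive (>= 2 distinct)
    match position, with at least four aligned bases on both sides of the
    junction.
    """

    min_reads: int = 2
    min_distinct_positions: int = 2
    min_overhang: int = 4

    def __post_init__(self) -> None:
        if min(self.min_reads, self.min_distinct_positions, self.min_overhang) < 1:
            raise ValueError("all filter thresholds must be >= 1")


def _parse_tsv(path: Path, individual_id: str) -> list[JunctionEvidence]:
    out: list[JunctionEvidence] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 tab-separated fields")
            try:
                out.append(
                    JunctionEvidence(
                        chrom=parts[0],
                        intron_start=int(parts[1]),
                        intron_end=int(parts[2]),
                        strand=parts[3],
                        read_count=int(parts[4]),
                        distinct_positions=int(parts[5]),
                        min_overhang=int(parts[6]),
                        individual_id=individual_id,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def _parse_bed12(path: Path, individual_id: str) -> list[JunctionEvidence]:
    """TopHat-style junctions.bed: each record's block gaps are introns.

    BED12 carries no duplicate-position or per-side-anchor metadata, so
    ``distinct_positions`` is set to the read count (score) and the overhang
    to the smaller flanking block size.
    """
    out: list[JunctionEvidence] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED fields")
            try:
                chrom, chrom_start = parts[0], int(parts[1])
                score, strand = int(float(parts[4])), parts[5]
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                starts = [int(x) for x in parts[11].rstrip(",").split(",")]
                for i in range(len(sizes) - 1):
                    j_start = chrom_start + starts[i] + sizes[i]
                    j_end = chrom_start + starts[i + 1]
                    out.append(
                        JunctionEvidence(
                            chrom=chrom,
                            strand=strand,
                            intron_start=j_start,
                            intron_end=j_end,
                            read_count=score,
                            distinct_positions=score,
                            min_overhang=min(sizes[i], sizes[i + 1]),
                            individual_id=individual_id,
                        )
                    )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_junctions(
    path: str | Path, dialect: str = "tsv", individual_id: str = ""
) -> list[JunctionEvidence]:
    """Read per-individual junction evidence (``tsv`` or ``bed12`` dialect)."""
    path = Path(path)
    if dialect == "tsv":
        return _parse_tsv(path, individual_id)
    if dialect == "bed12":
        return _parse_bed12(path, individual_id)
    raise ValueError(f"unknown junction dialect {dialect!r}")


def write_junctions(junctions: Sequence[JunctionEvidence], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(TSV_COLUMNS) + "\n")
        for j in sorted(junctions, key=lambda j: j.key):
            fh.write(
                f"{j.chrom}\t{j.intron_start}\t{j.intron_end}\t{j.strand}\t"
                f"{j.read_count}\t{j.distinct_positions}\t{j.min_overhang}\n"
            )


def filter_junctions(
    junctions: Iterable[JunctionEvidence], cfg: FilterConfig = FilterConfig()
) -> list[JunctionEvidence]:
    """Keep junctions meeting all three support thresholds."""
    junctions = list(junctions)
    passing = [
        j
        for j in junctions
        if j.read_count >= cfg.min_reads
        and j.distinct_positions >= cfg.min_distinct_positions
        and j.min_overhang >= cfg.min_overhang
    ]
    log.info("junction filter: %d passed, %d failed", len(passing), len(junctions) - len(passing))
    return passing


def classify_known_novel(
    junctions: Sequence[JunctionEvidence], genes: Mapping[str, GeneModel]
) -> list[str]:
    """Label each junction 'known' (exactly matches an annotated intron,
    same strand) or 'novel'."""
    annotated = annotated_intron_set(genes)
    labels = ["known" if j.key in annotated else "novel" for j in junctions]
    counts = Counter(labels)
    log.info("junctions: %d known, %d novel", counts.get("known", 0), counts.get("novel", 0))
    return labels


def junction_sharing_histogram(
    per_individual: Mapping[str, Iterable[JunctionEvidence]],
    genes: Mapping[str, GeneModel],
) -> pd.DataFrame:
    """Counts of distinct junctions present in exactly k of N individuals,
    split by known/novel status against the annotation."""
    if len(per_individual) < 2:
        raise ValueError("sharing histogram needs >= 2 individuals")
    annotated = annotated_intron_set(genes)
    presence: dict[JunctionKey, set[str]] = defaultdict(set)
    for ind, junctions in per_individual.items():
        for j in junctions:
            presence[j.key].add(ind)
    hist: Counter[tuple[int, str]] = Counter()
    for key, inds in presence.items():
        status = "known" if key in annotated else "novel"
        hist[(len(inds), status)] += 1
    n = len(per_individual)
    rows = [
        {
            "n_individuals": k,
            "known": hist.get((k, "known"), 0),
            "novel": hist.get((k, "novel"), 0),
        }
        for k in range(1, n + 1)
    ]
    df = pd.DataFrame(rows)
    df["total"] = df["known"] + df["novel"]
    return df
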