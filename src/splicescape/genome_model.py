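"""Gene-annotation model: genes, transcripts, exons, derived introns.

All coordinates are internally 0-based half-open ``[start, end)``; GFF3
input/output converts from/to the 1-based closed convention at the file
boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

log = logging.getLogger(__name__)

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of half-open intervals as a sorted list of disjoint intervals."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class Intron:
    """Genomic interval removed by splicing between two adjacent exons."""

    chrom: str
    strand: str
    start: int
    end: int
    gene_id: str = field(compare=False, default="")
    annotated: bool = field(compare=False, default=True)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"zero/negative-length intron {self.start}-{self.end}")

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.start, self.end)


@dataclass
class GeneModel:
    """One gene: a set of transcripts, each a sorted list of exon intervals."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, list[Interval]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene without transcripts")
        for tx_id, exons in self.transcripts.items():
            if not exons:
                raise ValueError(f"{tx_id}: transcript without exons")
            exons.sort()
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise ValueError(f"{tx_id}: overlapping exons {s1}-{e1} and {s2}-{e2}")

    @property
    def collapsed_exons(self) -> list[Interval]:
        """Union of exon intervals over all transcripts."""
        return merge_intervals(iv for exons in self.transcripts.values() for iv in exons)

    @property
    def collapsed_length(self) -> int:
        return sum(e - s for s, e in self.collapsed_exons)

    @property
    def span(self) -> Interval:
        ce = self.collapsed_exons
        return (ce[0][0], ce[-1][1])


def collapsed_exon_length(gene: GeneModel) -> int:
    """Total exonic bases of the gene's exon-interval union (FPKM denominator)."""
    return gene.collapsed_length


def derive_introns(gene: GeneModel) -> list[Intron]:
    """Introns between adjacent exons, deduplicated across transcripts.

    Per transcript with n exons there are n-1 introns; identical intervals
    arising from multiple transcripts are collapsed to a single record
    because downstream intron-retention events are per-intron entities.
    """
    seen: dict[tuple, Intron] = {}
    for exons in gene.transcripts.values():
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 == e1:
                # abutting exons leave no intron
                continue
            intr = Intron(gene.chrom, gene.strand, e1, s2, gene_id=gene.gene_id)
            seen.setdefault(intr.key, intr)
    return sorted(seen.values(), key=lambda i: (i.start, i.end))


def annotated_intron_set(genes: Mapping[str, GeneModel]) -> set[tuple[str, str, int, int]]:
    """All annotated intron identity keys (chrom, strand, start, end)."""
    keys: set[tuple[str, str, int, int]] = set()
    for gene in genes.values():
        keys.update(i.key for i in derive_introns(gene))
    return keys


def load_annotation(gff3_path: str | Path) -> dict[str, GeneModel]:
    """Load gene/mRNA/exon models from a GFF3 file.

    Exons are attached via their ``Parent`` attribute; exons whose parent
    transcript is absent are skipped with a warning.
    """
    gff3_path = Path(gff3_path)
    n_records = 0
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            if len(stripped.split("\t")) != 9:
                raise ValueError(
                    f"malformed GFF3 {gff3_path}: line {lineno} does not have 9 fields"
                )
            n_records += 1
    if n_records == 0:
        log.warning("no genes loaded from %s (empty GFF3)", gff3_path)
        return {}
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ValueError(f"malformed GFF3 {gff3_path}: {exc}") from exc

    genes: dict[str, GeneModel] = {}
    n_orphan = 0
    for g in db.features_of_type("gene"):
        transcripts: dict[str, list[Interval]] = {}
        for t in db.children(g, featuretype=("mRNA", "transcript")):
            exons = sorted((e.start - 1, e.end) for e in db.children(t, featuretype="exon"))
            if exons:
                transcripts[t.id] = exons
        if not transcripts:
            log.warning("gene %s has no transcripts with exons; skipped", g.id)
            continue
        genes[g.id] = GeneModel(g.id, g.seqid, g.strand, transcripts)

    tx_ids = {t for gm in genes.values() for t in gm.transcripts}
    for e in db.features_of_type("exon"):
        parents = e.attributes.get("Parent", [])
        if not any(p in tx_ids for p in parents):
            n_orphan += 1
    if n_orphan:
        log.warning("%d exon records without a loadable parent transcript were skipped", n_orphan)
    if not genes:
        log.warning("no genes loaded from %s", gff3_path)
    log.info("loaded %d genes from %s", len(genes), gff3_path)
    return genes


def write_gff3(genes: Mapping[str, GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(genes):
            g = genes[gid]
            gs, ge = g.span
            fh.write(
                f"{g.chrom}\tsplicescape\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\tID={gid}\n"
            )
            for tx_id in sorted(g.transcripts):
                exons = g.transcripts[tx_id]
                fh.write(
                    f"{g.chrom}\tsplicescape\tmRNA\t{exons[0][0] + 1}\t{exons[-1][1]}\t.\t"
                    f"{g.strand}\t.\tID={tx_id};Parent={gid}\n"
                )
                for i, (s, e) in enumerate(exons, 1):
                    fh.write(
                        f"{g.chrom}\tsplicescape\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={tx_id}.exon{i};Parent={tx_id}\n"
                    )
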