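"""Gene-expression summaries: FPKM, expression categories, feature densities.

FPKM = fragments per kilobase of collapsed exonic gene model per million
mapped fragments. Counts are fragments (read pairs counted once). The
per-individual mapped total is supplied by the caller (library-size table)
because the genome-wide mapped total generally exceeds the sum of counts
over the annotated gene set.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .genome_model import GeneModel, derive_introns, merge_intervals

log = logging.getLogger(__name__)

CATEGORIES = ["zero", "low", "medium", "high"]


def compute_fpkm(fragment_count: int, exonic_length: int, total_mapped_fragments: int) -> float:
    """FPKM = count / (exonic kb) / (millions of mapped fragments)."""
    if exonic_length <= 0:
        raise ValueError("exonic_length must be positive")
    if total_mapped_fragments <= 0:
        raise ValueError("total_mapped_fragments must be positive")
    if fragment_count < 0:
        raise ValueError("fragment_count must be non-negative")
    return fragment_count / (exonic_length / 1e3) / (total_mapped_fragments / 1e6)


def categorize_expression(fpkm: float, low_high: float = 5.0, medium_high: float = 40.0) -> str:
    """Expression category: zero (=0), low (0,5), medium [5,40], high (>40).

    The value 5 counts as medium and 40 as medium; both boundaries are
    configurable.
    """
    if fpkm < 0:
        raise ValueError("FPKM must be non-negative")
    if fpkm == 0:
        return "zero"
    if fpkm > medium_high:
        return "high"
    if fpkm >= low_high:
        return "medium"
    return "low"


def read_fragment_counts(path: str | Path) -> pd.DataFrame:
    """Long-format per-gene fragment counts: gene_id, individual_id, count."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene_id", "individual_id", "count"])
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative fragment counts")
    return df


def read_library_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["individual_id", "total_fragments"])
    return dict(zip(df["individual_id"], df["total_fragments"].astype(int)))


def fpkm_table(
    counts: pd.DataFrame,
    genes: Mapping[str, GeneModel],
    library_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Wide gene x individual FPKM table.

    ``library_sizes`` gives per-individual total mapped fragments; if absent
    the per-individual sum of the supplied counts is used.
    """
    wide = counts.pivot_table(
        index="gene_id", columns="individual_id", values="count", fill_value=0
    )
    unknown = [g for g in wide.index if g not in genes]
    if unknown:
        raise KeyError(f"counts reference genes absent from annotation: {unknown[:5]}")
    lengths = np.array([genes[g].collapsed_length for g in wide.index], dtype=float)
    if library_sizes is None:
        totals = wide.sum(axis=0).astype(float)
    else:
        totals = pd.Series({c: float(library_sizes[c]) for c in wide.columns})
    fpkm = wide.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)
    fpkm.index.name = "gene_id"
    return fpkm.sort_index()


def categorize_table(fpkm: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-gene per-individual category labels."""
    return fpkm.map(lambda v: categorize_expression(v, **kwargs))


def category_fractions(categories: pd.DataFrame) -> pd.DataFrame:
    """Per-individual fraction of genes in each expression category."""
    frac = categories.apply(lambda col: col.value_counts(normalize=True))
    frac = frac.reindex(CATEGORIES).fillna(0.0)
    frac.index.name = "category"
    return frac


def top_expressed(fpkm: pd.DataFrame, n: int) -> pd.DataFrame:
    """Top-n genes ranked by mean FPKM across individuals, ties broken by id."""
    if fpkm.empty:
        raise ValueError("empty expression table")
    mean = fpkm.mean(axis=1)
    ranked = mean.to_frame("mean_fpkm").reset_index()
    ranked = ranked.sort_values(["mean_fpkm", "gene_id"], ascending=[False, True])
    return ranked.head(n).reset_index(drop=True)


def feature_density_summary(
    coverage: CoverageTrack,
    genes: Mapping[str, GeneModel],
    total_mapped_fragments: int,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Coverage split over exon / intron / intergenic feature classes.

    Each base is assigned to exactly one class with precedence
    exon > intron > intergenic. Reported per class: total length, coverage
    integral (sum of depth over bases), fraction of the genome-wide coverage
    integral, and read density in FPKM-style units
    (integral / kb of class / millions of mapped fragments).
    """
    # chromosome universe and lengths
    chroms: dict[str, int] = {}
    for g in genes.values():
        chroms[g.chrom] = max(chroms.get(g.chrom, 0), g.span[1])
    for c in coverage.chroms:
        chroms[c] = max(chroms.get(c, 0), coverage.chrom_max_end(c))
    if chrom_lengths:
        for c, ln in chrom_lengths.items():
            chroms[c] = max(chroms.get(c, 0), ln)
    known = set(chroms)
    for c in coverage.chroms:
        if c not in known:  # pragma: no cover - defensive
            log.warning("coverage on unknown chrom %s skipped", c)

    integral = {"exon": 0.0, "intron": 0.0, "intergenic": 0.0}
    length = {"exon": 0, "intron": 0, "intergenic": 0}
    for chrom, clen in chroms.items():
        mask = np.zeros(clen, dtype=np.int8)  # 0 intergenic, 1 intron, 2 exon
        for g in genes.values():
            if g.chrom != chrom:
                continue
            for i in derive_introns(g):
                mask[i.start : i.end] = np.maximum(mask[i.start : i.end], 1)
        for g in genes.values():
            if g.chrom != chrom:
                continue
            for s, e in g.collapsed_exons:
                mask[s:e] = 2
        depth = np.zeros(clen, dtype=float)
        if chrom in coverage.chroms:
            starts, ends, values = coverage._chroms[chrom]
            for s, e, v in zip(starts, ends, values):
                depth[s : min(e, clen)] = v
        for code, name in ((2, "exon"), (1, "intron"), (0, "intergenic")):
            sel = mask == code
            length[name] += int(sel.sum())
            integral[name] += float(depth[sel].sum())

    total = sum(integral.values())
    rows = []
    for name in ("exon", "intron", "intergenic"):
        dens = (
            integral[name] / (length[name] / 1e3) / (total_mapped_fragments / 1e6)
            if length[name]
            else 0.0
        )
        rows.append(
            {
                "feature": name,
                "length_bp": length[name],
                "coverage_integral": integral[name],
                "fraction_of_coverage": integral[name] / total if total else 0.0,
                "density_fpkm": dens,
            }
        )
    return pd.DataFrame(rows)
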