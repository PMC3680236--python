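"""End-to-end orchestration from a single YAML config.

Outputs are plain TSV/JSON/Newick, deterministic for a fixed
(inputs, config) pair: report files are byte-identical across re-runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .as_events import (
    EventCatalog,
    build_catalog,
    catalogs_to_frame,
    conservation_summary,
    presence_matrix,
    type_shares,
)
from .coverage import CoverageTrack
from .expression import (
    category_fractions,
    categorize_table,
    fpkm_table,
    read_fragment_counts,
    read_library_sizes,
)
from .genome_model import load_annotation
from .isoform_quant import quant_frame, quantify_catalog
from .junction_io import (
    FilterConfig,
    classify_known_novel,
    filter_junctions,
    junction_sharing_histogram,
    read_junctions,
)
from .population_var import PopulationConfig, analyze_population

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class IndividualInput:
    individual_id: str
    group: str
    junctions: Path
    coverage: Path | None = None


@dataclass
class RunConfig:
    annotation: Path
    fragment_counts: Path
    individuals: list[IndividualInput]
    library_sizes: Path | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    min_fpkm: float = 5.0
    fdr_q: float = 0.05
    min_shared: int = 15
    bh_family: str = "group"
    exclude: list[str] = field(default_factory=list)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def _p(name: str) -> Path:
            return base / raw[name]

        inds = [
            IndividualInput(
                individual_id=i["id"],
                group=i["group"],
                junctions=base / i["junctions"],
                coverage=(base / i["coverage"]) if i.get("coverage") else None,
            )
            for i in raw["individuals"]
        ]
        filt = FilterConfig(**raw.get("filter", {}))
        pop = raw.get("population", {})
        cfg = cls(
            annotation=_p("annotation"),
            fragment_counts=_p("fragment_counts"),
            individuals=inds,
            library_sizes=_p("library_sizes") if raw.get("library_sizes") else None,
            filter=filt,
            min_fpkm=float(pop.get("min_fpkm", 5.0)),
            fdr_q=float(pop.get("fdr_q", 0.05)),
            min_shared=int(pop.get("min_shared", 15)),
            bh_family=pop.get("bh_family", "group"),
            exclude=list(pop.get("exclude", [])),
            raw=raw,
        )
        missing = [
            str(p)
            for p in [cfg.annotation, cfg.fragment_counts, cfg.library_sizes]
            + [i.junctions for i in inds]
            + [i.coverage for i in inds]
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError("missing input files: " + ", ".join(missing))
        return cfg

    @property
    def groups(self) -> dict[str, list[str]]:
        g: dict[str, list[str]] = {}
        for i in self.individuals:
            g.setdefault(i.group, []).append(i.individual_id)
        return g

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def run_all(cfg: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run every stage; returns the map of written report files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    genes = load_annotation(cfg.annotation)

    # --- junction reading, filtering, catalogs -----------------------------
    raw_junctions = {}
    filtered = {}
    coverages: dict[str, CoverageTrack | None] = {}
    catalogs: list[EventCatalog] = []
    for ind in cfg.individuals:
        junctions = read_junctions(ind.junctions, "tsv", ind.individual_id)
        raw_junctions[ind.individual_id] = junctions
        filtered[ind.individual_id] = filter_junctions(junctions, cfg.filter)
        cov = (
            CoverageTrack.from_bedgraph(ind.coverage) if ind.coverage else None
        )
        coverages[ind.individual_id] = cov
        catalogs.append(
            build_catalog(ind.individual_id, filtered[ind.individual_id], cov, genes)
        )

    cat_df = catalogs_to_frame(catalogs)
    _write_tsv(cat_df, out / "catalogs.tsv")
    written["catalogs"] = out / "catalogs.tsv"

    per_ind = pd.DataFrame(
        [
            {
                "individual_id": c.individual_id,
                "as_genes": c.as_gene_count,
                **c.type_counts,
            }
            for c in catalogs
        ]
    )
    _write_tsv(per_ind, out / "per_individual_events.tsv")
    written["per_individual_events"] = out / "per_individual_events.tsv"

    # --- junction sharing + known/novel ------------------------------------
    if len(cfg.individuals) >= 2:
        sharing = junction_sharing_histogram(filtered, genes)
        _write_tsv(sharing, out / "junction_sharing.tsv")
        written["junction_sharing"] = out / "junction_sharing.tsv"

    # --- presence + conservation summary -----------------------------------
    presence, types = presence_matrix(catalogs)
    pres_out = presence.astype(int)
    pres_out.insert(0, "event_type", types)
    _write_tsv(pres_out, out / "presence_matrix.tsv", index=True)
    written["presence_matrix"] = out / "presence_matrix.tsv"

    total_counts = types.value_counts().to_dict()
    shares = type_shares(total_counts)
    cons = conservation_summary(presence, types, cfg.min_shared)
    _write_tsv(shares, out / "type_shares.tsv")
    _write_tsv(cons, out / "conservation_summary.tsv")
    written["type_shares"] = out / "type_shares.tsv"
    written["conservation_summary"] = out / "conservation_summary.tsv"

    # --- expression ---------------------------------------------------------
    counts = read_fragment_counts(cfg.fragment_counts)
    lib = read_library_sizes(cfg.library_sizes) if cfg.library_sizes else None
    fpkm = fpkm_table(counts, genes, lib)
    _write_tsv(fpkm, out / "fpkm.tsv", index=True)
    written["fpkm"] = out / "fpkm.tsv"
    cats = categorize_table(fpkm)
    fracs = category_fractions(cats)
    _write_tsv(fracs, out / "expression_categories.tsv", index=True)
    written["expression_categories"] = out / "expression_categories.tsv"

    # --- quantification ------------------------------------------------------
    all_events = {}
    for c in catalogs:
        for ev in c.events:
            all_events.setdefault(ev.key, ev)
    events = [all_events[k] for k in sorted(all_events)]
    quants = []
    for ind in cfg.individuals:
        quants.extend(
            quantify_catalog(
                events,
                ind.individual_id,
                raw_junctions[ind.individual_id],
                coverages[ind.individual_id],
            )
        )
    qdf = quant_frame(quants)
    _write_tsv(qdf, out / "isoform_quant.tsv")
    written["isoform_quant"] = out / "isoform_quant.tsv"

    # --- population variation ------------------------------------------------
    pop = PopulationConfig(
        groups=cfg.groups,
        min_fpkm=cfg.min_fpkm,
        fdr_q=cfg.fdr_q,
        bh_family=cfg.bh_family,
        exclude=cfg.exclude,
    )
    result = analyze_population(events, qdf, fpkm, pop)
    _write_tsv(result.correlation, out / "spearman_correlation.tsv", index=True)
    written["spearman_correlation"] = out / "spearman_correlation.tsv"
    (out / "dendrogram.nwk").write_text(result.newick + "\n")
    written["dendrogram"] = out / "dendrogram.nwk"
    _write_tsv(result.tests, out / "fisher_tests.tsv")
    written["fisher_tests"] = out / "fisher_tests.tsv"
    summary = pd.DataFrame(
        [{"group": g, **s} for g, s in sorted(result.group_summaries.items())]
    )
    _write_tsv(summary, out / "variation_summary.tsv")
    written["variation_summary"] = out / "variation_summary.tsv"

    manifest = {
        "splicescape_version": __version__,
        "config_hash": cfg.config_hash(),
        "n_genes": len(genes),
        "n_individuals": len(cfg.individuals),
        "row_counts": {name: _count_rows(path) for name, path in sorted(written.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    written["manifest"] = out / "manifest.json"
    return written


def _count_rows(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for _ in fh)
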