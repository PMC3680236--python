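"""Synthetic multi-individual RNA-seq junction data with known ground truth.

The generator emits exactly the formats the pipeline consumes — GFF3
annotation, per-individual junction TSVs and sparse bedGraph coverage, a
fragment-count table and a library-size table — plus a JSON ground-truth
record, so every pipeline stage is testable without external data.

Statistical model: each AS gene hosts one event whose type is drawn from a
configurable mixture (default 0.40 IR / 0.32 A3SS / 0.20 A5SS / 0.08 ES,
the observed genome-wide type shares in poplar xylem). Each event has a
base long-isoform frequency p ~ Beta(a, b); a configurable fraction of
events carries a between-individual shift of size dp (whole-group or
single-individual scope). Per individual, the event's informative depth n
is Poisson with mean ~84 (twice the observed per-junction read density of
~42), and the inclusion count is Binomial(n, p) — matching the sampling
assumption of the downstream Fisher tests — with an optional beta-binomial
overdispersion knob.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .as_events import ASEvent
from .coverage import write_bedgraph
from .genome_model import GeneModel, write_gff3
from .isoform_quant import (
    assign_long_isoform,
    es_inclusion_junctions,
)
from .junction_io import JunctionEvidence, write_junctions

TRUTH_VERSION = 1


def _default_groups() -> dict[str, list[str]]:
    return {
        "southern": [f"PT{i:02d}" for i in range(2, 14)],
        "northern": [f"PT{i:02d}" for i in range(14, 22)],
    }


def _default_mixture() -> dict[str, float]:
    return {"IR": 0.40, "A3SS": 0.32, "A5SS": 0.20, "ES": 0.08}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; the defaults are the study conditions."""

    seed: int = 0
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (4, 9)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (60, 200)
    gene_gap: tuple[int, int] = (300, 800)
    n_chroms: int = 2
    groups: dict[str, list[str]] = field(default_factory=_default_groups)
    as_gene_fraction: float = 0.6
    as_mixture: dict[str, float] = field(default_factory=_default_mixture)
    base_freq_beta: tuple[float, float] = (2.0, 2.0)
    shift_fraction: float = 0.10
    shift_dp: float = 0.30
    shift_scope: str = "individual"  # "individual" or "group"
    event_depth_mean: float = 84.0
    junction_depth_mean: float = 42.0
    below_support_fraction: float = 0.05
    overhang: int = 20
    fpkm_lognormal: tuple[float, float] = (math.log(20.0), 1.0)
    library_size: int = 1_000_000
    beta_binomial_rho: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.as_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("as_mixture must sum to 1")
        if self.shift_scope not in ("group", "individual"):
            raise ValueError("shift_scope must be 'group' or 'individual'")
        if not (0 <= self.shift_dp <= 1):
            raise ValueError("shift_dp must lie in [0, 1]")
        if self.as_mixture.get("ES", 0) > 0 and self.exons_per_gene[1] < 3:
            raise ValueError("ES events need genes with >= 3 exons")

    @property
    def individuals(self) -> list[str]:
        return [m for members in self.groups.values() for m in members]


@dataclass
class TrueEvent:
    """Ground truth for one simulated AS event."""

    event: ASEvent
    p_by_individual: dict[str, float]
    passes_support: bool
    shifted: bool

    @property
    def key(self) -> str:
        return self.event.key


@dataclass
class GroundTruth:
    individuals: list[str]
    groups: dict[str, list[str]]
    events: list[TrueEvent]
    fpkm: dict[str, float]  # true per-gene FPKM, shared across individuals


# ---------------------------------------------------------------------------
# Genome + truth generation
# ---------------------------------------------------------------------------


def generate_genome(cfg: SimulationConfig) -> tuple[dict[str, GeneModel], GroundTruth]:
    """Deterministically (under cfg.seed) build gene models and event truth."""
    rng = np.random.default_rng(cfg.seed)
    n_as = round(cfg.as_gene_fraction * cfg.n_genes)
    as_idx = set(rng.choice(cfg.n_genes, size=n_as, replace=False).tolist())
    types = list(cfg.as_mixture)
    probs = [cfg.as_mixture[t] for t in types]
    cursors = {f"Chr{c + 1:02d}": 1000 for c in range(cfg.n_chroms)}
    chrom_names = sorted(cursors)

    genes: dict[str, GeneModel] = {}
    events: list[TrueEvent] = []
    fpkm: dict[str, float] = {}
    individuals = cfg.individuals

    for i in range(cfg.n_genes):
        gid = f"SYNG{i + 1:04d}"
        chrom = chrom_names[i % cfg.n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        etype = str(rng.choice(types, p=probs)) if i in as_idx else None
        lo, hi = cfg.exons_per_gene
        n_ex = int(rng.integers(lo, hi + 1))
        if etype == "ES":
            n_ex = max(n_ex, 3)
        cursor = cursors[chrom] + int(rng.integers(*cfg.gene_gap))
        exons: list[tuple[int, int]] = []
        for _ in range(n_ex):
            length = int(rng.integers(*cfg.exon_length))
            exons.append((cursor, cursor + length))
            cursor += length + int(rng.integers(*cfg.intron_length))
        cursors[chrom] = exons[-1][1]
        genes[gid] = GeneModel(gid, chrom, strand, {f"{gid}.1": list(exons)})
        fpkm[gid] = float(rng.lognormal(*cfg.fpkm_lognormal))

        if etype is None:
            continue
        introns = [(exons[k][1], exons[k + 1][0]) for k in range(n_ex - 1)]
        if etype == "IR":
            s, e = introns[int(rng.integers(len(introns)))]
            ev = ASEvent("IR", chrom, strand, (s, e), gid)
        elif etype in ("A3SS", "A5SS"):
            s, e = introns[int(rng.integers(len(introns)))]
            delta = int(rng.integers(15, 41))
            shared_at_start = (etype == "A3SS") == (strand == "+")
            if shared_at_start:
                anchors = (s, e - delta, e)
            else:
                anchors = (e, s, s + delta)
            ev = ASEvent(etype, chrom, strand, anchors, gid)
        else:  # ES
            k = int(rng.integers(1, n_ex - 1))
            es_, ee = exons[k]
            i1 = (exons[k - 1][1], es_)
            i2 = (ee, exons[k + 1][0])
            ev = ASEvent(
                "ES", chrom, strand, (i1[0], i2[1], es_, ee, *i1, *i2), gid
            )

        p = float(rng.beta(*cfg.base_freq_beta))
        shifted = bool(rng.random() < cfg.shift_fraction)
        p_by_ind = {ind: p for ind in individuals}
        if shifted and cfg.shift_dp > 0:
            p_shift = p + cfg.shift_dp if p + cfg.shift_dp <= 1.0 else p - cfg.shift_dp
            if cfg.shift_scope == "group":
                gname = str(rng.choice(sorted(cfg.groups)))
                targets = cfg.groups[gname]
            else:
                targets = [str(rng.choice(individuals))]
            for ind in targets:
                p_by_ind[ind] = p_shift
        passes = bool(rng.random() >= cfg.below_support_fraction)
        events.append(TrueEvent(ev, p_by_ind, passes, shifted))

    return genes, GroundTruth(list(individuals), dict(cfg.groups), events, fpkm)


# ---------------------------------------------------------------------------
# Statistical primitives (also used directly by calibration studies)
# ---------------------------------------------------------------------------


def simulate_event_frequencies(
    n_events: int,
    individuals: Sequence[str],
    rng: np.random.Generator,
    beta: tuple[float, float] = (2.0, 2.0),
    shift_fraction: float = 0.0,
    shift_dp: float = 0.3,
    shift_members: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """True L-frequency matrix (events x individuals) with optional shifts.

    A ``shift_fraction`` of events get their frequency moved by ``shift_dp``
    (direction chosen to stay inside [0, 1]) in the ``shift_members``
    individuals. Returns the matrix and a boolean shifted indicator.
    """
    base = rng.beta(*beta, size=n_events)
    keys = [f"E{i + 1:06d}" for i in range(n_events)]
    p = pd.DataFrame(
        np.tile(base[:, None], (1, len(individuals))),
        index=pd.Index(keys, name="event_key"),
        columns=list(individuals),
    )
    shifted = pd.Series(rng.random(n_events) < shift_fraction, index=keys, name="shifted")
    if shift_fraction > 0:
        if not shift_members:
            raise ValueError("shift_members required when shift_fraction > 0")
        delta = np.where(base + shift_dp <= 1.0, shift_dp, -shift_dp)
        for m in shift_members:
            p.loc[shifted, m] = base[shifted.to_numpy()] + delta[shifted.to_numpy()]
    return p, shifted


def _sample_depths(
    rng: np.random.Generator, mean: float, size: int, min_depth: int = 0
) -> np.ndarray:
    depths = rng.poisson(mean, size=size)
    while (low := depths < min_depth).any():
        depths[low] = rng.poisson(mean, size=int(low.sum()))
    return depths


def sample_junction_counts(
    p: pd.DataFrame,
    rng: np.random.Generator,
    depth_mean: float = 84.0,
    min_depth: int = 0,
    fixed_depth: int | None = None,
    beta_binomial_rho: float = 0.0,
) -> pd.DataFrame:
    """Draw inclusion/exclusion counts for a frequency matrix.

    Per (event, individual): n ~ Poisson(depth_mean) (optionally truncated
    below at ``min_depth``, or held constant at ``fixed_depth``), inclusion
    ~ Binomial(n, p). Returns a long quantification table compatible with
    the variation analysis.
    """
    rows = []
    for ind in p.columns:
        pv = p[ind].to_numpy(dtype=float)
        if fixed_depth is not None:
            n = np.full(len(pv), fixed_depth, dtype=int)
        else:
            n = _sample_depths(rng, depth_mean, len(pv), min_depth)
        pr = pv
        if beta_binomial_rho > 0:
            rho = beta_binomial_rho
            inner = np.clip(pv, 1e-9, 1 - 1e-9)
            a = inner * (1 - rho) / rho
            b = (1 - inner) * (1 - rho) / rho
            pr = rng.beta(a, b)
        incl = rng.binomial(n, pr)
        excl = n - incl
        for key, i, e in zip(p.index, incl, excl):
            tot = i + e
            rows.append(
                {
                    "event_key": key,
                    "individual_id": ind,
                    "inclusion_count": int(i),
                    "exclusion_count": int(e),
                    "l_frequency": float(i) / tot if tot else float("nan"),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-individual evidence emission
# ---------------------------------------------------------------------------


def _event_signature_junctions(ev: ASEvent) -> dict[str, tuple]:
    """Junction roles for emission: which keys carry incl/excl reads."""
    if ev.event_type in ("A3SS", "A5SS"):
        lj, sj = assign_long_isoform(ev)
        return {"L": lj, "S": sj}
    if ev.event_type == "ES":
        _, sj = assign_long_isoform(ev)
        i1, i2 = es_inclusion_junctions(ev)
        return {"I1": i1, "I2": i2, "S": sj}
    _, sj = assign_long_isoform(ev)  # IR: spliced junction only
    return {"S": sj}


def simulate_individual(
    genes: Mapping[str, GeneModel],
    truth: GroundTruth,
    cfg: SimulationConfig,
    individual_id: str,
) -> tuple[list[JunctionEvidence], list[tuple[str, int, int, float]], pd.DataFrame]:
    """Evidence for one individual: junctions, coverage rows, fragment counts.

    Deterministic given (cfg.seed, individual); independent of emission
    order of the other individuals.
    """
    if individual_id not in truth.individuals:
        raise KeyError(f"unknown individual {individual_id}")
    idx = truth.individuals.index(individual_id)
    rng = np.random.default_rng([cfg.seed, 1000 + idx])

    # constitutive junctions: every annotated intron
    from .genome_model import derive_introns  # local import avoids cycle at module load

    counts: dict[tuple, int] = {}
    for gid in sorted(genes):
        for intron in derive_introns(genes[gid]):
            counts[intron.key] = int(rng.poisson(cfg.junction_depth_mean))

    coverage_rows: list[tuple[str, int, int, float]] = []
    forced_low: set[tuple] = set()
    for te in truth.events:
        ev = te.event
        p = te.p_by_individual[individual_id]
        n = int(rng.poisson(cfg.event_depth_mean))
        pr = p
        if cfg.beta_binomial_rho > 0 and 0 < p < 1:
            rho = cfg.beta_binomial_rho
            pr = float(rng.beta(p * (1 - rho) / rho, (1 - p) * (1 - rho) / rho))
        incl = int(rng.binomial(n, pr)) if n else 0
        excl = n - incl
        sig = _event_signature_junctions(ev)
        if ev.event_type in ("A3SS", "A5SS"):
            counts[sig["L"]] = incl
            counts[sig["S"]] = excl
        elif ev.event_type == "ES":
            counts[sig["I1"]] = incl
            counts[sig["I2"]] = incl
            counts[sig["S"]] = excl
        else:  # IR
            counts[sig["S"]] = excl
            if incl >= 1:
                s, e = ev.anchors
                coverage_rows.append((ev.chrom, s, e, float(incl)))
        if not te.passes_support:
            # the distinguishing (novel) junction is emitted at 1 read so it
            # fails the >=2-read support filter; for IR the spliced junction
            # is capped instead, voiding the "supported by junction reads" rule
            low_key = sig["S"] if ev.event_type == "IR" else sig.get("L", sig["S"])
            if ev.event_type == "ES":
                low_key = sig["S"]
            counts[low_key] = 1
            forced_low.add(low_key)

    junctions = []
    for key in sorted(counts):
        c = counts[key]
        if c <= 0:
            continue
        chrom, strand, s, e = key
        distinct = 1 if key in forced_low else c
        junctions.append(
            JunctionEvidence(
                chrom=chrom,
                strand=strand,
                intron_start=s,
                intron_end=e,
                read_count=c,
                distinct_positions=distinct,
                min_overhang=cfg.overhang,
                individual_id=individual_id,
            )
        )

    gene_ids = sorted(genes)
    lam = np.array(
        [
            truth.fpkm[g] * genes[g].collapsed_length / 1e3 * cfg.library_size / 1e6
            for g in gene_ids
        ]
    )
    frag = rng.poisson(lam)
    counts_df = pd.DataFrame(
        {"gene_id": gene_ids, "individual_id": individual_id, "count": frag}
    )
    return junctions, sorted(coverage_rows), counts_df


# ---------------------------------------------------------------------------
# Truth round-trip + full bundle
# ---------------------------------------------------------------------------


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "version": TRUTH_VERSION,
        "individuals": truth.individuals,
        "groups": truth.groups,
        "fpkm": truth.fpkm,
        "events": [
            {
                "event_type": te.event.event_type,
                "chrom": te.event.chrom,
                "strand": te.event.strand,
                "anchors": list(te.event.anchors),
                "gene_id": te.event.gene_id,
                "p_by_individual": te.p_by_individual,
                "passes_support": te.passes_support,
                "shifted": te.shifted,
            }
            for te in truth.events
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"truth file not found: {path}")
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("version") != TRUTH_VERSION:
        raise ValueError(
            f"truth version mismatch: file has {payload.get('version')}, "
            f"expected {TRUTH_VERSION}"
        )
    events = [
        TrueEvent(
            ASEvent(
                e["event_type"],
                e["chrom"],
                e["strand"],
                tuple(e["anchors"]),
                e["gene_id"],
            ),
            {k: float(v) for k, v in e["p_by_individual"].items()},
            bool(e["passes_support"]),
            bool(e.get("shifted", False)),
        )
        for e in payload["events"]
    ]
    return GroundTruth(
        payload["individuals"], payload["groups"], events, payload["fpkm"]
    )


def simulate_bundle(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, object]:
    """Write a complete synthetic input bundle plus a ready-to-run config.

    Emits annotation.gff3, truth.json, per-individual ``<id>.junctions.tsv``
    and ``<id>.coverage.bedgraph``, fragment_counts.tsv, library_sizes.tsv
    and run.yaml; returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, truth = generate_genome(cfg)
    write_gff3(genes, out / "annotation.gff3")
    write_truth(truth, out / "truth.json")
    all_counts = []
    individuals_cfg = []
    for group, members in truth.groups.items():
        for ind in members:
            junctions, cov, counts_df = simulate_individual(genes, truth, cfg, ind)
            jpath = out / f"{ind}.junctions.tsv"
            cpath = out / f"{ind}.coverage.bedgraph"
            write_junctions(junctions, jpath)
            write_bedgraph(cov, cpath)
            all_counts.append(counts_df)
            individuals_cfg.append(
                {
                    "id": ind,
                    "group": group,
                    "junctions": jpath.name,
                    "coverage": cpath.name,
                }
            )
    counts = pd.concat(all_counts, ignore_index=True)
    counts.to_csv(out / "fragment_counts.tsv", sep="\t", header=False, index=False)
    with open(out / "library_sizes.tsv", "w") as fh:
        for ind in truth.individuals:
            fh.write(f"{ind}\t{cfg.library_size}\n")
    run_cfg = {
        "annotation": "annotation.gff3",
        "fragment_counts": "fragment_counts.tsv",
        "library_sizes": "library_sizes.tsv",
        "individuals": individuals_cfg,
        "filter": {"min_reads": 2, "min_distinct_positions": 2, "min_overhang": 4},
        "population": {"min_fpkm": 5.0, "fdr_q": 0.05, "min_shared": 15},
    }
    with open(out / "run.yaml", "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=True)
    return {
        "dir": out,
        "annotation": out / "annotation.gff3",
        "truth": out / "truth.json",
        "run_config": out / "run.yaml",
        "genes": genes,
        "truth_obj": truth,
    }
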