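"""Inter-individual AS-variation statistics.

Pipeline: restrict to events of well-expressed genes (FPKM >= 5 in every
individual), build the event x individual L-frequency matrix, compute
pairwise Spearman correlations (pairwise-complete, tie mid-ranking),
cluster individuals by average linkage on 1 - rho, and call
individual-specific splicing with per-event pairwise two-sided Fisher
exact tests on [[inclA, exclA], [inclB, exclB]] tables under
Benjamini-Hochberg FDR control.

The BH family defaults to all (event, pair) tests pooled within a
population group — the most conservative defensible reading of a single
per-group cutoff — with a per-pair family available as a config option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .as_events import ASEvent

log = logging.getLogger(__name__)


@dataclass
class PopulationConfig:
    """Population structure and variation-analysis thresholds."""

    groups: dict[str, list[str]]
    min_fpkm: float = 5.0
    fdr_q: float = 0.05
    bh_family: str = "group"  # "group" (pooled) or "pair"
    exclude: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.min_fpkm < 0:
            raise ValueError("min_fpkm must be >= 0")
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must be in (0, 1)")
        if self.bh_family not in ("group", "pair"):
            raise ValueError("bh_family must be 'group' or 'pair'")
        for name, members in self.analysis_groups.items():
            if len(members) < 2:
                raise ValueError(f"group {name!r} needs >= 2 individuals after exclusions")

    @property
    def analysis_groups(self) -> dict[str, list[str]]:
        return {
            name: [m for m in members if m not in self.exclude]
            for name, members in self.groups.items()
        }

    @property
    def individuals(self) -> list[str]:
        return [m for members in self.analysis_groups.values() for m in members]


def filter_expressed_events(
    events: Sequence[ASEvent],
    fpkm: pd.DataFrame,
    min_fpkm: float = 5.0,
    individuals: Sequence[str] | None = None,
) -> list[ASEvent]:
    """Keep events whose gene has FPKM >= min_fpkm in every individual.

    Events without a gene assignment are dropped.
    """
    cols = list(individuals) if individuals is not None else list(fpkm.columns)
    ok_genes = set(fpkm.index[(fpkm[cols] >= min_fpkm).all(axis=1)])
    kept = [e for e in events if e.gene_id is not None and e.gene_id in ok_genes]
    log.info("expression filter: %d of %d events kept", len(kept), len(events))
    return kept


def l_frequency_matrix(quants: pd.DataFrame) -> pd.DataFrame:
    """Wide event_key x individual matrix of L-frequencies (NaN undefined)."""
    return quants.pivot_table(
        index="event_key", columns="individual_id", values="l_frequency", dropna=False
    )


def spearman_matrix(lmat: pd.DataFrame, min_events: int = 2) -> pd.DataFrame:
    """Pairwise Spearman correlation over events defined in both individuals.

    Each pair is ranked on its own shared subset (pairwise-complete), with
    ties mid-ranked. Pairs with fewer than ``min_events`` shared events get
    NaN and a warning.
    """
    inds = list(lmat.columns)
    corr = pd.DataFrame(np.eye(len(inds)), index=inds, columns=inds)
    for a, b in combinations(inds, 2):
        sub = lmat[[a, b]].dropna()
        if len(sub) < min_events or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            log.warning("correlation undefined for pair (%s, %s)", a, b)
            rho = np.nan
        else:
            rho = stats.spearmanr(sub[a], sub[b]).statistic
        corr.loc[a, b] = corr.loc[b, a] = rho
    return corr


def cluster_individuals(corr: pd.DataFrame) -> tuple[np.ndarray, list[str], str]:
    """Average-linkage (UPGMA) clustering on distance 1 - rho.

    Returns the scipy linkage matrix, leaf labels, and a Newick string with
    ultrametric branch lengths (leaf height = merge height / 2).
    """
    if corr.isna().any().any():
        raise ValueError(
            "correlation matrix has undefined entries; tighten event filtering"
        )
    dist = 1.0 - corr.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = average(condensed)
    labels = list(corr.columns)
    newick = linkage_to_newick(Z, labels)
    return Z, labels, newick


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as Newick with ultrametric branch
    lengths (each node sits at half its merge distance)."""
    tree = to_tree(Z)

    def height(node) -> float:
        return 0.0 if node.is_leaf() else node.dist / 2.0

    def render(node, parent_height: float) -> str:
        bl = parent_height - height(node)
        if node.is_leaf():
            return f"{labels[node.id]}:{bl:.6g}"
        left = render(node.left, height(node))
        right = render(node.right, height(node))
        return f"({left},{right}):{bl:.6g}"

    h = height(tree)
    return f"({render(tree.left, h)},{render(tree.right, h)});"


def fisher_event_pair(
    incl_a: int, excl_a: int, incl_b: int, excl_b: int
) -> tuple[float, bool]:
    """Two-sided Fisher exact p for [[inclA, exclA], [inclB, exclB]].

    A zero row or column margin makes the table uninformative: p = 1 by
    convention, flagged degenerate.
    """
    table = np.array([[incl_a, excl_a], [incl_b, excl_b]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0, True
    return float(stats.fisher_exact(table, alternative="two-sided")[1]), False


def bh_adjust(pvalues: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment; flag iff adjusted p <= q."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj <= q


def pairwise_fisher_tests(
    quants: pd.DataFrame, individuals: Sequence[str]
) -> pd.DataFrame:
    """All per-event pairwise Fisher tests within a set of individuals.

    An event is tested for a pair only when its L-frequency is defined
    (inclusion + exclusion > 0) in both members.
    """
    cols = ["event_key", "individual_id", "inclusion_count", "exclusion_count"]
    sub = quants[quants["individual_id"].isin(individuals)][cols]
    sub = sub[(sub["inclusion_count"] + sub["exclusion_count"]) > 0]
    by_ind = {
        ind: df.set_index("event_key") for ind, df in sub.groupby("individual_id")
    }
    rows = []
    for a, b in combinations(individuals, 2):
        if a not in by_ind or b not in by_ind:
            continue
        da, db = by_ind[a], by_ind[b]
        shared = da.index.intersection(db.index)
        for key in shared:
            p, degen = fisher_event_pair(
                int(da.at[key, "inclusion_count"]),
                int(da.at[key, "exclusion_count"]),
                int(db.at[key, "inclusion_count"]),
                int(db.at[key, "exclusion_count"]),
            )
            rows.append(
                {"event_key": key, "ind_a": a, "ind_b": b, "p": p, "degenerate": degen}
            )
    return pd.DataFrame(rows, columns=["event_key", "ind_a", "ind_b", "p", "degenerate"])


def adjust_tests(
    tests: pd.DataFrame, q: float = 0.05, family: str = "group"
) -> pd.DataFrame:
    """Attach BH-adjusted p-values and significance flags to a test table."""
    tests = tests.copy()
    if tests.empty:
        tests["p_adj"] = pd.Series(dtype=float)
        tests["significant"] = pd.Series(dtype=bool)
        return tests
    if family == "group":
        p_adj, flags = bh_adjust(tests["p"].to_numpy(), q)
        tests["p_adj"], tests["significant"] = p_adj, flags
    elif family == "pair":
        parts = []
        for _, df in tests.groupby(["ind_a", "ind_b"], sort=True):
            p_adj, flags = bh_adjust(df["p"].to_numpy(), q)
            df = df.copy()
            df["p_adj"], df["significant"] = p_adj, flags
            parts.append(df)
        tests = pd.concat(parts).sort_index()
    else:
        raise ValueError("family must be 'group' or 'pair'")
    return tests


def variable_event_fraction(
    adjusted: pd.DataFrame, n_detected_events: int | None = None
) -> dict[str, float | int]:
    """Fraction of events significant in >= 1 within-group pair.

    Reports the fraction over events tested and, when supplied, over all
    detected events (both denominators, since the choice is a convention).
    """
    if adjusted.empty:
        tested, variable = 0, 0
    else:
        tested = adjusted["event_key"].nunique()
        variable = adjusted.loc[adjusted["significant"], "event_key"].nunique()
    out: dict[str, float | int] = {
        "n_events_tested": tested,
        "n_events_variable": variable,
        "fraction_of_tested": variable / tested if tested else 0.0,
    }
    if n_detected_events is not None:
        out["n_events_detected"] = n_detected_events
        out["fraction_of_detected"] = (
            variable / n_detected_events if n_detected_events else 0.0
        )
    return out


@dataclass
class VariationResult:
    """Bundle of all inter-individual variation outputs."""

    l_frequencies: pd.DataFrame  # event x individual
    correlation: pd.DataFrame
    linkage: np.ndarray
    labels: list[str]
    newick: str
    tests: pd.DataFrame  # per-event per-pair with group, p, p_adj, significant
    group_summaries: dict[str, dict[str, float | int]]


def analyze_population(
    events: Sequence[ASEvent],
    quants: pd.DataFrame,
    fpkm: pd.DataFrame,
    cfg: PopulationConfig,
) -> VariationResult:
    """Full variation analysis over expression-filtered events."""
    kept = filter_expressed_events(events, fpkm, cfg.min_fpkm, cfg.individuals)
    kept_keys = {e.key for e in kept}
    q = quants[
        quants["event_key"].isin(kept_keys)
        & quants["individual_id"].isin(cfg.individuals)
    ]
    lmat = l_frequency_matrix(q)
    lmat = lmat.reindex(columns=cfg.individuals)
    corr = spearman_matrix(lmat)
    Z, labels, newick = cluster_individuals(corr)
    all_tests = []
    summaries: dict[str, dict[str, float | int]] = {}
    for name, members in cfg.analysis_groups.items():
        t = pairwise_fisher_tests(q, members)
        t = adjust_tests(t, cfg.fdr_q, cfg.bh_family)
        t.insert(0, "group", name)
        all_tests.append(t)
        summaries[name] = variable_event_fraction(t, n_detected_events=len(kept_keys))
    tests = (
        pd.concat(all_tests, ignore_index=True)
        if all_tests
        else pd.DataFrame(
            columns=["group", "event_key", "ind_a", "ind_b", "p", "degenerate", "p_adj", "significant"]
        )
    )
    return VariationResult(lmat, corr, Z, labels, newick, tests, summaries)
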