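"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written from first principles (exhaustive enumeration,
per-base scans, textbook formulas) and deliberately shares no logic with
the package implementation it checks.
"""

from itertools import combinations

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration.

    Conditional on all margins, the top-left cell k follows a
    hypergeometric law; the two-sided p sums P(k) over every table at most
    as probable as the observed one (with a small relative tolerance for
    floating-point ties).
    """
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    pmf = {k: hypergeom.pmf(k, n, row1, col1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return float(min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7))))


def spearman_oracle(x, y) -> float:
    """Tie-corrected Spearman rho: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def midrank(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midrank(x), midrank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def bh_oracle(pvalues, q):
    """Benjamini-Hochberg by the direct max-k definition.

    Reject the k smallest p-values where k = max{i : p_(i) <= i*q/m};
    adjusted p_(i) = min over j >= i of m*p_(j)/j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = np.minimum.accumulate((m * sorted_p / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    ks = [i + 1 for i in range(m) if sorted_p[i] <= (i + 1) * q / m]
    k = max(ks) if ks else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return adj, reject


def alt_ss_oracle(junctions):
    """Orientation-explicit pairwise scan for alternative splice sites.

    For every unordered pair of same-chrom same-strand junctions sharing
    exactly one end, decide A3SS vs A5SS from which biological site (donor
    = 5' end of the intron in transcription direction) is shared.
    Returns a set of (type, chrom, strand, shared, alt_lo, alt_hi) tuples.
    """
    events = set()
    keys = sorted({(j.chrom, j.strand, j.intron_start, j.intron_end) for j in junctions})
    for (c1, s1, a1, b1), (c2, s2, a2, b2) in combinations(keys, 2):
        if c1 != c2 or s1 != s2 or s1 not in "+-":
            continue
        if a1 == a2 and b1 != b2:
            shared_site = "left"
        elif b1 == b2 and a1 != a2:
            shared_site = "right"
        else:
            continue
        if s1 == "+":
            donor_shared = shared_site == "left"
        else:
            donor_shared = shared_site == "right"
        etype = "A3SS" if donor_shared else "A5SS"
        if shared_site == "left":
            shared, alts = a1, sorted((b1, b2))
        else:
            shared, alts = b1, sorted((a1, a2))
        events.add((etype, c1, s1, shared, alts[0], alts[1]))
    return events


def es_oracle(junctions, genes):
    """Exhaustive exon-skipping scan over all (junction, transcript, exon)
    triples: a junction removing a complete internal exon is ES when both
    flanking introns are present as junctions."""
    present = {(j.chrom, j.strand, j.intron_start, j.intron_end) for j in junctions}
    events = set()
    for chrom, strand, js, je in present:
        for g in genes.values():
            if g.chrom != chrom or g.strand != strand:
                continue
            for exons in g.transcripts.values():
                for k in range(1, len(exons) - 1):
                    es, ee = exons[k]
                    if js < es and ee < je:
                        i1 = (chrom, strand, exons[k - 1][1], es)
                        i2 = (chrom, strand, ee, exons[k + 1][0])
                        if i1 in present and i2 in present:
                            events.add(
                                ("ES", chrom, strand, js, je, es, ee, *i1[2:], *i2[2:])
                            )
    return events


def ir_oracle(junctions, genes, depth_fn):
    """Per-base intron-retention scan: an intron (annotated or implied by a
    junction) is retained when its spliced junction is present and every
    single base has depth >= 1 under ``depth_fn(chrom, pos)``."""
    present = {(j.chrom, j.strand, j.intron_start, j.intron_end) for j in junctions}
    candidates = set(present)
    for g in genes.values():
        for exons in g.transcripts.values():
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 > e1:
                    candidates.add((g.chrom, g.strand, e1, s2))
    events = set()
    for chrom, strand, s, e in candidates:
        if (chrom, strand, s, e) not in present:
            continue
        if all(depth_fn(chrom, pos) >= 1 for pos in range(s, e)):
            events.add(("IR", chrom, strand, s, e))
    return events
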