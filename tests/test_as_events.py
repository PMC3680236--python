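import numpy as np
import pytest

from conftest import make_junction
from oracle_utils import alt_ss_oracle, es_oracle, ir_oracle
from splicescape.as_events import (
    ASEvent,
    build_catalog,
    conservation_summary,
    detect_alt_ss,
    detect_es,
    detect_ir,
    junction_implied_introns,
    presence_matrix,
    type_shares,
)
from splicescape.coverage import CoverageTrack
from splicescape.genome_model import GeneModel, derive_introns


class TestAltSS:
    def test_shared_donor_plus_strand_is_a3ss(self):
        js = [make_junction(start=100, end=200), make_junction(start=100, end=230)]
        (ev,) = detect_alt_ss(js)
        assert ev.event_type == "A3SS"
        assert ev.anchors == (100, 200, 230)

    def test_same_coordinates_minus_strand_is_a5ss(self):
        """On the '-' strand the shared intron start is the acceptor side,
        so the same coordinates classify as alternative 5' splice site."""
        js = [
            make_junction(start=100, end=200, strand="-"),
            make_junction(start=100, end=230, strand="-"),
        ]
        (ev,) = detect_alt_ss(js)
        assert ev.event_type == "A5SS"

    def test_three_acceptors_give_three_pairwise_events(self):
        js = [make_junction(start=100, end=e) for e in (200, 230, 260)]
        evs = detect_alt_ss(js)
        assert len(evs) == 3 and all(e.event_type == "A3SS" for e in evs)

    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_pairwise_count_is_k_choose_2(self, k):
        js = [make_junction(start=100, end=200 + 30 * i) for i in range(k)]
        assert len(detect_alt_ss(js)) == k * (k - 1) // 2

    def test_matches_orientation_explicit_oracle(self):
        """Random junction sets: events equal the exhaustive pair scan that
        resolves donor/acceptor roles explicitly per strand."""
        rng = np.random.default_rng(11)
        sites = list(range(100, 1000, 50))
        for trial in range(10):
            js = []
            for _ in range(15):
                s, e = sorted(rng.choice(sites, size=2, replace=False).tolist())
                js.append(
                    make_junction(
                        start=int(s), end=int(e), strand=str(rng.choice(["+", "-"]))
                    )
                )
            got = {
                (e.event_type, e.chrom, e.strand, *e.anchors) for e in detect_alt_ss(js)
            }
            assert got == alt_ss_oracle(js)


class TestIR:
    def _intron(self, gene):
        return derive_introns(gene)[0]  # 100-200

    def test_fully_covered_with_junction(self, three_exon_gene):
        cov = CoverageTrack({"Chr01": [(100, 200, 2.0)]})
        js = [make_junction(start=100, end=200)]
        (ev,) = detect_ir([self._intron(three_exon_gene)], js, cov)
        assert ev.event_type == "IR" and ev.anchors == (100, 200)

    def test_single_uncovered_base_blocks_event(self, three_exon_gene):
        cov = CoverageTrack({"Chr01": [(100, 150, 2.0), (151, 200, 2.0)]})
        js = [make_junction(start=100, end=200)]
        assert detect_ir([self._intron(three_exon_gene)], js, cov) == []

    def test_junction_below_filter_blocks_event(self, three_exon_gene):
        """Full coverage alone is not enough: the spliced junction must have
        passed the support filter (it is absent from the filtered set)."""
        cov = CoverageTrack({"Chr01": [(100, 200, 3.0)]})
        assert detect_ir([self._intron(three_exon_gene)], [], cov) == []

    def test_junction_implied_novel_intron_detectable(self):
        js = [make_junction(start=500, end=600)]
        cov = CoverageTrack({"Chr01": [(500, 600, 1.0)]})
        (ev,) = detect_ir(junction_implied_introns(js), js, cov)
        assert ev.anchors == (500, 600)


class TestES:
    def test_triangle_detected(self, three_exon_gene):
        js = [
            make_junction(start=100, end=200),  # inclusion E1-E2
            make_junction(start=300, end=400),  # inclusion E2-E3
            make_junction(start=100, end=400),  # exclusion spanning E2
        ]
        (ev,) = detect_es(js, {"G1": three_exon_gene})
        assert ev.event_type == "ES"
        assert ev.anchors[:4] == (100, 400, 200, 300)

    def test_missing_inclusion_junction_blocks_event(self, three_exon_gene):
        js = [
            make_junction(start=100, end=200),
            make_junction(start=100, end=400),  # exclusion, but E2->E3 absent
        ]
        assert detect_es(js, {"G1": three_exon_gene}) == []

    def test_junction_spanning_two_exons_gives_two_events(self):
        exons = [(0, 100), (200, 300), (400, 500), (600, 700)]
        g = GeneModel("G", "Chr01", "+", {"G.1": exons})
        js = [
            make_junction(start=100, end=200),
            make_junction(start=300, end=400),
            make_junction(start=500, end=600),
            make_junction(start=100, end=600),  # spans E2 and E3
        ]
        evs = detect_es(js, {"G": g})
        skipped = sorted(e.anchors[2:4] for e in evs)
        assert skipped == [(200, 300), (400, 500)]

    def test_matches_enumeration_oracle(self, toy_genes):
        """Random subsets of plausible junctions agree with the exhaustive
        triple scan."""
        rng = np.random.default_rng(13)
        pool = [
            (100, 200), (300, 400), (100, 400),      # G1 ('+')
            (1100, 1200), (1300, 1400), (1500, 1600),  # G2 introns ('-')
            (1100, 1400), (1300, 1600), (1100, 1600),
        ]
        for _ in range(15):
            chosen = [pool[i] for i in np.flatnonzero(rng.random(len(pool)) < 0.6)]
            js = []
            for s, e in chosen:
                strand = "+" if s < 1000 else "-"
                js.append(make_junction(start=s, end=e, strand=strand))
            got = {
                (ev.event_type, ev.chrom, ev.strand, *ev.anchors)
                for ev in detect_es(js, toy_genes)
            }
            assert got == es_oracle(js, toy_genes)


class TestCatalog:
    def test_empty_inputs_empty_catalog(self, toy_genes):
        cat = build_catalog("PT01", [], CoverageTrack(), toy_genes)
        assert cat.events == [] and cat.as_gene_count == 0

    def test_one_event_of_each_type(self, toy_genes):
        js = [
            # ES triangle + A3SS pair in G1 ('+'):
            make_junction(start=100, end=200),
            make_junction(start=300, end=400),
            make_junction(start=100, end=400),
            make_junction(start=300, end=380),   # A3SS with (300,400)
            # A5SS pair in G2 ('-'): shared start is acceptor side
            make_junction(start=1100, end=1200, strand="-"),
            make_junction(start=1100, end=1180, strand="-"),
        ]
        cov = CoverageTrack({"Chr01": [(1400, 1500, 1.0)]})  # G2 intron retained
        js.append(make_junction(start=1400, end=1500, strand="-"))
        cat = build_catalog("PT01", js, cov, toy_genes)
        counts = cat.type_counts
        # the ES exclusion junction also pairs with each inclusion junction
        assert counts["ES"] == 1 and counts["IR"] == 1
        assert counts["A3SS"] >= 1 and counts["A5SS"] >= 1
        assert cat.as_gene_count == 2

    def test_no_coverage_skips_ir(self, toy_genes, caplog):
        js = [make_junction(start=100, end=200)]
        with caplog.at_level("WARNING"):
            cat = build_catalog("PT01", js, None, toy_genes)
        assert "IR detection skipped" in caplog.text
        assert cat.type_counts["IR"] == 0

    def test_detection_monotone_in_evidence(self, toy_genes):
        """Adding a junction never removes an existing event."""
        rng = np.random.default_rng(17)
        pool = [
            make_junction(start=100, end=200),
            make_junction(start=300, end=400),
            make_junction(start=100, end=400),
            make_junction(start=300, end=380),
            make_junction(start=1100, end=1200, strand="-"),
            make_junction(start=1100, end=1180, strand="-"),
        ]
        cov = CoverageTrack()
        order = rng.permutation(len(pool))
        prev: set[str] = set()
        for k in range(1, len(pool) + 1):
            js = [pool[i] for i in order[:k]]
            keys = {e.key for e in build_catalog("x", js, cov, toy_genes).events}
            assert prev <= keys
            prev = keys

    def test_random_instance_equals_bruteforce_oracles(self, toy_genes):
        """Catalog on a randomized instance equals the union of the three
        unoptimized oracle scans (pairs, triples, per-base intron scan)."""
        rng = np.random.default_rng(19)
        js = []
        # plausible junctions around G1/G2 plus random noise junctions
        anchors = [100, 200, 300, 380, 400, 1100, 1180, 1200, 1300, 1400, 1500, 1600]
        for _ in range(40):
            s, e = sorted(rng.choice(anchors, size=2, replace=False).tolist())
            if s == e:
                continue
            strand = str(rng.choice(["+", "-"]))
            js.append(make_junction(start=int(s), end=int(e), strand=strand))
        js = list({j.key: j for j in js}.values())
        ivs = []
        cursor = 80
        while cursor < 1700:
            cursor += int(rng.integers(0, 120))
            end = cursor + int(rng.integers(20, 200))
            ivs.append((cursor, end, float(rng.integers(1, 4))))
            cursor = end
        cov = CoverageTrack({"Chr01": ivs})
        cat = build_catalog("x", js, cov, toy_genes)
        got = {(e.event_type, e.chrom, e.strand, *e.anchors) for e in cat.events}
        expected = alt_ss_oracle(js) | es_oracle(js, toy_genes) | ir_oracle(
            js, toy_genes, cov.depth
        )
        assert got == expected

    def test_keys_deterministic(self, toy_genes):
        js = [make_junction(start=100, end=e) for e in (200, 230)]
        k1 = [e.key for e in build_catalog("x", js, CoverageTrack(), toy_genes).events]
        k2 = [e.key for e in build_catalog("x", js, CoverageTrack(), toy_genes).events]
        assert k1 == k2


class TestPresenceConservation:
    def _catalogs(self, presence, types):
        from splicescape.as_events import EventCatalog

        n_ind = presence.shape[1]
        inds = [f"I{k}" for k in range(n_ind)]
        def anchors_for(t, i):
            base = int(i) * 100
            if t == "IR":
                return (base, base + 50)
            if t in ("A3SS", "A5SS"):
                return (base, base + 30, base + 50)
            return (base, base + 90, base + 30, base + 60,
                    base, base + 30, base + 60, base + 90)

        catalogs = []
        for k, ind in enumerate(inds):
            evs = []
            for i in np.flatnonzero(presence[:, k]):
                evs.append(ASEvent(types[i], "c", "+", anchors_for(types[i], i)))
            catalogs.append(EventCatalog(ind, evs))
        return catalogs

    def test_single_individual_all_in_bin_one(self):
        presence = np.ones((4, 1), dtype=bool)
        cats = self._catalogs(presence, ["IR"] * 4)
        mat, types = presence_matrix(cats)
        summary = conservation_summary(mat, types, min_shared=1).set_index("event_type")
        assert summary.loc["Total", "n_in_1"] == 4

    def test_random_fixture_matches_tally(self):
        rng = np.random.default_rng(23)
        presence = rng.random((30, 4)) < 0.5
        presence[presence.sum(axis=1) == 0, 0] = True
        types = [str(t) for t in rng.choice(["IR", "A3SS", "A5SS", "ES"], size=30)]
        cats = self._catalogs(presence, types)
        mat, tmap = presence_matrix(cats)
        summary = conservation_summary(mat, tmap, min_shared=3).set_index("event_type")
        counts = presence.sum(axis=1)
        # brute-force tally per type
        for t in ["IR", "A3SS", "A5SS", "ES"]:
            sel = np.array([ty == t for ty in types])
            assert summary.loc[t, "n_events"] == int(sel.sum())
            assert summary.loc[t, "n_in_1"] == int((counts[sel] == 1).sum())
            assert summary.loc[t, "n_in_ge_3"] == int((counts[sel] >= 3).sum())
            assert summary.loc[t, "n_in_4"] == int((counts[sel] == 4).sum())
        assert summary.loc["Total", "n_events"] == 30

    def test_type_shares_sum_to_hundred(self):
        df = type_shares({"IR": 3, "A3SS": 1}).set_index("event_type")
        assert df.loc["Total", "n_events"] == 4
        assert df["share_pct"][:-1].sum() == pytest.approx(100.0)
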