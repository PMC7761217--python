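"""Feature construction, overlap annotation, nearest genes — with brute-force oracles."""

import numpy as np
import pytest

from twindiff.annotation import (
    PromoterDefinition,
    build_cgi_shores,
    build_promoter_cgis,
    build_promoters,
    classify_location,
    nearest_gene,
    overlap_sites,
    summarize_feature_counts,
)
from twindiff.model import FeatureTrack, GeneModel, GenomicInterval, ThresholdConfig

CFG = ThresholdConfig()


def ft(name, spans, chrom="chr1"):
    return FeatureTrack(name, [GenomicInterval(chrom, s, e) for s, e in spans])


class TestPromoters:
    def test_plus_strand_window(self):
        g = GeneModel("g", "A", "chr1", 10_000, 20_000, "+")
        (iv,) = build_promoters([g]).intervals
        assert (iv.start, iv.end) == (9500, 12_000)

    def test_minus_strand_mirror(self):
        g = GeneModel("g", "A", "chr1", 2_000, 10_000, "-")  # tss 9999
        (iv,) = build_promoters([g]).intervals
        assert (iv.start, iv.end) == (8_000, 10_500)

    def test_clipped_at_chromosome_start(self):
        g = GeneModel("g", "A", "chr1", 100, 5_000, "+")
        (iv,) = build_promoters([g]).intervals
        assert iv.start == 0

    def test_alternate_orientation_swaps_extents(self):
        pdef = PromoterDefinition.from_orientation("minus2k_plus500")
        g = GeneModel("g", "A", "chr1", 10_000, 20_000, "+")
        (iv,) = build_promoters([g], pdef).intervals
        assert (iv.start, iv.end) == (8_000, 10_500)

    def test_overlapping_promoters_not_merged(self):
        genes = [
            GeneModel("g1", "A", "chr1", 10_000, 12_000, "+"),
            GeneModel("g2", "B", "chr1", 10_500, 13_000, "+"),
        ]
        track = build_promoters(genes)
        assert len(track) == 2
        assert {iv.label for iv in track} == {"A", "B"}


class TestShores:
    def test_single_island_flanks(self):
        shores = build_cgi_shores(ft("cgi", [(5000, 6000)]), CFG)
        assert [(i.start, i.end) for i in shores] == [(3000, 5000), (6000, 8000)]

    def test_inter_island_gap_is_shore_but_islands_are_not(self):
        shores = build_cgi_shores(ft("cgi", [(5000, 6000), (6500, 7000)]), CFG)
        spans = [(i.start, i.end) for i in shores]
        assert (6000, 6500) in spans
        for sh in shores:  # no shore base inside either island
            assert sh.overlap_length(GenomicInterval("chr1", 5000, 6000)) == 0
            assert sh.overlap_length(GenomicInterval("chr1", 6500, 7000)) == 0

    def test_island_at_chromosome_start_has_no_left_shore(self):
        shores = build_cgi_shores(ft("cgi", [(0, 500)]), CFG)
        assert [(i.start, i.end) for i in shores] == [(500, 2500)]

    def test_shores_never_intersect_islands_random(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = rng.integers(1, 15)
            starts = rng.integers(0, 50_000, size=n)
            cgis = ft("cgi", [(int(s), int(s + rng.integers(100, 2000))) for s in starts])
            shores = build_cgi_shores(cgis, CFG)
            for sh in shores:
                for c in cgis:
                    assert sh.overlap_length(c) == 0


class TestPromoterCgis:
    @pytest.mark.parametrize(
        "prom,cgi,expected",
        [
            ([(9500, 12_000)], [(11_000, 13_000)], [(11_000, 12_000)]),
            ([(9500, 12_000)], [(20_000, 21_000)], []),
            ([(9500, 12_000)], [(10_000, 11_000)], [(10_000, 11_000)]),
        ],
    )
    def test_intersection_cases(self, prom, cgi, expected):
        out = build_promoter_cgis(ft("promoter", prom), ft("cgi", cgi))
        assert [(i.start, i.end) for i in out] == expected

    def test_result_subset_of_both_parents(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            proms = ft("promoter", [(int(s), int(s) + 2500) for s in rng.integers(0, 30_000, 5)])
            cgis = ft("cgi", [(int(s), int(s) + 800) for s in rng.integers(0, 30_000, 5)])
            inter = build_promoter_cgis(proms, cgis)
            for iv in inter:
                assert sum(iv.overlap_length(p) for p in proms) >= len(iv)
                assert sum(iv.overlap_length(c) for c in cgis) >= len(iv)


class TestOverlapSites:
    TRACKS = [
        ft("promoter", [(9500, 12_000)]),
        ft("tfbs", [(9600, 9630), (30_000, 30_020)]),
        ft("cardiac_tfbs", [(9600, 9630)]),
    ]

    def test_one_bp_hit_and_half_open_miss(self):
        sites = [
            GenomicInterval("chr1", 9500, 9501),
            GenomicInterval("chr1", 12_000, 12_001),
        ]
        hit, miss = overlap_sites(sites, self.TRACKS)
        assert "promoter" in hit.feature_hits
        assert miss.feature_hits == set()

    def test_composite_labels_require_both_parents(self):
        inside = overlap_sites([GenomicInterval("chr1", 9610, 9611)], self.TRACKS)[0]
        outside = overlap_sites([GenomicInterval("chr1", 30_010, 30_011)], self.TRACKS)[0]
        assert {"tfbs_in_promoter", "cardiac_tfbs_in_promoter"} <= inside.feature_hits
        assert "tfbs_in_promoter" not in outside.feature_hits


class TestNearestGene:
    GENES = [
        GeneModel("g1", "A", "chr1", 1000, 2000, "+"),
        GeneModel("g2", "B", "chr1", 2350, 3000, "+"),
    ]

    def test_overlap_is_distance_zero(self):
        assert nearest_gene(GenomicInterval("chr1", 1500, 1501), self.GENES) == [("A", 0)]

    def test_minimal_gap_wins_with_sign(self):
        # site 100 bp right of A's end, 250 bp left of B's start
        out = nearest_gene(GenomicInterval("chr1", 2099, 2100), self.GENES)
        assert out == [("A", -100)]

    def test_ties_return_all_genes(self):
        out = nearest_gene(GenomicInterval("chr1", 2174, 2176), self.GENES)
        assert {g for g, _ in out} == {"A", "B"}

    def test_no_gene_on_chromosome_unassigned(self):
        assert nearest_gene(GenomicInterval("chr9", 10, 11), self.GENES) == []


class TestLocation:
    GENE = GeneModel("g", "A", "chr1", 1000, 5000, "+", exons=((1000, 1500), (4000, 5000)))

    @pytest.mark.parametrize(
        "pos,expected", [(1200, "exonic"), (2000, "intronic"), (9000, "intergenic")]
    )
    def test_precedence(self, pos, expected):
        assert classify_location(GenomicInterval("chr1", pos, pos + 1), [self.GENE]) == expected

    def test_gene_without_blocks_is_all_exonic(self):
        g = GeneModel("g", "A", "chr1", 1000, 5000, "+")
        assert classify_location(GenomicInterval("chr1", 2000, 2001), [g]) == "exonic"


def test_summary_three_hand_annotated_sites():
    tracks = [
        ft("promoter", [(9500, 12_000)]),
        ft("cgi", [(11_000, 13_000)]),
        ft("promoter_cgi", [(11_000, 12_000)]),
        ft("cgi_shore", [(9000, 11_000)]),
    ]
    sites = [
        GenomicInterval("chr1", 11_500, 11_501),  # promoter + CGI + promoter-CGI
        GenomicInterval("chr1", 10_000, 10_001),  # promoter + shore
        GenomicInterval("chr1", 50_000, 50_001),  # nothing
    ]
    counts = summarize_feature_counts(overlap_sites(sites, tracks))
    assert counts["total"] == 3
    assert counts["promoter"] == 2
    assert counts["cgi"] == 1
    assert counts["promoter_cgi"] == 1
    assert counts["cgi_shore"] == 1


# ---------------------------------------------------------------------------
# Brute-force oracles on random instances
# ---------------------------------------------------------------------------


def _random_track(rng, name, n, max_coord=20_000, max_len=2000):
    spans = []
    for _ in range(n):
        s = int(rng.integers(0, max_coord))
        spans.append((s, s + int(rng.integers(1, max_len))))
    return ft(name, spans)


def test_overlap_agrees_with_quadratic_scan():
    """Tree-based annotation equals an O(n*m) all-pairs scan, 100 instances."""
    rng = np.random.default_rng(77)
    for _ in range(100):
        tracks = [
            _random_track(rng, name, int(rng.integers(0, 12)))
            for name in ("promoter", "cgi", "tfbs", "enhancer")
        ]
        sites = [
            GenomicInterval("chr1", int(p), int(p) + 1)
            for p in rng.integers(0, 22_000, size=int(rng.integers(1, 60)))
        ]
        fast = overlap_sites(sites, tracks)
        for ann in fast:
            brute = {
                t.name
                for t in tracks
                for iv in t
                if iv.start < ann.site.end and ann.site.start < iv.end
            }
            if {"tfbs", "promoter"} <= brute:
                brute.add("tfbs_in_promoter")
            assert ann.feature_hits == brute


def _base_set(track, limit):
    s = set()
    for iv in track:
        s.update(range(iv.start, min(iv.end, limit)))
    return s


def test_shore_and_intersection_agree_with_per_base_sets():
    """Shore construction and promoter-CGI intersection vs per-base set arithmetic."""
    rng = np.random.default_rng(101)
    LIMIT = 12_000
    for _ in range(100):
        cgis = _random_track(rng, "cgi", int(rng.integers(1, 8)), max_coord=8000, max_len=800)
        proms = _random_track(rng, "promoter", int(rng.integers(1, 6)), max_coord=8000, max_len=2500)

        shores = build_cgi_shores(cgis, CFG)
        cgi_bases = _base_set(cgis, LIMIT)
        flank_bases = set()
        for iv in cgis:
            flank_bases.update(range(max(0, iv.start - 2000), iv.start))
            flank_bases.update(range(iv.end, min(iv.end + 2000, LIMIT)))
        assert _base_set(shores, LIMIT) == flank_bases - cgi_bases

        inter = build_promoter_cgis(proms, cgis)
        assert _base_set(inter, LIMIT) == _base_set(proms, LIMIT) & cgi_bases


def test_summary_agrees_with_brute_force_on_500_sites():
    rng = np.random.default_rng(55)
    tracks = [
        _random_track(rng, name, 40)
        for name in ("promoter", "cgi", "promoter_cgi", "cgi_shore", "tfbs",
                     "cardiac_tfbs", "enhancer")
    ]
    sites = [
        GenomicInterval("chr1", int(p), int(p) + 1)
        for p in rng.integers(0, 22_000, size=500)
    ]
    counts = summarize_feature_counts(overlap_sites(sites, tracks))
    brute = {key: 0 for key in counts}
    brute["total"] = len(sites)
    for s in sites:
        hits = {
            t.name for t in tracks for iv in t if iv.start < s.end and s.start < iv.end
        }
        if {"tfbs", "promoter"} <= hits:
            hits.add("tfbs_in_promoter")
        if {"cardiac_tfbs", "promoter"} <= hits:
            hits.add("cardiac_tfbs_in_promoter")
        for h in hits:
            if h in brute:
                brute[h] += 1
    assert counts == brute
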