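"""Interval arithmetic against a per-base brute-force oracle, and the
catalogue construction filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from etg3d.regions import (
    EnhancerCatalogue,
    GeneAnnotation,
    Interval,
    Peak,
    build_catalogue,
    classify_tss_proximal,
    define_promoters,
    ep_distance,
    filter_by_size,
    filter_peaks,
    intersect_sets,
    jaccard,
    merge_union,
    select_upstream_tss,
    subtract_exons,
)

GENOME_BP = 100_000  # toy chromosome for the bit-vector oracle


def _bitvec(intervals, chrom="chr1"):
    v = np.zeros(GENOME_BP, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            v[iv.start : iv.end] = True
    return v


def _random_intervals(rng, n):
    starts = rng.integers(0, GENOME_BP - 200, size=n)
    lengths = rng.integers(1, 400, size=n)
    return [Interval("chr1", int(s), int(min(s + l, GENOME_BP))) for s, l in zip(starts, lengths)]


class TestIntervalInvariants:
    def test_rejects_empty_and_negative(self):
        with pytest.raises(ValueError):
            Interval("chr1", 10, 10)
        with pytest.raises(ValueError):
            Interval("chr1", -1, 5)
        with pytest.raises(ValueError):
            Interval("", 0, 5)

    def test_midpoint_floor(self):
        assert Interval("chr1", 0, 101).mid == 50


class TestPeakFilter:
    @pytest.mark.parametrize(
        "q,kept", [(4.9, False), (5.0, True), (5.1, True), (0.0, False)]
    )
    def test_boundary_inclusive(self, q, kept):
        peaks = [Peak(Interval("chr1", 0, 100), q)]
        assert (len(filter_peaks(peaks, 5.0)) == 1) is kept

    def test_empty_and_order(self):
        assert filter_peaks([], 5.0) == []
        peaks = [Peak(Interval("chr1", i * 10, i * 10 + 5), 6.0) for i in range(5)]
        assert filter_peaks(peaks, 5.0) == peaks


class TestSetOperations:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([(100, 1000)], [(900, 1300)], [(900, 1000)]),
            ([(0, 10)], [(10, 20)], []),  # half-open: no shared base
            ([(0, 100)], [(0, 100)], [(0, 100)]),
        ],
    )
    def test_intersect_examples(self, a, b, expected):
        ia = [Interval("chr1", s, e) for s, e in a]
        ib = [Interval("chr1", s, e) for s, e in b]
        assert [(i.start, i.end) for i in intersect_sets(ia, ib)] == expected

    @pytest.mark.parametrize(
        "region,exon,expected",
        [
            ((900, 1000), (950, 980), [(900, 950), (980, 1000)]),  # internal split
            ((900, 1000), (850, 1100), []),  # fully exonic
            ((900, 1000), (2000, 3000), [(900, 1000)]),  # untouched
        ],
    )
    def test_subtract_exons_examples(self, region, exon, expected):
        out = subtract_exons(
            [Interval("chr1", *region)], [Interval("chr1", *exon)]
        )
        assert [(i.start, i.end) for i in out] == expected

    def test_merge_union_examples(self):
        out = merge_union([[Interval("chr1", 0, 10)], [Interval("chr1", 5, 15)]])
        assert [(i.start, i.end) for i in out] == [(0, 15)]

    @pytest.mark.parametrize("seed", range(5))
    def test_bitvector_oracle(self, seed):
        """intersect/union/subtract cover exactly the per-base truth."""
        rng = np.random.default_rng(seed)
        a, b = _random_intervals(rng, 30), _random_intervals(rng, 30)
        assert (_bitvec(intersect_sets(a, b)) == (_bitvec(a) & _bitvec(b))).all()
        assert (_bitvec(merge_union([a, b])) == (_bitvec(a) | _bitvec(b))).all()
        assert (_bitvec(subtract_exons(a, b)) == (_bitvec(a) & ~_bitvec(b))).all()

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        a=st.lists(
            st.tuples(st.integers(0, 990), st.integers(1, 200)), min_size=1, max_size=15
        ),
        b=st.lists(
            st.tuples(st.integers(0, 990), st.integers(1, 200)), min_size=1, max_size=15
        ),
    )
    def test_property_per_base_equivalence(self, a, b):
        ia = [Interval("chr1", s, min(s + l, 1000)) for s, l in a]
        ib = [Interval("chr1", s, min(s + l, 1000)) for s, l in b]
        va = _bitvec(ia)[:1000]
        vb = _bitvec(ib)[:1000]
        assert (_bitvec(intersect_sets(ia, ib))[:1000] == (va & vb)).all()
        assert (_bitvec(merge_union([ia, ib]))[:1000] == (va | vb)).all()
        assert (_bitvec(subtract_exons(ia, ib))[:1000] == (va & ~vb)).all()

    def test_subtract_then_filter_idempotent(self, rng):
        a, b = _random_intervals(rng, 40), _random_intervals(rng, 10)
        once = filter_by_size(subtract_exons(a, b))
        twice = filter_by_size(subtract_exons(once, b))
        assert once == twice


class TestSizeFilter:
    @pytest.mark.parametrize(
        "length,kept",
        [(8, False), (9, False), (10, True), (2500, True), (2501, False), (2600, False)],
    )
    def test_boundaries(self, length, kept):
        out = filter_by_size([Interval("chr1", 0, length)])
        assert (len(out) == 1) is kept


class TestPromoters:
    def test_strand_aware_windows(self):
        plus = GeneAnnotation("A", "chr1", 10_000, "+")
        minus = GeneAnnotation("B", "chr2", 10_000, "-")
        ps = define_promoters([plus, minus])
        by_chrom = {iv.chrom: iv for iv, _ in ps.promoters}
        assert (by_chrom["chr1"].start, by_chrom["chr1"].end) == (8500, 10500)
        assert (by_chrom["chr2"].start, by_chrom["chr2"].end) == (9500, 11500)

    def test_close_tsses_merge_with_both_symbols(self):
        genes = [
            GeneAnnotation("A", "chr1", 10_000, "+"),
            GeneAnnotation("B", "chr1", 10_400, "-"),
        ]
        ps = define_promoters(genes)
        assert ps.m == 1
        iv, syms = ps.promoters[0]
        assert syms == {"A", "B"}
        assert (iv.start, iv.end) == (8500, 11900)  # union of member windows

    def test_merge_is_transitive(self):
        genes = [
            GeneAnnotation(s, "chr1", 10_000 + i * 450, "+") for i, s in enumerate("ABC")
        ]
        assert define_promoters(genes).m == 1

    def test_most_upstream_tss(self):
        plus = [GeneAnnotation("A", "chr1", t, "+") for t in (5000, 4000, 6000)]
        minus = [GeneAnnotation("B", "chr1", t, "-") for t in (5000, 9000)]
        sel = {g.symbol: g.tss for g in select_upstream_tss(plus + minus)}
        assert sel == {"A": 4000, "B": 9000}

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError):
            GeneAnnotation("A", "chr1", 100, ".")


class TestProximalClassification:
    def test_window_membership(self):
        genes = [GeneAnnotation("A", "chr1", 10_000, "+")]  # window [6500, 11500)
        regions = [
            Interval("chr1", 9000, 9100),     # inside
            Interval("chr1", 50_000, 50_100),  # far
            Interval("chr1", 6400, 6501),      # touches by exactly 1 bp
            Interval("chr1", 6400, 6500),      # bookended, no shared base
        ]
        assert classify_tss_proximal(regions, genes) == [
            "proximal", "distal", "proximal", "distal",
        ]


class TestJaccard:
    def test_coverage_example(self):
        a, b = [Interval("chr1", 0, 10)], [Interval("chr1", 5, 15)]
        assert jaccard(a, b, "coverage") == pytest.approx(5 / 15)

    @pytest.mark.parametrize("mode", ["coverage", "overlap"])
    def test_identity_and_disjoint(self, mode):
        a = [Interval("chr1", 0, 10), Interval("chr1", 100, 150)]
        b = [Interval("chr1", 500, 600)]
        assert jaccard(a, a, mode) == 1.0
        assert jaccard(a, b, mode) == 0.0

    def test_symmetry_and_range(self, rng):
        a, b = _random_intervals(rng, 25), _random_intervals(rng, 25)
        for mode in ("coverage", "overlap"):
            ja, jb = jaccard(a, b, mode), jaccard(b, a, mode)
            assert ja == pytest.approx(jb)
            assert 0.0 <= ja <= 1.0

    def test_asymmetric_reference_variant(self):
        a = [Interval("chr1", 0, 10), Interval("chr1", 100, 110)]
        b = [Interval("chr1", 5, 8)]
        assert jaccard(a, b, "overlap", reference="a") == 0.5
        assert jaccard(a, b, "overlap", reference="b") == 1.0

    def test_both_empty_signalled(self):
        with pytest.raises(ValueError):
            jaccard([], [], "coverage")


class TestEpDistance:
    @pytest.mark.parametrize(
        "e,p,expected",
        [((0, 100), (900, 1100), 950), ((0, 10), (0, 10), 0)],
    )
    def test_examples(self, e, p, expected):
        assert ep_distance(Interval("chr1", *e), Interval("chr1", *p)) == expected

    def test_cross_chromosome_error(self):
        with pytest.raises(ValueError):
            ep_distance(Interval("chr1", 0, 10), Interval("chr2", 0, 10))


def _toy_inputs():
    exon = Interval("chr1", 30_000, 30_100)
    genes = [GeneAnnotation("G1", "chr1", 50_000, "+", (exon,))]
    cells = []
    for shift in (0, 120, 240):
        ac = [
            Peak(Interval("chr1", 20_000 + shift, 20_900 + shift), 9.0),
            Peak(Interval("chr1", 29_900, 30_600), 9.0),   # straddles the exon
            Peak(Interval("chr1", 48_000, 48_500), 9.0),   # promoter-proximal
            Peak(Interval("chr1", 70_000, 70_400), 2.0),   # weak, filtered
        ]
        dhs = [
            Peak(Interval("chr1", 20_100 + shift, 20_600 + shift), 8.0),
            Peak(Interval("chr1", 29_900, 30_600), 8.0),
            Peak(Interval("chr1", 48_000, 48_500), 8.0),
            Peak(Interval("chr1", 70_000, 70_400), 8.0),
        ]
        cells.append((ac, dhs))
    return [c[0] for c in cells], [c[1] for c in cells], genes


class TestBuildCatalogue:
    def test_invariants_on_fixture(self):
        ac, dhs, genes = _toy_inputs()
        cat = build_catalogue(ac, dhs, genes)
        assert cat.n > 0
        exon = genes[0].exons[0]
        for e in cat.enhancers:
            assert 10 <= len(e) <= 2500
            assert not (e.start < exon.end and exon.start < e.end)
            # distal: outside [TSS-3500, TSS+1500)
            assert e.end <= 46_500 or e.start >= 51_500

    def test_cell_type_order_insensitive(self):
        ac, dhs, genes = _toy_inputs()
        cat1 = build_catalogue(ac, dhs, genes)
        cat2 = build_catalogue(ac[::-1], dhs[::-1], genes)
        assert cat1.enhancers == cat2.enhancers

    def test_weak_peaks_excluded(self):
        ac, dhs, genes = _toy_inputs()
        cat = build_catalogue(ac, dhs, genes)
        assert all(not (70_000 <= e.start < 70_400) for e in cat.enhancers)
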