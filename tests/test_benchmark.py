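"""Reference-support annotation and performance metrics."""

import math

import numpy as np
import pandas as pd
import pytest

from etg3d.benchmark import (
    MetricReport,
    annotate_chic,
    annotate_eqtl,
    filter_fulco,
    filter_gasperini,
    fold_enrichment_vs_window,
    harmonize_external_predictions,
    metrics,
    pr_curve,
)
from etg3d.regions import GeneAnnotation, Interval


class TestMetrics:
    def test_worked_example(self):
        cand = set(range(100))
        truth = {0, 1, 2, 3}
        pred = set(range(10))
        rep = metrics({0, 1, 50, 51, 52, 53, 54, 55, 56, 57}, cand, truth)
        assert (rep.Z, rep.V, rep.z, rep.v) == (100, 4, 10, 2)
        assert rep.precision == pytest.approx(0.2)
        assert rep.recall == pytest.approx(0.5)
        assert rep.f1 == pytest.approx(2 * 0.2 * 0.5 / 0.7)
        assert rep.ri == pytest.approx(5.0)

    def test_identities(self, rng):
        for _ in range(20):
            cand = set(range(int(rng.integers(10, 60))))
            truth = set(rng.choice(len(cand), size=max(1, len(cand) // 5), replace=False).tolist())
            pred = set(rng.choice(len(cand), size=max(1, len(cand) // 3), replace=False).tolist())
            rep = metrics(pred, cand, truth)
            if rep.z and rep.V:
                assert rep.ri * (rep.V / rep.Z) == pytest.approx(rep.precision)
                if rep.precision + rep.recall > 0:
                    assert rep.f1 == pytest.approx(
                        2 * rep.precision * rep.recall / (rep.precision + rep.recall)
                    )

    def test_undefined_components_are_nan(self):
        rep = metrics(set(), {1, 2}, set())
        assert math.isnan(rep.precision) and math.isnan(rep.recall)

    def test_truths_outside_universe_ignored(self):
        rep = metrics({1}, {1, 2}, {1, 99})
        assert rep.V == 1 and rep.v == 1

    def test_prediction_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            metrics({99}, {1, 2}, set())

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            MetricReport(Z=10, V=2, z=3, v=4)


class TestAnnotateEqtl:
    def _pairs(self):
        return [
            (Interval("chr1", 400, 600), {"GENEA"}),
            (Interval("chr1", 400, 600), {"OTHER"}),
            (Interval("chr1", 2000, 2100), {"GENEA"}),
        ]

    def test_snp_in_enhancer_targeting_gene(self):
        eqtl = pd.DataFrame({"chrom": ["chr1"], "pos": [500], "gene": ["GeneA"]})
        assert annotate_eqtl(self._pairs(), eqtl).tolist() == [True, False, False]

    def test_redundant_snps_count_once_flag_unchanged(self):
        eqtl = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [450, 500, 550], "gene": ["GENEA"] * 3}
        )
        assert annotate_eqtl(self._pairs(), eqtl).tolist() == [True, False, False]

    def test_snp_one_bp_outside(self):
        eqtl = pd.DataFrame({"chrom": ["chr1"], "pos": [600], "gene": ["GENEA"]})
        assert annotate_eqtl(self._pairs(), eqtl).tolist() == [False, False, False]


class TestAnnotateChic:
    def setup_method(self):
        self.enh = Interval("chr1", 10_000, 10_500)
        self.prom = Interval("chr1", 50_000, 52_000)

    def test_bait_other_end_and_vice_versa(self):
        fwd = [(Interval("chr1", 51_999, 53_000), Interval("chr1", 9000, 11_000), 6.0)]
        rev = [(Interval("chr1", 9000, 11_000), Interval("chr1", 51_999, 53_000), 6.0)]
        assert annotate_chic([(self.enh, self.prom)], fwd).tolist() == [True]
        assert annotate_chic([(self.enh, self.prom)], rev).tolist() == [True]

    def test_both_elements_on_bait_only(self):
        inter = [(Interval("chr1", 9000, 53_000), Interval("chr2", 0, 1000), 6.0)]
        assert annotate_chic([(self.enh, self.prom)], inter).tolist() == [False]

    def test_shared_interaction_supports_all_pairs(self):
        enh2 = Interval("chr1", 10_600, 10_900)
        inter = [(Interval("chr1", 50_000, 52_000), Interval("chr1", 9000, 11_000), 6.0)]
        out = annotate_chic([(self.enh, self.prom), (enh2, self.prom)], inter)
        assert out.tolist() == [True, True]


def _fulco_synthetic():
    # synthetic stand-in exercising every filter rule
    return pd.DataFrame(
        {
            "class": ["distal", "promoter", "distal", "distal"],
            "adjusted_pvalue": [0.04, 0.01, 0.06, 0.04],
            "power": [0.85, 0.9, 0.9, 0.7],
        }
    )


def _gasperini_synthetic():
    return pd.DataFrame(
        {
            "class": ["DHS", "TSS", "NTC", "DHS", "DHS", "DHS"],
            "quality_control": ["top_two", "top_two", "top_two", "bottom", "top_two", "top_two"],
            "adjusted_empirical_pvalue": [0.05, 0.05, 0.05, 0.05, np.nan, 0.2],
        }
    )


class TestCrisprFilters:
    def test_fulco_rules(self):
        out = filter_fulco(_fulco_synthetic())
        assert len(out) == 3  # promoter row dropped
        assert out["validated"].tolist() == [True, False, False]

    def test_fulco_missing_column_named(self):
        with pytest.raises(ValueError, match="power"):
            filter_fulco(_fulco_synthetic().drop(columns=["power"]))

    def test_gasperini_rules(self):
        out = filter_gasperini(_gasperini_synthetic())
        # survivors: rows 0 and 5 (DHS, top_two, p present)
        assert len(out) == 2
        assert out["validated"].tolist() == [True, False]

    def test_gasperini_missing_column_named(self):
        with pytest.raises(ValueError, match="quality_control"):
            filter_gasperini(_gasperini_synthetic().drop(columns=["quality_control"]))


class TestPrCurve:
    def test_perfect_ranking(self):
        truth = {0, 1, 2}
        curve = pr_curve([0, 1, 2, 3, 4], truth)
        assert curve.precision.iloc[:3].tolist() == [1.0, 1.0, 1.0]
        assert curve.recall.iloc[2] == 1.0

    def test_inverted_ranking(self):
        truth = {3, 4}
        curve = pr_curve([0, 1, 2, 3, 4], truth)
        assert curve.precision.iloc[:3].tolist() == [0.0, 0.0, 0.0]

    def test_final_point_and_monotone_recall(self, rng):
        cand = list(range(50))
        truth = set(rng.choice(50, size=10, replace=False).tolist())
        ranked = list(rng.permutation(cand))
        curve = pr_curve(ranked, truth)
        assert curve.precision.iloc[-1] == pytest.approx(10 / 50)
        assert curve.recall.iloc[-1] == 1.0
        assert (np.diff(curve.recall) >= 0).all()


class TestFoldEnrichment:
    def test_arithmetic(self):
        hc = set(range(100))
        win = set(range(200))
        truth = set(range(10))
        assert fold_enrichment_vs_window(hc, win, truth) == pytest.approx(2.0)

    def test_identical_sets_give_one(self):
        s = set(range(50))
        assert fold_enrichment_vs_window(s, s, {1, 2}) == 1.0

    def test_zero_denominator_signalled(self):
        with pytest.raises(ValueError):
            fold_enrichment_vs_window({1}, {2}, {1})


class TestHarmonize:
    def _genes(self):
        exon = Interval("chr1", 10_200, 10_400)
        return [GeneAnnotation("G1", "chr1", 100_000, "+", (exon,))]

    def test_internal_exon_splits_and_duplicates(self):
        pairs = [(Interval("chr1", 10_000, 10_600), "G1")]
        out, dropped = harmonize_external_predictions(pairs, self._genes())
        assert dropped == 0
        assert [(iv.start, iv.end) for iv, _ in out] == [(10_000, 10_200), (10_400, 10_600)]

    @pytest.mark.parametrize("mid,kept", [(97_001, False), (97_000, True)])
    def test_proximity_boundary(self, mid, kept):
        # enhancer of length 200 centred at `mid`; TSS at 100_000
        enh = Interval("chr1", mid - 100, mid + 100)
        out, _ = harmonize_external_predictions([(enh, "G1")], self._genes())
        assert (len(out) == 1) is kept

    def test_unmapped_gene_counted(self):
        pairs = [(Interval("chr1", 10_000, 10_100), "NOSUCH")]
        out, dropped = harmonize_external_predictions(pairs, self._genes())
        assert out == [] and dropped == 1
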