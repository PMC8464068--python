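"""Benchmarking of predicted enhancer-target gene pairs.

Reference support comes from four kinds of evidence: eQTL SNP-gene
associations (a pair is supported when a SNP inside the enhancer targets a
gene of the promoter), capture Hi-C interactions (promoter on the bait and
enhancer on the other end, or vice versa, >=1 bp overlap), CRISPR
perturbation screens (element-gene pairs with study-specific validation
filters), and curated benchmark pair lists with a binary truth flag.

Performance is summarized by the candidate/truth counts Z, V, z, v and the
derived precision v/z, recall v/V, F1, and relative improvement
RI = (v/z)/(V/Z) (precision over the base rate; 1 = random selection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .regions import (
    EnhancerCatalogue,
    GeneAnnotation,
    Interval,
    PromoterSet,
    ep_distance,
    subtract_exons,
)

__all__ = [
    "MetricReport",
    "annotate_eqtl",
    "annotate_chic",
    "filter_fulco",
    "filter_gasperini",
    "metrics",
    "pr_curve",
    "fold_enrichment_vs_window",
    "harmonize_external_predictions",
]


@dataclass(frozen=True)
class MetricReport:
    """Counts and derived indices for one predictor against one truth set."""

    Z: int
    V: int
    z: int
    v: int

    def __post_init__(self) -> None:
        if not (self.v <= min(self.z, self.V) and self.z <= self.Z and self.V <= self.Z):
            raise ValueError(f"inconsistent counts Z={self.Z} V={self.V} z={self.z} v={self.v}")

    @property
    def precision(self) -> float:
        return self.v / self.z if self.z else math.nan

    @property
    def recall(self) -> float:
        return self.v / self.V if self.V else math.nan

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if math.isnan(p) or math.isnan(r) or p + r == 0:
            return math.nan
        return 2 * p * r / (p + r)

    @property
    def ri(self) -> float:
        base = self.V / self.Z if self.Z else math.nan
        p = self.precision
        if math.isnan(p) or not base or math.isnan(base):
            return math.nan
        return p / base


def annotate_eqtl(
    pairs: Sequence[tuple[Interval, frozenset[str] | set[str]]],
    eqtls: pd.DataFrame,
) -> np.ndarray:
    """Support flag per (enhancer interval, promoter gene symbols) pair.

    ``eqtls`` needs columns chrom, pos, gene.  A pair is supported iff at
    least one SNP lies inside the enhancer and targets one of the
    promoter's genes; redundant SNPs (same enhancer, same gene — including
    the same eQTL reported across tissues) count once, which cannot change
    the binary flag.
    """
    need = {"chrom", "pos", "gene"} - set(eqtls.columns)
    if need:
        raise ValueError(f"eQTL table missing columns {sorted(need)}")
    snp = eqtls.drop_duplicates(subset=["chrom", "pos", "gene"])
    genes_upper = snp["gene"].str.upper()
    out = np.zeros(len(pairs), dtype=bool)
    by_chrom = {
        c: (g["pos"].to_numpy(), genes_upper[g.index].to_numpy())
        for c, g in snp.groupby("chrom")
    }
    for i, (enh, syms) in enumerate(pairs):
        if enh.chrom not in by_chrom:
            continue
        pos, gene = by_chrom[enh.chrom]
        inside = (pos >= enh.start) & (pos < enh.end)
        if not inside.any():
            continue
        targets = {s.upper() for s in syms}
        out[i] = bool(targets & set(gene[inside]))
    return out


def _overlaps(a: Interval, b: Interval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def annotate_chic(
    pairs: Sequence[tuple[Interval, Interval]],
    interactions: Sequence[tuple[Interval, Interval, float]],
) -> np.ndarray:
    """Support per (enhancer, promoter) pair from bait/other-end fragments.

    A pair is supported iff for some interaction the promoter overlaps
    (>=1 bp) the bait and the enhancer the other end, or vice versa.
    Interactions are assumed pre-filtered for significance upstream.
    """
    out = np.zeros(len(pairs), dtype=bool)
    for i, (enh, prom) in enumerate(pairs):
        for bait, other, _ in interactions:
            if (_overlaps(prom, bait) and _overlaps(enh, other)) or (
                _overlaps(enh, bait) and _overlaps(prom, other)
            ):
                out[i] = True
                break
    return out


def filter_fulco(records: pd.DataFrame) -> pd.DataFrame:
    """CRISPRi-FlowFISH element-gene screen: candidates and validated flags.

    Drops elements classified 'promoter'; a candidate is validated iff its
    adjusted p-value is below 0.05 and the power to detect a 25% effect is
    at least 0.8.  Expects columns ``class``, ``adjusted_pvalue``, ``power``.
    """
    need = {"class", "adjusted_pvalue", "power"} - set(records.columns)
    if need:
        raise ValueError(f"missing columns {sorted(need)}")
    out = records.loc[records["class"].str.lower() != "promoter"].copy()
    out["validated"] = (out["adjusted_pvalue"] < 0.05) & (out["power"] >= 0.8)
    return out


def filter_gasperini(records: pd.DataFrame) -> pd.DataFrame:
    """At-scale gRNA-gene screen: candidates and validated flags.

    Keeps DHS-associated gRNAs only (drops classes TSS, selfTSS, NTC,
    positive_ctrl), requires quality_control == 'top_two' and a non-missing
    adjusted empirical p-value; validated iff that p-value <= 0.1.
    """
    need = {"class", "quality_control", "adjusted_empirical_pvalue"} - set(
        records.columns
    )
    if need:
        raise ValueError(f"missing columns {sorted(need)}")
    drop = {"tss", "selftss", "ntc", "positive_ctrl"}
    out = records.loc[~records["class"].str.lower().isin(drop)].copy()
    out = out.loc[out["quality_control"] == "top_two"]
    out = out.loc[out["adjusted_empirical_pvalue"].notna()].copy()
    out["validated"] = out["adjusted_empirical_pvalue"] <= 0.1
    return out


def metrics(pred: set, candidates: set, truth: set) -> MetricReport:
    """Counts Z, V, z, v for a predicted subset of a candidate universe.

    Truths outside the candidate universe do not count toward V.
    """
    if not pred <= candidates:
        raise ValueError("predictions must be a subset of the candidate universe")
    V = len(truth & candidates)
    v = len(truth & pred)
    return MetricReport(Z=len(candidates), V=V, z=len(pred), v=v)


def pr_curve(
    ranked: Sequence[object],
    truth: set,
) -> pd.DataFrame:
    """Precision/recall at every cutoff of a ranked candidate list.

    ``ranked`` must already be sorted best-first by the chosen key
    (ascending distance or p-value, descending score or correlation); ties
    keep the caller's stable order.  Recall is non-decreasing along the
    curve and the final point is (V/Z, 1) when V > 0.
    """
    flags = np.array([c in truth for c in ranked])
    tp = np.cumsum(flags)
    cut = np.arange(1, len(ranked) + 1)
    V = flags.sum()
    return pd.DataFrame(
        {
            "cutoff": cut,
            "precision": tp / cut,
            "recall": tp / V if V else np.full(len(ranked), np.nan),
        }
    )


def fold_enrichment_vs_window(
    hc_candidates: set, window_candidates: set, truth: set
) -> float:
    """Validated fraction among TAD-based candidates over fixed-window ones.

    Values above 1 mean the TAD-hierarchy pairing concentrates reference
    support better than a fixed distance window of the given half-width.
    """
    if not hc_candidates or not window_candidates:
        raise ValueError("both candidate sets must be non-empty")
    num = len(truth & hc_candidates) / len(hc_candidates)
    den = len(truth & window_candidates) / len(window_candidates)
    if den == 0:
        raise ValueError("no validated pairs among fixed-window candidates")
    return num / den


def harmonize_external_predictions(
    pairs: Sequence[tuple[Interval, str]],
    genes: Sequence[GeneAnnotation],
    min_distance_bp: int = 3000,
) -> tuple[list[tuple[Interval, str]], int]:
    """Clean an external tool's pair list for comparison against ours.

    Exonic portions are subtracted from every enhancer — an exon strictly
    inside splits the enhancer and duplicates the pair per fragment — and
    pairs whose enhancer-midpoint-to-TSS distance falls below
    ``min_distance_bp`` are dropped as promoter-proximal.  Pairs naming an
    unknown gene symbol are dropped; their count is returned alongside.
    """
    by_symbol = {g.symbol.upper(): g for g in genes}
    exons = sorted(
        {e for g in genes for e in g.exons}, key=lambda e: (e.chrom, e.start, e.end)
    )
    out: list[tuple[Interval, str]] = []
    n_unmapped = 0
    for enh, symbol in pairs:
        gene = by_symbol.get(symbol.upper())
        if gene is None:
            n_unmapped += 1
            continue
        for frag in subtract_exons([enh], exons):
            if frag.chrom != gene.chrom:
                continue
            tss_point = Interval(gene.chrom, gene.tss, gene.tss + 1)
            if ep_distance(frag, tss_point) >= min_distance_bp:
                out.append((frag, gene.symbol))
    return out, n_unmapped
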