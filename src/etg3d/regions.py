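"""Genomic-interval arithmetic and reference enhancer/promoter construction.

The enhancer catalogue is built from cell-type-specific peak calls in two
steps: per cell type, accessible acetylated chromatin is defined as the
base-pair intersection of H3K27ac and DNase peaks (>=1 bp overlap); the
per-cell-type sets are then merged (union) across cell types, cleaned of
exonic portions, size-filtered and restricted to promoter-distal elements.
Promoters are strand-aware windows around the most upstream TSS of each
gene, merged when TSSes lie within +/-500 bp of each other.

All coordinates are 0-based half-open; "overlap" always means at least one
shared base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

__all__ = [
    "Interval",
    "Peak",
    "GeneAnnotation",
    "EnhancerCatalogue",
    "PromoterSet",
    "filter_peaks",
    "intersect_sets",
    "subtract_exons",
    "filter_by_size",
    "merge_union",
    "select_upstream_tss",
    "define_promoters",
    "classify_tss_proximal",
    "jaccard",
    "ep_distance",
    "build_catalogue",
    "CANONICAL_CHROMS",
]

#: autosomes + chrX; chrY and non-canonical contigs are excluded upstream
CANONICAL_CHROMS = frozenset({f"chr{i}" for i in range(1, 23)} | {"chrX"})


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic region, 0-based half-open, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def mid(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A peak call with its -log10 adjusted p-value."""

    interval: Interval
    neglog10_q: float

    def __post_init__(self) -> None:
        if self.neglog10_q < 0:
            raise ValueError("neglog10_q must be >= 0")


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: symbol, reference TSS, strand and (merged) exons."""

    symbol: str
    chrom: str
    tss: int
    strand: str
    exons: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.symbol}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass
class EnhancerCatalogue:
    """Disjoint enhancer intervals with stable ids 1..n."""

    enhancers: list[Interval]

    @property
    def n(self) -> int:
        return len(self.enhancers)

    def ids(self) -> range:
        return range(1, self.n + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "enh_id": np.arange(1, self.n + 1),
                "chrom": [e.chrom for e in self.enhancers],
                "start": [e.start for e in self.enhancers],
                "end": [e.end for e in self.enhancers],
            }
        )


@dataclass
class PromoterSet:
    """Disjoint promoter intervals, each mapping to >=1 gene symbol."""

    promoters: list[tuple[Interval, frozenset[str]]]

    @property
    def m(self) -> int:
        return len(self.promoters)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "prom_id": np.arange(1, self.m + 1),
                "chrom": [p.chrom for p, _ in self.promoters],
                "start": [p.start for p, _ in self.promoters],
                "end": [p.end for p, _ in self.promoters],
                "genes": [",".join(sorted(g)) for _, g in self.promoters],
            }
        )


# ---------------------------------------------------------------------------
# pyranges bridge

def _to_ranges(intervals: Iterable[Interval]) -> pr.PyRanges:
    ivs = list(intervals)
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [i.chrom for i in ivs],
                "Start": [i.start for i in ivs],
                "End": [i.end for i in ivs],
            }
        )
    )


def _from_ranges(g: pr.PyRanges) -> list[Interval]:
    if g.empty:
        return []
    df = g.df.sort_values(["Chromosome", "Start", "End"])
    return [
        Interval(str(c), int(s), int(e))
        for c, s, e in zip(df.Chromosome, df.Start, df.End)
    ]


# ---------------------------------------------------------------------------
# core operations

def filter_peaks(peaks: Sequence[Peak], min_score: float = 5.0) -> list[Peak]:
    """Keep peaks with -log10(adjusted p) >= ``min_score`` (boundary kept)."""
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    return [p for p in peaks if p.neglog10_q >= min_score]


def intersect_sets(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Base-pair intersection of two interval sets (>=1 bp overlap)."""
    if not a or not b:
        return []
    return _from_ranges(_to_ranges(a).set_intersect(_to_ranges(b)))


def subtract_exons(
    regions: Sequence[Interval], exons: Sequence[Interval]
) -> list[Interval]:
    """Remove exonic portions; an internal exon splits the region in two."""
    if not regions:
        return []
    if not exons:
        return sorted(regions, key=lambda i: (i.chrom, i.start, i.end))
    return _from_ranges(_to_ranges(regions).subtract(_to_ranges(exons)))


def filter_by_size(
    regions: Sequence[Interval], min_bp: int = 10, max_bp: int = 2500
) -> list[Interval]:
    """Keep intervals with min_bp <= length <= max_bp (both boundaries kept)."""
    if min_bp > max_bp:
        raise ValueError("min_bp must be <= max_bp")
    return [r for r in regions if min_bp <= len(r) <= max_bp]


def merge_union(sets: Sequence[Sequence[Interval]]) -> list[Interval]:
    """Union of interval sets; overlapping (and bookended) intervals merge."""
    if not sets:
        raise ValueError("need at least one input set")
    flat = [iv for s in sets for iv in s]
    if not flat:
        return []
    return _from_ranges(_to_ranges(flat).merge())


def select_upstream_tss(genes: Sequence[GeneAnnotation]) -> list[GeneAnnotation]:
    """Collapse alternative transcripts to the most upstream TSS per symbol.

    Most upstream is the minimum coordinate on '+' and the maximum on '-';
    exon sets of all transcripts of the gene are pooled.
    """
    by_symbol: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_symbol.setdefault(g.symbol, []).append(g)
    out = []
    for symbol, grp in by_symbol.items():
        strand = grp[0].strand
        if any(g.strand != strand or g.chrom != grp[0].chrom for g in grp):
            raise ValueError(f"gene {symbol}: inconsistent chrom/strand across transcripts")
        tss = min(g.tss for g in grp) if strand == "+" else max(g.tss for g in grp)
        exons = tuple(
            sorted({e for g in grp for e in g.exons}, key=lambda e: (e.start, e.end))
        )
        out.append(GeneAnnotation(symbol, grp[0].chrom, tss, strand, exons))
    return sorted(out, key=lambda g: (g.chrom, g.tss, g.symbol))


def _tss_window(g: GeneAnnotation, up_bp: int, down_bp: int) -> Interval:
    if g.strand == "+":
        start, end = g.tss - up_bp, g.tss + down_bp
    else:
        start, end = g.tss - down_bp, g.tss + up_bp
    return Interval(g.chrom, max(0, start), end)


def define_promoters(
    genes: Sequence[GeneAnnotation],
    up_bp: int = 1500,
    down_bp: int = 500,
    merge_radius: int = 500,
) -> PromoterSet:
    """Strand-aware TSS windows, merged when TSSes fall within the radius.

    Merging is transitive: a chain of TSSes each within ``merge_radius`` of a
    neighbour collapses into one promoter spanning the union of the member
    windows and carrying every member's gene symbol.
    """
    genes = select_upstream_tss(genes)
    promoters: list[tuple[Interval, frozenset[str]]] = []
    for chrom in sorted({g.chrom for g in genes}):
        chrom_genes = sorted(
            (g for g in genes if g.chrom == chrom), key=lambda g: g.tss
        )
        cluster: list[GeneAnnotation] = []
        for g in chrom_genes:
            if cluster and g.tss - cluster[-1].tss > merge_radius:
                promoters.append(_close_cluster(cluster, up_bp, down_bp))
                cluster = []
            cluster.append(g)
        if cluster:
            promoters.append(_close_cluster(cluster, up_bp, down_bp))
    return PromoterSet(promoters)


def _close_cluster(
    cluster: list[GeneAnnotation], up_bp: int, down_bp: int
) -> tuple[Interval, frozenset[str]]:
    windows = [_tss_window(g, up_bp, down_bp) for g in cluster]
    iv = Interval(
        cluster[0].chrom,
        min(w.start for w in windows),
        max(w.end for w in windows),
    )
    return iv, frozenset(g.symbol for g in cluster)


def classify_tss_proximal(
    regions: Sequence[Interval],
    genes: Sequence[GeneAnnotation],
    up_bp: int = 3500,
    down_bp: int = 1500,
) -> list[str]:
    """Label each region 'proximal' iff it overlaps (>=1 bp) any TSS window."""
    if not regions:
        return []
    genes = select_upstream_tss(genes)
    windows = [_tss_window(g, up_bp, down_bp) for g in genes]
    if not windows:
        return ["distal"] * len(regions)
    win = _to_ranges(windows)
    hits = set()
    reg_df = pd.DataFrame(
        {
            "Chromosome": [r.chrom for r in regions],
            "Start": [r.start for r in regions],
            "End": [r.end for r in regions],
            "idx": np.arange(len(regions)),
        }
    )
    ov = pr.PyRanges(reg_df).overlap(win)
    if not ov.empty:
        hits = set(ov.df["idx"].tolist())
    return ["proximal" if i in hits else "distal" for i in range(len(regions))]


def jaccard(
    a: Sequence[Interval],
    b: Sequence[Interval],
    mode: Literal["overlap", "coverage"] = "coverage",
    reference: Literal["both", "a", "b"] = "both",
) -> float:
    """Jaccard index between two internally merged interval sets.

    coverage mode: intersected bases / union bases.  overlap mode: elements of
    either set overlapping the other, over the total element count; with
    ``reference='a'`` (or ``'b'``) the asymmetric per-row variant — the
    fraction of that set's elements overlapping the other set.
    """
    if not a and not b:
        raise ValueError("jaccard undefined for two empty sets")
    if not a or not b:
        return 0.0
    ga, gb = _to_ranges(a).merge(), _to_ranges(b).merge()
    if mode == "coverage":
        inter = ga.set_intersect(gb)
        union = ga.set_union(gb)
        ibp = 0 if inter.empty else int(inter.lengths().sum())
        ubp = int(union.lengths().sum())
        return ibp / ubp
    na = len(ga.overlap(gb))
    nb = len(gb.overlap(ga))
    if reference == "a":
        return na / len(ga)
    if reference == "b":
        return nb / len(gb)
    return (na + nb) / (len(ga) + len(gb))


def ep_distance(e: Interval, p: Interval) -> int:
    """Midpoint-to-midpoint distance; errors across chromosomes."""
    if e.chrom != p.chrom:
        raise ValueError(f"inter-chromosomal pair: {e.chrom} vs {p.chrom}")
    return abs(e.mid - p.mid)


# ---------------------------------------------------------------------------
# pipeline

def build_catalogue(
    h3k27ac: Sequence[Sequence[Peak]],
    dhs: Sequence[Sequence[Peak]],
    genes: Sequence[GeneAnnotation],
    min_qscore: float = 5.0,
    min_len: int = 10,
    max_len: int = 2500,
    proximal_up: int = 3500,
    proximal_down: int = 1500,
    canonical_only: bool = True,
) -> EnhancerCatalogue:
    """Build the reference enhancer catalogue from per-cell-type peak calls.

    ``h3k27ac`` and ``dhs`` are parallel lists of peak sets, one pair per
    cell type.  Per cell type: significant H3K27ac and DNase peaks are
    intersected at base-pair level, exonic portions removed, and sizes
    filtered; the per-cell-type enhancers are then merged across cell types
    and only promoter-distal elements are retained.
    """
    if len(h3k27ac) != len(dhs):
        raise ValueError("need one H3K27ac and one DHS peak set per cell type")
    exons = sorted(
        {e for g in genes for e in g.exons}, key=lambda e: (e.chrom, e.start, e.end)
    )
    per_cell: list[list[Interval]] = []
    for ac_peaks, dhs_peaks in zip(h3k27ac, dhs):
        ac = [p.interval for p in filter_peaks(ac_peaks, min_qscore)]
        dh = [p.interval for p in filter_peaks(dhs_peaks, min_qscore)]
        if canonical_only:
            ac = [i for i in ac if i.chrom in CANONICAL_CHROMS]
            dh = [i for i in dh if i.chrom in CANONICAL_CHROMS]
        enh = intersect_sets(ac, dh)
        enh = subtract_exons(enh, exons)
        enh = filter_by_size(enh, min_len, max_len)
        per_cell.append(enh)
    merged = merge_union(per_cell) if any(per_cell) else []
    labels = classify_tss_proximal(merged, genes, proximal_up, proximal_down)
    distal = [iv for iv, lab in zip(merged, labels) if lab == "distal"]
    return EnhancerCatalogue(distal)
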