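"""Hierarchical Contact (HC) score for enhancer-promoter co-localization.

A TAD ensemble is one segmentation of the genome at one hierarchy level
(DI-window ``w``) from one Hi-C dataset.  For each ensemble, a sparse binary
co-occurrence matrix M_D(w) records whether enhancer i and promoter j fall
in the same TAD.  Per dataset, levels are combined as

    S^(D) = sum_{w in W} lambda(w) * M_D(w)

with lambda(w) = sqrt(max(W)/w) under the default scheme, so the coarsest
level carries weight one and finer (smaller, more specific) TADs weigh
more.  The full score S sums S^(D) over datasets.  With the default window
set [5, 10, 20, 50] the per-dataset maximum is sum(lambda) ~ 7.98 and, over
11 datasets, max(S) ~ 87.8; pairs never sharing a TAD score 0 (stored
sparsely as absent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import EnhancerCatalogue, Interval, PromoterSet, ep_distance

__all__ = [
    "TadEnsemble",
    "WeightScheme",
    "CoOccurrence",
    "HCScoreTable",
    "lambda_weight",
    "co_occurrence",
    "score_dataset",
    "score_total",
    "filter_candidates",
    "compute_hc_table",
    "DEFAULT_WINDOWS",
]

DEFAULT_WINDOWS: tuple[int, ...] = (5, 10, 20, 50)

Scheme = Literal["sqrt", "unit", "linear", "log10", "inverse"]


@dataclass(frozen=True)
class WeightScheme:
    """Window set and scaling-factor family for the per-level weights."""

    W: tuple[int, ...] = DEFAULT_WINDOWS
    scheme: Scheme = "sqrt"

    def __post_init__(self) -> None:
        if not self.W or any(w <= 0 for w in self.W):
            raise ValueError("windows must be positive")

    @property
    def max_per_dataset(self) -> float:
        """Largest attainable S^(D): a pair within one TAD at every level."""
        return sum(lambda_weight(w, self) for w in self.W)


def lambda_weight(w: int, ws: WeightScheme) -> float:
    """Per-level scaling factor lambda(w) under the scheme of ``ws``."""
    if w not in ws.W:
        raise ValueError(f"window {w} not in scheme windows {ws.W}")
    wmax = max(ws.W)
    if ws.scheme == "sqrt":
        return math.sqrt(wmax / w)
    if ws.scheme == "unit":
        return 1.0
    if ws.scheme == "linear":
        return wmax / w
    if ws.scheme == "log10":
        return math.log10(wmax / w)
    if ws.scheme == "inverse":
        return 1.0 / w
    raise ValueError(f"unknown scheme {ws.scheme!r}")


@dataclass
class TadEnsemble:
    """TAD calls from one Hi-C dataset at one DI-window."""

    dataset_id: str
    window: int
    tads: list[Interval]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Interval]] = {}
        for t in self.tads:
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, tads in by_chrom.items():
            tads.sort(key=lambda t: t.start)
            for a, b in zip(tads, tads[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"{self.dataset_id} w={self.window}: overlapping TADs on {chrom}"
                    )


@dataclass
class CoOccurrence:
    dataset_id: str
    window: int
    pairs: set[tuple[int, int]]


@dataclass
class HCScoreTable:
    """Sparse (enhancer_id, promoter_id) -> S map; absent pairs score 0."""

    scores: dict[tuple[int, int], float]
    per_dataset: dict[str, dict[tuple[int, int], float]] | None = None

    def to_frame(
        self, cat: EnhancerCatalogue | None = None, prom: PromoterSet | None = None
    ) -> pd.DataFrame:
        rows = sorted(self.scores.items())
        df = pd.DataFrame(
            {
                "enh_id": [k[0] for k, _ in rows],
                "prom_id": [k[1] for k, _ in rows],
                "hc_score": [v for _, v in rows],
            }
        )
        if cat is not None:
            df["chrom"] = [cat.enhancers[i - 1].chrom for i in df["enh_id"]]
        return df


def _assign_to_tads(
    elements: Sequence[Interval],
    tads: Sequence[Interval],
    rule: Literal["midpoint", "containment"],
) -> np.ndarray:
    """Element -> TAD index (or -1), per chromosome via sorted search."""
    out = np.full(len(elements), -1, dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, Interval]]] = {}
    for ti, t in enumerate(tads):
        by_chrom.setdefault(t.chrom, []).append((ti, t))
    for chrom, items in by_chrom.items():
        items.sort(key=lambda it: it[1].start)
        starts = np.array([t.start for _, t in items])
        ends = np.array([t.end for _, t in items])
        tidx = np.array([ti for ti, _ in items])
        idx = [i for i, e in enumerate(elements) if e.chrom == chrom]
        if not idx:
            continue
        if rule == "midpoint":
            pos = np.array([elements[i].mid for i in idx])
            j = np.searchsorted(starts, pos, side="right") - 1
            ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        else:
            s = np.array([elements[i].start for i in idx])
            e = np.array([elements[i].end for i in idx])
            j = np.searchsorted(starts, s, side="right") - 1
            ok = (j >= 0) & (e <= ends[np.clip(j, 0, None)])
        out[np.array(idx)[ok]] = tidx[j[ok]]
    return out


def co_occurrence(
    cat: EnhancerCatalogue,
    prom: PromoterSet,
    ens: TadEnsemble,
    rule: Literal["midpoint", "containment"] = "midpoint",
) -> CoOccurrence:
    """Pairs (enh_id, prom_id) assigned to the same TAD of the ensemble.

    Under the default rule an element belongs to a TAD iff its midpoint does;
    ``containment`` requires the full interval inside the TAD.  Elements in
    boundary gaps belong to no TAD and contribute no pairs.
    """
    e_tad = _assign_to_tads(cat.enhancers, ens.tads, rule)
    p_tad = _assign_to_tads([iv for iv, _ in prom.promoters], ens.tads, rule)
    by_tad: dict[int, list[int]] = {}
    for j, t in enumerate(p_tad):
        if t >= 0:
            by_tad.setdefault(int(t), []).append(j + 1)
    pairs: set[tuple[int, int]] = set()
    for i, t in enumerate(e_tad):
        if t >= 0:
            for pj in by_tad.get(int(t), ()):
                pairs.add((i + 1, pj))
    return CoOccurrence(ens.dataset_id, ens.window, pairs)


def score_dataset(
    cos: Sequence[CoOccurrence], ws: WeightScheme
) -> dict[tuple[int, int], float]:
    """S^(D): per-pair sum of lambda(w) over the levels where it co-occurs."""
    if len(cos) != len(set(c.window for c in cos)):
        raise ValueError("duplicate windows in co-occurrence list")
    missing = set(ws.W) - {c.window for c in cos}
    if missing:
        raise ValueError(f"missing co-occurrence for windows {sorted(missing)}")
    datasets = {c.dataset_id for c in cos}
    if len(datasets) != 1:
        raise ValueError(f"expected one dataset, got {sorted(datasets)}")
    scores: dict[tuple[int, int], float] = {}
    for c in cos:
        lw = lambda_weight(c.window, ws)
        for pair in c.pairs:
            scores[pair] = scores.get(pair, 0.0) + lw
    return scores


def score_total(
    per_dataset: Mapping[str, dict[tuple[int, int], float]],
    keep_components: bool = False,
) -> HCScoreTable:
    """HC score S: element-wise sum of S^(D) across datasets."""
    if not per_dataset:
        raise ValueError("need at least one dataset")
    total: dict[tuple[int, int], float] = {}
    for comp in per_dataset.values():
        for pair, s in comp.items():
            total[pair] = total.get(pair, 0.0) + s
    return HCScoreTable(total, dict(per_dataset) if keep_components else None)


def compute_hc_table(
    cat: EnhancerCatalogue,
    prom: PromoterSet,
    ensembles: Iterable[TadEnsemble],
    ws: WeightScheme = WeightScheme(),
    rule: Literal["midpoint", "containment"] = "midpoint",
    keep_components: bool = False,
) -> HCScoreTable:
    """Full HC computation from raw TAD ensembles (grouped by dataset)."""
    by_dataset: dict[str, list[CoOccurrence]] = {}
    for ens in ensembles:
        by_dataset.setdefault(ens.dataset_id, []).append(
            co_occurrence(cat, prom, ens, rule)
        )
    per_dataset = {d: score_dataset(cos, ws) for d, cos in sorted(by_dataset.items())}
    return score_total(per_dataset, keep_components)


def filter_candidates(
    table: HCScoreTable,
    min_score: float = 11.0,
    max_distance_bp: int | None = None,
    cat: EnhancerCatalogue | None = None,
    prom: PromoterSet | None = None,
) -> list[tuple[int, int]]:
    """Candidate pairs with S strictly above ``min_score``.

    Pairs at or below the cutoff are poorly supported across the TAD
    hierarchy ensemble and are discarded before testing.  When
    ``max_distance_bp`` is given (e.g. 1 Mb for eQTL comparisons) more
    distant pairs are dropped too, which requires the catalogue and
    promoter set for midpoint distances.
    """
    pairs = [p for p, s in table.scores.items() if s > min_score]
    if max_distance_bp is not None:
        if cat is None or prom is None:
            raise ValueError("distance filter needs the catalogue and promoter set")
        pairs = [
            (i, j)
            for i, j in pairs
            if ep_distance(cat.enhancers[i - 1], prom.promoters[j - 1][0])
            <= max_distance_bp
        ]
    return sorted(pairs)
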