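"""Enhancer/promoter activity quantification and normalization.

Activity of a region in a cell type is the maximum fold-change enrichment of
a mark over the region.  Enrichments are log2(x+1) transformed and
quantile-normalized across cell types within each chromosome block, per
mark, which makes the per-cell-type distributions identical while keeping
the original value range.  The normalized matrices are assembled into the
per-pair feature blocks used by the canonical-correlation test: enhancers
carry DNase + H3K27ac (p = 2), promoters DNase + H3K27ac + H3K4me3 (q = 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .regions import Interval

__all__ = [
    "FeatureTensor",
    "ENHANCER_MARKS",
    "PROMOTER_MARKS",
    "region_max_signal",
    "region_max_signal_bigwig",
    "log2p1",
    "quantile_normalize",
    "quantile_normalize_by_chrom",
    "assemble_features",
]

ENHANCER_MARKS: tuple[str, ...] = ("DHS", "H3K27ac")
PROMOTER_MARKS: tuple[str, ...] = ("DHS", "H3K27ac", "H3K4me3")


@dataclass
class FeatureTensor:
    """Per-element activity blocks with a shared cell-type axis.

    ``X[i]`` is the k x p matrix of the enhancer with id ``enh_ids[i]``;
    ``Y[j]`` the k x q matrix of promoter ``prom_ids[j]``.  Column order is
    fixed: (DHS, H3K27ac) for X and (DHS, H3K27ac, H3K4me3) for Y.
    """

    X: np.ndarray  # n_enh x k x p
    Y: np.ndarray  # n_prom x k x q
    enh_ids: np.ndarray
    prom_ids: np.ndarray
    cell_types: list[str]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    def enhancer(self, enh_id: int) -> np.ndarray:
        idx = np.flatnonzero(self.enh_ids == enh_id)
        if idx.size == 0:
            raise KeyError(f"enhancer {enh_id} not in tensor")
        return self.X[idx[0]]

    def promoter(self, prom_id: int) -> np.ndarray:
        idx = np.flatnonzero(self.prom_ids == prom_id)
        if idx.size == 0:
            raise KeyError(f"promoter {prom_id} not in tensor")
        return self.Y[idx[0]]


def region_max_signal(
    track: Mapping[str, Sequence[tuple[int, int, float]]],
    regions: Sequence[Interval],
) -> np.ndarray:
    """Per-region maximum of a step-function track.

    ``track`` maps chromosome -> (start, end, value) blocks, the in-memory
    form of a bedGraph/bigWig; uncovered bases count as 0.  A region on a
    chromosome absent from the track gets 0 with a warning.
    """
    out = np.zeros(len(regions))
    blocks: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, bl in track.items():
        arr = sorted(bl)
        blocks[chrom] = (
            np.array([b[0] for b in arr]),
            np.array([b[1] for b in arr]),
            np.array([b[2] for b in arr], dtype=float),
        )
    missing = set()
    for i, r in enumerate(regions):
        if r.chrom not in blocks:
            missing.add(r.chrom)
            continue
        starts, ends, vals = blocks[r.chrom]
        lo = np.searchsorted(ends, r.start, side="right")
        hi = np.searchsorted(starts, r.end, side="left")
        if hi <= lo:
            continue
        v = vals[lo:hi]
        covered = np.minimum(ends[lo:hi], r.end) - np.maximum(starts[lo:hi], r.start)
        v = v[covered > 0]
        gap = covered.sum() < len(r)  # any uncovered base contributes 0
        out[i] = max(v.max(initial=0.0), 0.0) if gap else v.max(initial=0.0)
    if missing:
        warnings.warn(f"regions on chromosomes absent from track: {sorted(missing)}")
    return out


def region_max_signal_bigwig(path: str, regions: Sequence[Interval]) -> np.ndarray:
    """Per-region maximum signal from a bigWig file (requires pyBigWig)."""
    import pyBigWig

    out = np.zeros(len(regions))
    missing = set()
    with pyBigWig.open(path) as bw:
        chrom_sizes = bw.chroms()
        for i, r in enumerate(regions):
            if r.chrom not in chrom_sizes:
                missing.add(r.chrom)
                continue
            end = min(r.end, chrom_sizes[r.chrom])
            if end <= r.start:
                continue
            val = bw.stats(r.chrom, r.start, end, type="max")[0]
            out[i] = 0.0 if val is None else max(float(val), 0.0)
    if missing:
        warnings.warn(f"regions on chromosomes absent from track: {sorted(missing)}")
    return out


def log2p1(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("enrichment values must be non-negative")
    return np.log2(values + 1.0)


def quantile_normalize(mat: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns to the mean-of-sorted reference.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; ties within a column receive the average of their target
    quantiles (average ranks).
    """
    mat = np.asarray(mat, dtype=float)
    n, k = mat.shape
    if n < 2 or k < 2:
        return mat.copy()
    ref = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    for c in range(k):
        ranks = rankdata(mat[:, c], method="average")  # 1..n, ties averaged
        out[:, c] = np.interp(ranks, np.arange(1, n + 1), ref)
    return out


def quantile_normalize_by_chrom(
    df: pd.DataFrame, chrom_of: Mapping[object, str] | pd.Series
) -> pd.DataFrame:
    """Apply quantile normalization within each chromosome's row block."""
    if df.shape[1] < 2:
        raise ValueError("need >=2 cell-type columns")
    chrom = pd.Series({rid: chrom_of[rid] for rid in df.index})
    out = df.copy().astype(float)
    for _, idx in df.index.groupby(chrom.values).items():
        block = df.loc[idx]
        out.loc[idx] = quantile_normalize(block.to_numpy())
    return out


def assemble_features(
    enh_matrices: Mapping[str, pd.DataFrame],
    prom_matrices: Mapping[str, pd.DataFrame],
    enh_ids: Sequence[int],
    prom_ids: Sequence[int],
) -> FeatureTensor:
    """Stack per-mark matrices into the CCA feature blocks.

    ``enh_matrices`` maps mark -> region x cell-type DataFrame (index =
    element id); marks must cover (DHS, H3K27ac) for enhancers and
    (DHS, H3K27ac, H3K4me3) for promoters, all sharing the same cell-type
    columns in the same order.
    """
    for name, needed, mats in (
        ("enhancer", ENHANCER_MARKS, enh_matrices),
        ("promoter", PROMOTER_MARKS, prom_matrices),
    ):
        missing = set(needed) - set(mats)
        if missing:
            raise ValueError(f"{name} marks missing: {sorted(missing)}")
    cols = list(enh_matrices[ENHANCER_MARKS[0]].columns)
    for mats in (enh_matrices, prom_matrices):
        for mark, df in mats.items():
            if list(df.columns) != cols:
                raise ValueError(
                    f"cell-type columns of mark {mark!r} differ from {cols}"
                )
    enh_ids = np.asarray(list(enh_ids))
    prom_ids = np.asarray(list(prom_ids))
    X = np.stack(
        [enh_matrices[m].loc[enh_ids].to_numpy().T for m in ENHANCER_MARKS], axis=-1
    ).transpose(1, 0, 2)
    Y = np.stack(
        [prom_matrices[m].loc[prom_ids].to_numpy().T for m in PROMOTER_MARKS], axis=-1
    ).transpose(1, 0, 2)
    return FeatureTensor(X, Y, enh_ids, prom_ids, cols)
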