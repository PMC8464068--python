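"""Canonical-correlation test of enhancer-promoter activity synchronization.

For each candidate pair, the k cell types provide k joint observations of
the enhancer features X (k x p) and promoter features Y (k x q).  The null
hypothesis of independence (all population canonical correlations zero) is
tested through Wilks' lambda,

    Lambda = prod_l (1 - r_l^2),

converted to an approximately F-distributed statistic with Rao's
small-sample approximation.  For p = q = 1 the procedure reduces exactly to
the classical two-sided Pearson correlation F-test.

Canonical correlations are computed as the singular values of the whitened
cross-covariance matrix; whitening uses symmetric inverse square roots with
an eigenvalue floor so that near-constant columns cannot blow up the
estimates.  Pairs with a truly constant column are degenerate: they are
reported with p-value 1 and flagged, never dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .activity import FeatureTensor

__all__ = [
    "PairTestResult",
    "canonical_correlations",
    "wilks_lambda",
    "rao_f_pvalue",
    "test_pair",
    "test_pairs",
    "results_to_frame",
]

_EIG_FLOOR = 1e-12


@dataclass(frozen=True)
class PairTestResult:
    enhancer_id: int
    promoter_id: int
    r: tuple[float, ...]
    wilks: float
    f_stat: float
    df1: float
    df2: float
    pvalue: float
    degenerate: bool = False


def _inv_sqrt(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(cov)
    vals = np.maximum(vals, _EIG_FLOOR)
    return (vecs / np.sqrt(vals)) @ vecs.T


def canonical_correlations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """The min(p, q) sample canonical correlations, descending, in [0, 1]."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with a shared observation axis")
    k = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc / (k - 1)
    Syy = Yc.T @ Yc / (k - 1)
    Sxy = Xc.T @ Yc / (k - 1)
    M = _inv_sqrt(Sxx) @ Sxy @ _inv_sqrt(Syy)
    sv = np.linalg.svd(M, compute_uv=False)
    r = np.clip(sv[: min(X.shape[1], Y.shape[1])], 0.0, 1.0)
    return np.sort(r)[::-1]


def wilks_lambda(r: Sequence[float]) -> float:
    """Wilks' Lambda = prod(1 - r_l^2) over the canonical correlations."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("canonical correlations must lie in [0, 1]")
    return float(np.prod(1.0 - r**2))


def rao_f_pvalue(lam: float, p: int, q: int, k: int) -> tuple[float, float, float, float]:
    """Rao's F-approximation for Wilks' Lambda.

    Returns (F, df1, df2, pvalue) with df1 = p*q,
    s = sqrt((p^2 q^2 - 4) / (p^2 + q^2 - 5)) (s = 1 in the degenerate
    p*q <= 2 branch), m = k - (p + q + 3)/2 and df2 = m*s - p*q/2 + 1.
    The approximation is exact for min(p, q) <= 2, which covers both the
    production case (p=2, q=3) and the p=q=1 Pearson reduction.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"Lambda must be in [0, 1], got {lam}")
    pq = p * q
    denom = p * p + q * q - 5
    s = 1.0 if (pq <= 2 or denom <= 0) else math.sqrt((pq * pq - 4.0) / denom)
    m = k - (p + q + 3) / 2.0
    df1 = float(pq)
    df2 = m * s - pq / 2.0 + 1.0
    if df2 <= 0:
        raise ValueError(f"df2 = {df2} <= 0: sample too small (k={k}, p={p}, q={q})")
    if lam <= 0.0:
        return math.inf, df1, df2, 0.0
    ratio = lam ** (1.0 / s)
    f = (1.0 - ratio) / ratio * (df2 / df1)
    pvalue = float(stats.f.sf(f, df1, df2))
    return f, df1, df2, pvalue


def _is_degenerate(mat: np.ndarray) -> bool:
    return bool(np.any(np.ptp(mat, axis=0) == 0.0))


def test_pair(
    X: np.ndarray, Y: np.ndarray, enhancer_id: int = 0, promoter_id: int = 0
) -> PairTestResult:
    """Full test for one pair: correlations, Lambda, Rao F, p-value."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 1:
        X, Y = X.T, Y.T
    p, q, k = X.shape[1], Y.shape[1], X.shape[0]
    if k <= p + q:
        raise ValueError(f"need k > p + q observations, got k={k}, p={p}, q={q}")
    if _is_degenerate(X) or _is_degenerate(Y):
        nr = min(p, q)
        _, df1, df2, _ = rao_f_pvalue(1.0, p, q, k)
        return PairTestResult(
            enhancer_id, promoter_id, (0.0,) * nr, 1.0, 0.0, df1, df2, 1.0, True
        )
    r = canonical_correlations(X, Y)
    lam = wilks_lambda(r)
    f, df1, df2, pvalue = rao_f_pvalue(lam, p, q, k)
    return PairTestResult(
        enhancer_id, promoter_id, tuple(r), lam, f, df1, df2, pvalue
    )


def test_pairs(
    tensor: FeatureTensor, pairs: Sequence[tuple[int, int]]
) -> list[PairTestResult]:
    """Test every (enh_id, prom_id) candidate against the feature tensor."""
    enh_pos = {int(e): i for i, e in enumerate(tensor.enh_ids)}
    prom_pos = {int(p): j for j, p in enumerate(tensor.prom_ids)}
    out = []
    for enh_id, prom_id in pairs:
        X = tensor.X[enh_pos[enh_id]]
        Y = tensor.Y[prom_pos[prom_id]]
        out.append(test_pair(X, Y, enh_id, prom_id))
    return out


# library functions, not pytest cases
test_pair.__test__ = False  # type: ignore[attr-defined]
test_pairs.__test__ = False  # type: ignore[attr-defined]


def results_to_frame(results: Sequence[PairTestResult]) -> pd.DataFrame:
    nr = max((len(res.r) for res in results), default=0)
    rows = []
    for res in results:
        row = {
            "enh_id": res.enhancer_id,
            "prom_id": res.promoter_id,
            **{f"r{l + 1}": (res.r[l] if l < len(res.r) else np.nan) for l in range(nr)},
            "wilks": res.wilks,
            "F": res.f_stat,
            "df1": res.df1,
            "df2": res.df2,
            "pvalue": res.pvalue,
            "degenerate": res.degenerate,
        }
        rows.append(row)
    return pd.DataFrame(rows)
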