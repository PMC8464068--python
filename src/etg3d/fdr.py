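"""Multiple-testing control with 3D-proximity side information.

Three procedures operate on the per-pair CCA p-values: Bonferroni,
Benjamini-Hochberg (BH), and an adaptive p-value thresholding (AdaPT-style)
procedure that uses the HC score s_ij as a covariate.  The adaptive
procedure exploits the masking argument: each p-value is initially known to
the fitting model only through min(p, 1-p), so the model can learn where
(in covariate space) small p-values concentrate without ever seeing which
tail a masked p-value is in.  The false discovery proportion is estimated
by the mirror statistic

    fdp_hat = (1 + #{p_i >= 1 - s_t(x_i)}) / max(1, #{p_i <= s_t(x_i)})

and the threshold s_t is shrunk (hypotheses are "peeled" and their p-values
revealed) until fdp_hat <= alpha.  This controls FDR in finite samples for
any peeling rule that depends only on masked information; the fitted model
only affects power.  With uninformative side information the learned
threshold is flat and behaviour approaches BH.

The two-groups working model is the logistic-Gamma family: non-null
probability pi(x) by logistic regression on a natural cubic spline basis of
the side score, and the non-null transform y = -log p by a Gamma GLM (log
link, global mean), fitted jointly by EM over the masked labels.  Candidate
bases with df in {2,...,6} are compared by BIC at the first fit; later
refits are kept only when they explain the current masked data better than
the incumbent model.  The masked likelihood has degenerate modes (mixture
spikes, all-null / all-non-null collapses) that the masking symmetry cannot
rule out; the constraints and guards in the fitting routines exist to keep
the EM off them and are documented inline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Hypothesis",
    "RejectionSet",
    "bonferroni",
    "benjamini_hochberg",
    "adapt_threshold",
    "adapt_per_chromosome",
    "adjusted_pvalues",
    "adjusted_pvalues_per_chromosome",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_MODEL_GRID",
]

DEFAULT_MODEL_GRID: tuple[int, ...] = (2, 3, 4, 5, 6)
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(
    sorted({round(0.01 * i, 2) for i in range(1, 31)} | {0.05})
)

_S0_CAP = 0.45          # initial constant threshold cap
_EM_TOL = 1e-6          # relative log-likelihood change
_EM_MAXIT = 50
_MIN_ADAPT_N = 50       # below this, per-chromosome runs fall back to BH


@dataclass(frozen=True)
class Hypothesis:
    """One EP pair entering multiple testing."""

    pair_id: object
    pvalue: float
    side: float
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0) or not math.isfinite(self.pvalue):
            raise ValueError(f"p-value out of [0,1]: {self.pvalue}")


@dataclass
class RejectionSet:
    alpha: float
    rejected: set
    adjusted: dict = field(default_factory=dict)
    threshold_curve: dict = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


# ---------------------------------------------------------------------------
# classical corrections (statsmodels behind the surface)

def bonferroni(pvalues: Sequence[float], alpha: float = 0.05) -> RejectionSet:
    p = np.asarray(pvalues, dtype=float)
    reject, adj, _, _ = multipletests(p, alpha=alpha, method="bonferroni")
    return RejectionSet(
        alpha,
        set(np.flatnonzero(reject).tolist()),
        dict(enumerate(adj.tolist())),
    )


def benjamini_hochberg(pvalues: Sequence[float], alpha: float = 0.05) -> RejectionSet:
    p = np.asarray(pvalues, dtype=float)
    reject, adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return RejectionSet(
        alpha,
        set(np.flatnonzero(reject).tolist()),
        dict(enumerate(adj.tolist())),
    )


# ---------------------------------------------------------------------------
# spline basis and weighted GLM fits (small, self-contained IRLS)

def natural_cubic_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic spline basis of ``x`` with ``df`` columns plus intercept.

    Knots sit at evenly spaced quantiles (boundary knots at min/max).  The
    basis is linear beyond the boundary knots.  Degenerate covariates
    (fewer distinct knots than needed) degrade gracefully to the intercept
    plus whatever non-constant columns remain.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    cols = [np.ones(n)]
    knots = np.unique(np.quantile(x, np.linspace(0, 1, df + 1)))
    if knots.size >= 2:
        cols.append(x)
    if knots.size >= 3:
        xi_k = knots[-1]
        xi_km1 = knots[-2]

        def d(xi: float) -> np.ndarray:
            return (np.maximum(x - xi, 0.0) ** 3 - np.maximum(x - xi_k, 0.0) ** 3) / (
                xi_k - xi
            )

        d_last = d(xi_km1)
        for xi in knots[:-2]:
            cols.append(d(xi) - d_last)
    Z = np.column_stack(cols)
    # scale columns for numerical stability of the IRLS solves
    scale = np.maximum(np.abs(Z).max(axis=0), 1e-12)
    return Z / scale


def _wls_solve(Z: np.ndarray, w: np.ndarray, target: np.ndarray) -> np.ndarray:
    A = Z.T @ (Z * w[:, None]) + 1e-8 * np.eye(Z.shape[1])
    return np.linalg.solve(A, Z.T @ (w * target))


def _fit_weighted_logistic(
    Z: np.ndarray, y: np.ndarray, maxit: int = 25
) -> np.ndarray:
    """IRLS for logistic regression with soft responses y in [0, 1]."""
    beta = np.zeros(Z.shape[1])
    beta[0] = math.log(max(y.mean(), 1e-6) / max(1 - y.mean(), 1e-6))
    for _ in range(maxit):
        eta = np.clip(Z @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        beta_new = _wls_solve(Z, w, eta + (y - mu) / w)
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _fit_weighted_gamma(
    Z: np.ndarray, y: np.ndarray, w: np.ndarray, maxit: int = 25
) -> tuple[np.ndarray, float]:
    """IRLS for a Gamma GLM with log link and observation weights.

    Returns the coefficient vector and the shape parameter estimated from
    the weighted Pearson dispersion.
    """
    wsum = w.sum()
    if wsum <= 0:
        return np.zeros(Z.shape[1]), 1.0
    beta = np.zeros(Z.shape[1])
    beta[0] = math.log(max(np.sum(w * y) / wsum, 1e-6))
    for _ in range(maxit):
        eta = np.clip(Z @ beta, -30, 30)
        mu = np.exp(eta)
        beta_new = _wls_solve(Z, w, eta + (y - mu) / mu)
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    mu = np.exp(np.clip(Z @ beta, -30, 30))
    disp = np.sum(w * ((y - mu) / mu) ** 2) / max(wsum, 1e-12)
    # shape confined to [1, 2]: below 1 the density spikes at p ~ 1 (a mode
    # the masked likelihood cannot distinguish from signal near p ~ 0);
    # well above 1 it can turn into a narrow spike on the few most extreme
    # p-values, collapsing the mixture weight to zero
    shape = float(np.clip(1.0 / max(disp, 1e-6), 1.0, 2.0))
    return beta, shape


@dataclass
class _TwoGroups:
    """Fitted logistic-Gamma two-groups model."""

    beta_pi: np.ndarray
    beta_mu: np.ndarray
    shape: float
    df: int
    loglik: float

    def pi(self, Z: np.ndarray) -> np.ndarray:
        raw = 1.0 / (1.0 + np.exp(-np.clip(Z @ self.beta_pi, -30, 30)))
        return np.clip(raw, 1e-8, 1.0 - 1e-8)

    def f1(self, Z: np.ndarray, p: np.ndarray) -> np.ndarray:
        """Non-null density of p: Gamma density of y = -log p times 1/p.

        The alternative is one-sided and identifiable by construction: the
        mean of -log p is floored at twice the null value, so the component
        must live at genuinely small p-values.  Without the gap the mixture
        is degenerate — a "non-null" component with mean ~1 is a null clone,
        pi becomes arbitrary, and the peeling order can invert.
        """
        y = -np.log(np.clip(p, 1e-300, 1.0))
        mu = np.maximum(np.exp(np.clip(Z @ self.beta_mu, -30, 30)), 2.0)
        nu = self.shape
        logf = (
            nu * (np.log(nu) - np.log(mu))
            + (nu - 1.0) * np.log(np.maximum(y, 1e-300))
            - nu * y / mu
            - math.lgamma(nu)
            + y  # 1/p = exp(y)
        )
        return np.exp(np.clip(logf, -300, 300))


def _masked_loglik(
    model: _TwoGroups, Z: np.ndarray, p: np.ndarray, masked: np.ndarray
) -> float:
    """Log-likelihood of the two-groups model on the current masked view."""
    a = np.minimum(p, 1.0 - p)
    b = 1.0 - a
    pi = model.pi(Z)
    denom_m = pi * model.f1(Z, a) + pi * model.f1(Z, b) + 2.0 * (1.0 - pi)
    denom_r = pi * model.f1(Z, p) + (1.0 - pi)
    return float(np.sum(np.log(np.where(masked, denom_m, denom_r) + 1e-300)))


def _fit_two_groups(
    Z: np.ndarray,
    p: np.ndarray,
    masked: np.ndarray,
    df: int,
) -> _TwoGroups:
    """EM fit of the logistic-Gamma model under p-value masking.

    Masked hypotheses enter only through the pair {p, 1-p}; revealed ones
    through their actual p-value.  The null component has uniform density.
    The EM is multi-started from a moderate and a strong signal-mean
    initialization and the higher-likelihood fit is kept.
    """
    fits = [_em_run(Z, p, masked, df, mu0) for mu0 in (3.0, 10.0)]
    return max(fits, key=lambda m: m.loglik)


def _em_run(
    Z: np.ndarray, p: np.ndarray, masked: np.ndarray, df: int, mu0: float
) -> _TwoGroups:
    a = np.minimum(p, 1.0 - p)
    b = 1.0 - a
    model = _TwoGroups(
        beta_pi=np.zeros(Z.shape[1]),
        beta_mu=np.zeros(Z.shape[1]),
        shape=1.0,
        df=df,
        loglik=-np.inf,
    )
    model.beta_pi[0] = math.log(0.1 / 0.9)
    model.beta_mu[0] = math.log(mu0)  # non-null -log p away from null mean 1
    ya = -np.log(np.clip(a, 1e-300, None))
    yb = -np.log(np.clip(b, 1e-300, None))
    yobs = -np.log(np.clip(p, 1e-300, None))
    prev_ll = -np.inf
    for _ in range(_EM_MAXIT):
        pi = model.pi(Z)
        f1a = model.f1(Z, a)
        f1b = model.f1(Z, b)
        f1p = model.f1(Z, p)
        # E-step
        denom_m = pi * f1a + pi * f1b + 2.0 * (1.0 - pi)
        denom_r = pi * f1p + (1.0 - pi)
        gamma = np.where(masked, (pi * (f1a + f1b)) / denom_m, (pi * f1p) / denom_r)
        wa = np.where(masked, pi * f1a / denom_m, gamma)
        wb = np.where(masked, pi * f1b / denom_m, 0.0)
        ll = float(np.sum(np.log(np.where(masked, denom_m, denom_r) + 1e-300)))
        # M-step
        # posterior labels capped at 0.95: the masked likelihood has a
        # self-reinforcing "everything non-null" fixpoint (pi -> 1 makes
        # every posterior -> 1 regardless of the densities); bounding the
        # logistic target keeps 1-pi > 0 so the density term still orders
        # hypotheses
        model.beta_pi = _fit_weighted_logistic(Z, np.clip(gamma, 1e-8, 0.95))
        if float(np.mean(model.pi(Z))) < 0.02:
            # mirror-image collapse: pi -> 0 with the Gamma component
            # spiking on the few most extreme p-values; restart the weight
            model.beta_pi = np.zeros(Z.shape[1])
            model.beta_pi[0] = math.log(0.1 / 0.9)
        # the Gamma mean is global (intercept-only): letting it vary with
        # the covariate lets sparsely-populated covariate regions drag the
        # fitted mean to the floor, which then vetoes even overwhelming
        # per-hypothesis evidence there; the covariate enters through pi
        Zmu = np.vstack([Z[:, :1], Z[masked, :1]])
        yg = np.concatenate([np.where(masked, ya, yobs), yb[masked]])
        wg = np.concatenate([wa, wb[masked]])
        bmu, model.shape = _fit_weighted_gamma(Zmu, yg, wg)
        if math.exp(min(bmu[0], 30.0)) < 1.0:
            # flipped onto the mirror mode (non-null mass at p ~ 1):
            # reject and restart the component from the signal side
            bmu = np.array([math.log(mu0)])
            model.shape = 1.0
        model.beta_mu = np.zeros(Z.shape[1])
        model.beta_mu[0] = bmu[0]
        if abs(ll - prev_ll) < _EM_TOL * (abs(prev_ll) + 1.0):
            prev_ll = ll
            break
        prev_ll = ll
    model.loglik = prev_ll
    return model


# ---------------------------------------------------------------------------
# the adaptive thresholding loop

def _adapt_path(
    p: np.ndarray,
    x: np.ndarray,
    alphas: Sequence[float],
    model_grid: Sequence[int] = DEFAULT_MODEL_GRID,
    batch_frac: float = 0.01,
    refit_frac: float = 0.05,
    exact: bool = False,
) -> dict[float, np.ndarray]:
    """Run the peeling loop once; return, per alpha, the rejection mask.

    The peeling path is shared across alphas: as hypotheses are revealed the
    candidate rejection set only shrinks, so the first state whose estimated
    FDP drops below each alpha yields nested rejection sets (monotone in
    alpha by construction).
    """
    n = p.size
    alphas = sorted(set(float(a) for a in alphas), reverse=True)
    s0 = min(float(np.quantile(p, 0.45)), _S0_CAP) if n else _S0_CAP
    in_A = p <= s0
    in_B = p >= 1.0 - s0
    masked = in_A | in_B
    out: dict[float, np.ndarray] = {}
    pending = list(alphas)

    def fdp_hat() -> float:
        return (1.0 + int(in_B.sum())) / max(1, int(in_A.sum()))

    def flush() -> None:
        while pending and fdp_hat() <= pending[0]:
            out[pending.pop(0)] = in_A.copy()

    flush()
    if not pending:
        return out

    model: _TwoGroups | None = None
    Z_by_df: dict[int, np.ndarray] = {}
    n_masked0 = int(masked.sum())
    revealed_since_fit = n_masked0  # force a fit on entry
    a_small = np.minimum(p, 1.0 - p)
    # deterministic tie-break on masked quantities only: using the raw
    # p-value here would leak which tail a masked hypothesis is in and
    # void the mirror-estimator FDR guarantee
    order_eps = np.argsort(np.lexsort((np.arange(n), x, a_small)))

    while pending and masked.any():
        if revealed_since_fit >= refit_frac * max(n_masked0, 1):
            try:
                if model is None:
                    # BIC across the candidate bases: the EM's soft labels
                    # make flexible bases look better than they are, and an
                    # overfit basis can invert the learned ordering
                    fits = []
                    for df in model_grid:
                        Z_by_df[df] = natural_cubic_basis(x, df)
                        fit = _fit_two_groups(Z_by_df[df], p, masked, df)
                        k_par = 2 * Z_by_df[df].shape[1] + 1
                        fits.append((k_par * math.log(n) - 2 * fit.loglik, fit))
                    model = min(fits, key=lambda t: t[0])[1]
                else:
                    # a refit is a candidate, not a replacement: late-path
                    # EM runs (few masked, signal-pure remainder) can land
                    # in degenerate modes, so keep whichever of incumbent
                    # and refit explains the current masked data better
                    Z = Z_by_df[model.df]
                    refit = _fit_two_groups(Z, p, masked, model.df)
                    if _masked_loglik(refit, Z, p, masked) > _masked_loglik(
                        model, Z, p, masked
                    ):
                        model = refit
            except (np.linalg.LinAlgError, FloatingPointError):
                warnings.warn("two-groups fit failed; using intercept-only model")
                Z_by_df[1] = np.ones((n, 1))
                model = _fit_two_groups(Z_by_df[1], p, masked, 1)
            revealed_since_fit = 0
        Z = Z_by_df[model.df]
        pi = model.pi(Z)
        f1a = model.f1(Z, a_small)
        lfdr = (1.0 - pi) / np.maximum((1.0 - pi) + pi * f1a, 1e-300)
        # peel the least promising masked hypotheses (highest estimated lfdr)
        cand = np.flatnonzero(masked)
        # near the stopping boundary, peel one at a time: a whole batch can
        # overshoot the first state with fdp_hat <= alpha and forfeit
        # rejections that a finer path would have kept
        near_stop = fdp_hat() <= 0.05 + 2.0 * pending[0]
        batch = 1 if (exact or near_stop) else max(1, math.ceil(batch_frac * cand.size))
        key = lfdr[cand] + 1e-12 * order_eps[cand] / max(n, 1)
        reveal = cand[np.argsort(key)[::-1][:batch]]
        masked[reveal] = False
        in_A[reveal] = False
        in_B[reveal] = False
        revealed_since_fit += reveal.size
        flush()

    empty = np.zeros(n, dtype=bool)
    for a in pending:
        out[a] = in_A.copy() if fdp_hat() <= a else empty
    return out


def _as_arrays(hyps: Sequence[Hypothesis]) -> tuple[np.ndarray, np.ndarray, list]:
    p = np.array([h.pvalue for h in hyps], dtype=float)
    x = np.array([h.side for h in hyps], dtype=float)
    ids = [h.pair_id for h in hyps]
    return p, x, ids


def adapt_threshold(
    hyps: Sequence[Hypothesis],
    alpha: float = 0.05,
    model_grid: Sequence[int] = DEFAULT_MODEL_GRID,
    exact: bool = False,
) -> RejectionSet:
    """Side-information-adaptive rejection set at one target FDR level."""
    p, x, ids = _as_arrays(hyps)
    if p.size == 0:
        return RejectionSet(alpha, set())
    masks = _adapt_path(p, x, [alpha], model_grid=model_grid, exact=exact)
    mask = masks[float(alpha)]
    thresholds = {
        ids[i]: (max(float(p[i]), 0.0) if mask[i] else 0.0) for i in range(p.size)
    }
    return RejectionSet(
        alpha,
        {ids[i] for i in np.flatnonzero(mask)},
        threshold_curve=thresholds,
    )


def adjusted_pvalues(
    hyps: Sequence[Hypothesis],
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    model_grid: Sequence[int] = DEFAULT_MODEL_GRID,
    exact: bool = False,
) -> dict:
    """Per-hypothesis smallest grid alpha at which it is rejected (else 1).

    A single peeling path serves the whole grid, so the values are monotone
    by construction: rejection at alpha implies rejection at every larger
    grid alpha.
    """
    p, x, ids = _as_arrays(hyps)
    if p.size == 0:
        return {}
    masks = _adapt_path(p, x, alpha_grid, model_grid=model_grid, exact=exact)
    adj = np.ones(p.size)
    for a in sorted(alpha_grid, reverse=True):
        adj[masks[float(a)]] = a
    return {ids[i]: float(adj[i]) for i in range(p.size)}


def adjusted_pvalues_per_chromosome(
    hyps: Sequence[Hypothesis],
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    model_grid: Sequence[int] = DEFAULT_MODEL_GRID,
    min_n: int = _MIN_ADAPT_N,
) -> dict:
    """Chromosome-local adjusted values (smallest rejecting grid alpha).

    Chromosomes with fewer than ``min_n`` hypotheses fall back to BH
    adjusted p-values, mirroring :func:`adapt_per_chromosome`.
    """
    by_chrom: dict[str, list[Hypothesis]] = {}
    for h in hyps:
        by_chrom.setdefault(h.chrom, []).append(h)
    out: dict = {}
    for chrom in sorted(by_chrom):
        sub = by_chrom[chrom]
        if len(sub) < min_n:
            warnings.warn(f"{chrom}: only {len(sub)} hypotheses; falling back to BH")
            rs = benjamini_hochberg([h.pvalue for h in sub])
            out.update({h.pair_id: rs.adjusted[i] for i, h in enumerate(sub)})
            continue
        out.update(adjusted_pvalues(sub, alpha_grid, model_grid=model_grid))
    return out


def adapt_per_chromosome(
    hyps: Sequence[Hypothesis],
    alpha: float = 0.05,
    model_grid: Sequence[int] = DEFAULT_MODEL_GRID,
    min_n: int = _MIN_ADAPT_N,
    exact: bool = False,
) -> RejectionSet:
    """Run the adaptive procedure independently per chromosome.

    Chromosomes with fewer than ``min_n`` hypotheses fall back to BH (with a
    warning): the two-groups model cannot be estimated usefully there.
    """
    by_chrom: dict[str, list[Hypothesis]] = {}
    for h in hyps:
        by_chrom.setdefault(h.chrom, []).append(h)
    rejected: set = set()
    thresholds: dict = {}
    for chrom in sorted(by_chrom):
        sub = by_chrom[chrom]
        if len(sub) < min_n:
            warnings.warn(
                f"{chrom}: only {len(sub)} hypotheses; falling back to BH"
            )
            rs = benjamini_hochberg([h.pvalue for h in sub], alpha)
            rejected |= {sub[i].pair_id for i in rs.rejected}
            continue
        rs = adapt_threshold(sub, alpha, model_grid=model_grid, exact=exact)
        rejected |= rs.rejected
        thresholds.update(rs.threshold_curve)
    return RejectionSet(alpha, rejected, threshold_curve=thresholds)
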