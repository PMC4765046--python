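"""Linear mixed model association machinery.

Implements the association engine used throughout the package:

* the realized relationship matrix (RRM) as background covariance,
* a null-model fit of the noise-to-background variance ratio ``delta``
  (fit once per gene by maximum likelihood, then held fixed for every
  variant tested against that gene — the EMMA-X treatment),
* per-variant likelihood-ratio tests with p-values from chi2(1 df),
* a low-rank extension with a third variance component spanned by the
  expression of selected *exogenous* genes, fit by Woodbury identities so
  the per-test cost scales with the conditioning-set rank R rather than
  with a dense N x N refactorization.

Model for gene expression y (length N) tested against variant x::

    y ~ N(x beta + C alpha,  sigma_bg^2 K + [sigma_exo^2 G G^T] + sigma_n^2 I)

with K the background (kinship) covariance, C fixed-effect covariates
(always including an intercept) and G the standardized expression of the
exogenous genes (only in the conditioned test).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data import ExpressionData, GenotypeData, check_paired

logger = logging.getLogger("gnetlmm")

__all__ = [
    "Kinship",
    "NullModelFit",
    "AssociationResult",
    "AssociationScan",
    "realized_relationship",
    "fit_null",
    "lmm_assoc",
    "scan",
    "fit_null_conditioned",
    "lmm_assoc_conditioned",
    "scan_conditioned",
]

# Grid used for the 1-D profile of delta = sigma_n^2 / sigma_bg^2.
DELTA_GRID = np.logspace(-4, 4, 100)


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class Kinship:
    """N x N background covariance with a cached eigendecomposition."""

    matrix: np.ndarray
    kind: str = "custom"
    _eig: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("kinship must be a square matrix")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("kinship must be symmetric (tolerance 1e-10)")
        if self.kind not in ("realized-relationship", "identity", "custom"):
            raise ValueError(f"unknown kinship kind: {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending, clipped at 0) and eigenvectors of K."""
        if self._eig is None:
            s, U = np.linalg.eigh(self.matrix)
            top = max(s[-1], 0.0)
            if s[0] < -1e-8 * max(top, 1.0):
                raise ValueError("kinship is not positive semi-definite")
            self._eig = (np.clip(s, 0.0, None), U)
        return self._eig

    @classmethod
    def identity(cls, n: int) -> "Kinship":
        return cls(np.eye(n), kind="identity")


def _impute_dosage_mean(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-variant mean of observed calls."""
    X = np.array(dosages, dtype=float)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        col_mean = np.nanmean(np.where(nan_mask, np.nan, X), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    return X


def standardize_genotypes(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute, centre and scale each variant column to unit variance.

    Returns the standardized matrix (zero-variance columns dropped) and a
    boolean mask of the retained columns.
    """
    X = _impute_dosage_mean(dosages)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    return X[:, keep] / sd[keep], keep


def realized_relationship(genotypes: GenotypeData) -> Kinship:
    """Realized relationship matrix K = Z Z^T / F from standardized dosages.

    Zero-variance (monomorphic) variants are dropped with a warning; if no
    variant is informative an error is raised.
    """
    Z, keep = standardize_genotypes(genotypes.dosages)
    n_dropped = int((~keep).sum())
    if Z.shape[1] == 0:
        raise ValueError("no informative variants")
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} zero-variance variants from the RRM",
            stacklevel=2,
        )
    K = Z @ Z.T / Z.shape[1]
    return Kinship(K, kind="realized-relationship")


# ---------------------------------------------------------------------------
# Fixed-effect design
# ---------------------------------------------------------------------------

def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    """Intercept column plus any additional covariates."""
    if covariates is None:
        return np.ones((n, 1))
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != n:
        C = C.T
    if C.shape[0] != n:
        raise ValueError("covariates must have N rows")
    return np.column_stack([np.ones(n), C])


# ---------------------------------------------------------------------------
# Null model: delta profile (EMMA-X)
# ---------------------------------------------------------------------------

def _weighted_rss(y: np.ndarray, C: np.ndarray, w: np.ndarray):
    """GLS residual sum of squares of y on C under covariance diag(w).

    Returns (rss, coef) where rss = min_a (y - C a)' W^{-1} (y - C a).
    """
    sw = np.sqrt(w)
    yt = y / sw
    Ct = C / sw[:, None]
    coef, res, rank, _ = np.linalg.lstsq(Ct, yt, rcond=None)
    r = yt - Ct @ coef
    return float(r @ r), coef


def _ml_loglik_diag(y: np.ndarray, C: np.ndarray, w: np.ndarray) -> float:
    """Profiled ML log-likelihood for covariance sigma^2 * diag(w)."""
    n = y.shape[0]
    rss, _ = _weighted_rss(y, C, w)
    if rss <= 0:
        return np.inf
    return float(
        -0.5 * n * (np.log(2 * np.pi) + 1.0)
        - 0.5 * n * np.log(rss / n)
        - 0.5 * np.sum(np.log(w))
    )


@dataclass
class NullModelFit:
    """Null-model variance components for one gene, with cached rotation.

    ``delta = sigma_n^2 / sigma_bg^2`` is +inf when the background component
    is inactive (the boundary convention for unidentifiable cases such as
    K = I, where only the total variance is determined).
    """

    delta: float
    sigma_bg2: float
    sigma_n2: float
    loglik: float
    rotation: tuple[np.ndarray, np.ndarray]  # (eigenvalues s, eigenvectors U)
    y_rot: np.ndarray = field(repr=False)
    C_rot: np.ndarray = field(repr=False)

    @property
    def weights(self) -> np.ndarray:
        """Diagonal of the total covariance in the rotated basis (unit scale)."""
        s = self.rotation[0]
        if np.isinf(self.delta):
            return np.ones_like(s)
        return s + self.delta


def fit_null(
    y: np.ndarray,
    K: Kinship,
    covariates: np.ndarray | None = None,
) -> NullModelFit:
    """Fit ``y ~ N(C alpha, sigma_bg^2 K + sigma_n^2 I)`` by maximum likelihood.

    The ratio delta = sigma_n^2 / sigma_bg^2 is profiled on a 100-point
    log-spaced grid over [1e-4, 1e4] and refined by bounded 1-D optimization;
    the boundary delta = +inf (pure noise, ordinary least squares) is always
    evaluated as a candidate and wins ties.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    C = _design(n, covariates)
    if n <= C.shape[1]:
        raise ValueError("need more samples than fixed effects")
    s, U = K.eigendecomposition()
    ystar = U.T @ y
    Cstar = U.T @ C

    def neg_ll(log_delta: float) -> float:
        return -_ml_loglik_diag(ystar, Cstar, s + np.exp(log_delta))

    grid_ll = np.array([-neg_ll(np.log(d)) for d in DELTA_GRID])
    i = int(np.argmax(grid_ll))
    lo = np.log(DELTA_GRID[max(i - 1, 0)])
    hi = np.log(DELTA_GRID[min(i + 1, len(DELTA_GRID) - 1)])
    best_delta, best_ll = DELTA_GRID[i], grid_ll[i]
    if hi > lo:
        res = optimize.minimize_scalar(
            neg_ll, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        if -res.fun > best_ll:
            best_delta, best_ll = float(np.exp(res.x)), float(-res.fun)

    # Boundary candidate: covariance collapses to sigma_n^2 I (OLS).
    ones = np.ones(n)
    ll_inf = _ml_loglik_diag(ystar, Cstar, ones)
    if ll_inf >= best_ll - 1e-8:
        rss, _ = _weighted_rss(ystar, Cstar, ones)
        sigma_n2 = rss / n
        return NullModelFit(np.inf, 0.0, sigma_n2, ll_inf, (s, U), ystar, Cstar)

    w = s + best_delta
    rss, _ = _weighted_rss(ystar, Cstar, w)
    sigma_bg2 = rss / n
    return NullModelFit(
        best_delta, sigma_bg2, sigma_bg2 * best_delta, best_ll, (s, U),
        ystar, Cstar,
    )


# ---------------------------------------------------------------------------
# Association results
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    beta: float
    pvalue: float
    lrt_stat: float
    n_conditioned: int = 0


@dataclass
class AssociationScan:
    """Gene-by-variant grid of association statistics (T x F)."""

    pvalues: np.ndarray
    betas: np.ndarray
    gene_ids: np.ndarray
    variant_ids: np.ndarray
    n_conditioned: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        self.betas = np.asarray(self.betas, dtype=float)
        t, f = self.pvalues.shape
        if self.betas.shape != (t, f):
            raise ValueError("betas must match pvalues shape")
        self.gene_ids = np.asarray(self.gene_ids)
        self.variant_ids = np.asarray(self.variant_ids)
        if self.gene_ids.shape != (t,) or self.variant_ids.shape != (f,):
            raise ValueError("id vectors must align with the T x F grid")
        if self.n_conditioned is None:
            self.n_conditioned = np.zeros((t, f), dtype=int)
        else:
            self.n_conditioned = np.asarray(self.n_conditioned, dtype=int)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pvalues.shape

    def copy(self) -> "AssociationScan":
        return AssociationScan(
            self.pvalues.copy(), self.betas.copy(),
            self.gene_ids.copy(), self.variant_ids.copy(),
            self.n_conditioned.copy(),
        )


def _lrt_pvalue(lrt: float) -> float:
    return float(stats.chi2.sf(lrt, df=1))


def _prepare_x(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if np.isnan(x).any():
        m = np.nanmean(x)
        x = np.where(np.isnan(x), m, x)
    if np.std(x) == 0:
        raise ValueError("monomorphic variant")
    return x


def lmm_assoc(
    x: np.ndarray,
    y: np.ndarray,
    null: NullModelFit,
    covariates: np.ndarray | None = None,
) -> AssociationResult:
    """Likelihood-ratio test of the variant effect at the null-model delta.

    Generalized least squares under sigma^2 (K + delta I) with sigma^2
    profiled out; the LRT statistic is referred to chi2 with 1 df.
    """
    x = _prepare_x(x)
    s, U = null.rotation
    xstar = U.T @ x
    w = null.weights
    n = len(xstar)
    rss0, _ = _weighted_rss(null.y_rot, null.C_rot, w)
    design1 = np.column_stack([null.C_rot, xstar])
    rss1, coef1 = _weighted_rss(null.y_rot, design1, w)
    lrt = max(n * np.log(rss0 / rss1), 0.0) if rss1 > 0 else np.inf
    return AssociationResult(float(coef1[-1]), _lrt_pvalue(lrt), float(lrt), 0)


# ---------------------------------------------------------------------------
# Vectorized scan (Step 1)
# ---------------------------------------------------------------------------

def _gls_scan_stats(y, C, X, vinv):
    """Per-column GLS stats of y on [C, x_f] under a covariance action.

    ``vinv(B)`` must return V^{-1} B for the (rotated) total covariance V at
    unit scale.  Returns (rss0, rss1 array, beta array) for the ML profile.
    """
    ViC = vinv(C)
    Viy = vinv(y)
    ViX = vinv(X)
    CtVC = C.T @ ViC
    CtVy = C.T @ Viy
    sol = np.linalg.solve(CtVC, np.column_stack([CtVy, C.T @ ViX]))
    alpha0 = sol[:, 0]
    CtVC_inv_CtVX = sol[:, 1:]
    rss0 = float(y @ Viy - CtVy @ alpha0)
    # x residualized against C in the V^{-1} metric
    xVx = np.einsum("nf,nf->f", X, ViX) - np.einsum(
        "pf,pf->f", C.T @ ViX, CtVC_inv_CtVX
    )
    xVy = X.T @ Viy - (C.T @ ViX).T @ alpha0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(xVx > 0, xVy / np.where(xVx > 0, xVx, 1.0), np.nan)
        rss1 = rss0 - np.where(xVx > 0, xVy**2 / np.where(xVx > 0, xVx, 1.0), 0.0)
    return rss0, rss1, beta


def _finalize_scan_row(n, rss0, rss1, beta, informative):
    with np.errstate(divide="ignore", invalid="ignore"):
        lrt = n * np.log(rss0 / np.maximum(rss1, 1e-300))
    lrt = np.where(informative, np.maximum(lrt, 0.0), np.nan)
    pv = np.where(np.isnan(lrt), np.nan, stats.chi2.sf(np.nan_to_num(lrt), df=1))
    beta = np.where(informative, beta, np.nan)
    return pv, beta


def scan(
    genotypes: GenotypeData,
    expression: ExpressionData,
    K: Kinship,
    covariates: np.ndarray | None = None,
) -> AssociationScan:
    """Genome-wide eQTL scan: for every gene, fit the null once, then test
    every variant at the fixed delta.  Monomorphic variants yield missing
    entries (logged once)."""
    check_paired(genotypes, expression)
    s, U = K.eigendecomposition()
    X = _impute_dosage_mean(genotypes.dosages)
    informative = X.std(axis=0) > 0
    n_bad = int((~informative).sum())
    if n_bad:
        logger.warning("scan: %d monomorphic variants reported as missing", n_bad)
    Xstar = U.T @ X
    n, f = X.shape
    t = expression.n_genes
    pvals = np.full((t, f), np.nan)
    betas = np.full((t, f), np.nan)
    for j in range(t):
        null = fit_null(expression.values[:, j], K, covariates)
        w = null.weights

        def vinv(B, w=w):
            return B / w[:, None] if B.ndim == 2 else B / w

        rss0, rss1, beta = _gls_scan_stats(null.y_rot, null.C_rot, Xstar, vinv)
        pvals[j], betas[j] = _finalize_scan_row(n, rss0, rss1, beta, informative)
    return AssociationScan(pvals, betas, expression.gene_ids, genotypes.variant_ids)


# ---------------------------------------------------------------------------
# Low-rank conditioned model (Step 3)
# ---------------------------------------------------------------------------

def _standardize_columns(M: np.ndarray) -> np.ndarray:
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if M.ndim == 1:
        M = M[:, None]
    M = M - M.mean(axis=0)
    sd = M.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("exogenous gene with zero variance")
    return M / sd


class _LowRankCov:
    """Action of V^{-1} for V = diag(d) + gamma * G G^T via Woodbury."""

    def __init__(self, d: np.ndarray, G: np.ndarray, gamma: float):
        self.d = d
        self.G = G
        self.gamma = gamma
        if gamma > 0 and G.shape[1] > 0:
            GtDiG = (G / d[:, None]).T @ G
            self.M = np.eye(G.shape[1]) / gamma + GtDiG
            sign, logdet_M = np.linalg.slogdet(np.eye(G.shape[1]) + gamma * GtDiG)
            self.logdet = float(np.sum(np.log(d)) + logdet_M)
        else:
            self.M = None
            self.logdet = float(np.sum(np.log(d)))

    def vinv(self, B: np.ndarray) -> np.ndarray:
        DiB = B / (self.d[:, None] if B.ndim == 2 else self.d)
        if self.M is None:
            return DiB
        GtDiB = self.G.T @ DiB
        corr = (self.G / self.d[:, None]) @ np.linalg.solve(self.M, GtDiB)
        return DiB - corr


@dataclass
class ConditionedNullFit:
    """Three-component null fit for one (gene, conditioning set) pair."""

    sigma_bg2: float
    sigma_exo2: float
    sigma_n2: float
    loglik: float
    rotation: tuple[np.ndarray, np.ndarray]
    y_rot: np.ndarray = field(repr=False)
    C_rot: np.ndarray = field(repr=False)
    cov: _LowRankCov = field(repr=False)
    n_conditioned: int = 0


def _cond_ml_loglik(ystar, Cstar, s, Gstar, g_bg, g_exo):
    n = ystar.shape[0]
    cov = _LowRankCov(g_bg * s + 1.0, Gstar, g_exo)
    ViC = cov.vinv(Cstar)
    Viy = cov.vinv(ystar)
    CtVC = Cstar.T @ ViC
    CtVy = Cstar.T @ Viy
    try:
        alpha = np.linalg.solve(CtVC, CtVy)
    except np.linalg.LinAlgError:
        return -np.inf, None
    rss = float(ystar @ Viy - CtVy @ alpha)
    if rss <= 0:
        return -np.inf, None
    ll = (
        -0.5 * n * (np.log(2 * np.pi) + 1.0)
        - 0.5 * n * np.log(rss / n)
        - 0.5 * cov.logdet
    )
    return float(ll), (rss, cov)


def fit_null_conditioned(
    y: np.ndarray,
    K: Kinship,
    exo: np.ndarray,
    covariates: np.ndarray | None = None,
    max_rank: int | None = None,
) -> ConditionedNullFit:
    """ML fit of ``y ~ N(C a, sigma_bg^2 K + sigma_exo^2 G G^T + sigma_n^2 I)``.

    Exogenous-gene columns are standardized to unit variance (so sigma_exo^2
    is on the per-gene variance scale).  The two variance ratios are profiled
    on a coarse log grid including the zero boundaries, then refined by
    Nelder-Mead in log space.  Columns beyond ``max_rank`` are truncated
    (callers order them by relevance) with a log message.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    G = _standardize_columns(exo)
    if max_rank is not None and G.shape[1] > max_rank:
        logger.info(
            "conditioning set truncated from %d to max rank %d",
            G.shape[1], max_rank,
        )
        G = G[:, :max_rank]
    R = G.shape[1]
    if R < 1:
        raise ValueError("need at least one exogenous gene")
    C = _design(n, covariates)
    if n <= C.shape[1]:
        raise ValueError("need more samples than fixed effects")
    s, U = K.eigendecomposition()
    ystar = U.T @ y
    Cstar = U.T @ C
    Gstar = U.T @ G

    def ll_at(g_bg: float, g_exo: float) -> float:
        return _cond_ml_loglik(ystar, Cstar, s, Gstar, g_bg, g_exo)[0]

    # coarse profile over the two variance ratios, sharing per-g_bg work
    grid = np.concatenate([[0.0], np.logspace(-2.5, 2.5, 6)])
    best = (-np.inf, 0.0, 0.0)
    B = np.column_stack([Cstar, ystar])
    p = Cstar.shape[1]
    I_R = np.eye(R)
    for g_bg in grid:
        d = g_bg * s + 1.0
        sum_log_d = float(np.sum(np.log(d)))
        DiB = B / d[:, None]
        DiG = Gstar / d[:, None]
        GtDiG = Gstar.T @ DiG
        GtDiB = Gstar.T @ DiB
        BtDiB = B.T @ DiB
        for g_exo in grid:
            if g_exo == 0.0:
                BtViB = BtDiB
                logdet = sum_log_d
            else:
                M = I_R / g_exo + GtDiG
                try:
                    sol = np.linalg.solve(M, GtDiB)
                except np.linalg.LinAlgError:
                    continue
                BtViB = BtDiB - GtDiB.T @ sol
                sign, ld_m = np.linalg.slogdet(I_R + g_exo * GtDiG)
                logdet = sum_log_d + float(ld_m)
            CtVC = BtViB[:p, :p]
            CtVy = BtViB[:p, p]
            try:
                alpha = np.linalg.solve(CtVC, CtVy)
            except np.linalg.LinAlgError:
                continue
            rss = float(BtViB[p, p] - CtVy @ alpha)
            if rss <= 0:
                continue
            ll = (
                -0.5 * n * (np.log(2 * np.pi) + 1.0)
                - 0.5 * n * np.log(rss / n)
                - 0.5 * logdet
            )
            if ll > best[0]:
                best = (ll, float(g_bg), float(g_exo))
    _, g_bg, g_exo = best

    def refine_2d(bg0: float, ex0: float):
        res = optimize.minimize(
            lambda t: -ll_at(np.exp(t[0]), np.exp(t[1])),
            [np.log(bg0), np.log(ex0)],
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": 200},
        )
        return -res.fun, float(np.exp(res.x[0])), float(np.exp(res.x[1]))

    def refine_1d(which: str, g0: float):
        other_zero = 0.0
        if which == "bg":
            neg = lambda t: -ll_at(np.exp(t), other_zero)  # noqa: E731
        else:
            neg = lambda t: -ll_at(other_zero, np.exp(t))  # noqa: E731
        res = optimize.minimize_scalar(
            neg, bounds=(np.log(g0) - 3.0, np.log(g0) + 3.0),
            method="bounded", options={"xatol": 1e-9},
        )
        g = float(np.exp(res.x))
        return (-res.fun, g, 0.0) if which == "bg" else (-res.fun, 0.0, g)

    candidates = [best]
    if g_bg > 0 and g_exo > 0:
        candidates.append(refine_2d(g_bg, g_exo))
    elif g_bg == 0 and g_exo > 0:
        candidates.append(refine_1d("exo", g_exo))
        candidates.append(refine_2d(1e-4, g_exo))
    elif g_exo == 0 and g_bg > 0:
        candidates.append(refine_1d("bg", g_bg))
        candidates.append(refine_2d(g_bg, 1e-4))
    ll_best, g_bg, g_exo = max(candidates, key=lambda c: c[0])

    ll, aux = _cond_ml_loglik(ystar, Cstar, s, Gstar, g_bg, g_exo)
    rss, cov = aux
    sigma_n2 = rss / n
    return ConditionedNullFit(
        sigma_bg2=sigma_n2 * g_bg,
        sigma_exo2=sigma_n2 * g_exo,
        sigma_n2=sigma_n2,
        loglik=ll,
        rotation=(s, U),
        y_rot=ystar,
        C_rot=Cstar,
        cov=cov,
        n_conditioned=R,
    )


def lmm_assoc_conditioned(
    x: np.ndarray,
    y: np.ndarray,
    null_background: Kinship,
    exo: np.ndarray,
    covariates: np.ndarray | None = None,
    max_rank: int | None = 10,
    null: ConditionedNullFit | None = None,
) -> AssociationResult:
    """Variant LRT conditioning on exogenous-gene expression as a low-rank
    random effect.  Variance components are refit on the null of this
    (gene, conditioning set) pair unless a prefit ``null`` is supplied, then
    held fixed for the test."""
    if null is None:
        null = fit_null_conditioned(y, null_background, exo, covariates, max_rank)
    x = _prepare_x(x)
    s, U = null.rotation
    xstar = (U.T @ x)[:, None]
    n = len(x)
    rss0, rss1, beta = _gls_scan_stats(
        null.y_rot, null.C_rot, xstar, null.cov.vinv
    )
    lrt = max(n * np.log(rss0 / max(rss1[0], 1e-300)), 0.0)
    return AssociationResult(
        float(beta[0]), _lrt_pvalue(lrt), float(lrt), null.n_conditioned
    )


def scan_conditioned(
    X_dosages: np.ndarray,
    null: ConditionedNullFit,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Test many variants against one conditioned null fit (vectorized).

    Returns (pvalues, betas, lrt) arrays over the variant columns.
    """
    X = _impute_dosage_mean(np.atleast_2d(X_dosages))
    if X.shape[0] != len(null.y_rot):
        X = X.T
    informative = X.std(axis=0) > 0
    s, U = null.rotation
    Xstar = U.T @ X
    n = X.shape[0]
    rss0, rss1, beta = _gls_scan_stats(null.y_rot, null.C_rot, Xstar, null.cov.vinv)
    pv, beta = _finalize_scan_row(n, rss0, rss1, beta, informative)
    with np.errstate(divide="ignore", invalid="ignore"):
        lrt = np.where(informative, np.maximum(n * np.log(rss0 / np.maximum(rss1, 1e-300)), 0.0), np.nan)
    return pv, beta, lrt
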