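"""Alternative association methods benchmarked against the network-guided
scan, all sharing the mixed-model engine.

* ``lmm``            — the plain Step-1 scan (baseline).
* ``pc-lmm``         — top principal components of the expression matrix as
                       a second random-effect covariance.
* ``pcselect-lmm``   — as pc-lmm, but PCs that show a genetic association
                       (any BH q-value < 0.2 when mapped as quantitative
                       traits) are excluded before conditioning.
* ``ice-lmm``        — second random effect from the empirical expression
                       covariance Y Y^T / T (genes standardized).
* ``ideal-lmm``      — oracle: conditions on the true parents of the focal
                       gene that are independent of the tested variant, and
                       on the true confounder factors.
* ``coreg-lmm``      — deliberately misspecified oracle: conditions on genes
                       co-regulated by the tested variant (downstream genes
                       such as gene D), which is known to cost power.

All methods consume identical inputs and emit an
:class:`~gnetlmm.lmm.AssociationScan` of the same shape, so they can be
swapped into any downstream evaluation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .data import ExpressionData, GenotypeData, check_paired
from .lmm import (
    AssociationScan,
    Kinship,
    fit_null,
    fit_null_conditioned,
    scan,
    scan_conditioned,
    _finalize_scan_row,
    _gls_scan_stats,
    _impute_dosage_mean,
    _standardize_columns,
)
from .simulate import NetworkTruth

logger = logging.getLogger("gnetlmm")

__all__ = [
    "ComparatorSpec",
    "run_pc_lmm",
    "run_ice_lmm",
    "run_oracle_lmm",
    "choose_n_pcs",
]

PC_GRID = (10, 20, 30, 40, 50)


@dataclass
class ComparatorSpec:
    method: str = "lmm"
    n_pcs: tuple[int, ...] = PC_GRID
    pc_qval_cutoff: float = 0.2

    METHODS = ("lmm", "ideal-lmm", "coreg-lmm", "pc-lmm", "pcselect-lmm", "ice-lmm")

    def __post_init__(self) -> None:
        if self.method not in self.METHODS:
            raise ValueError(f"unknown method {self.method!r}")


def _plain_gene_row(y, K, Xstar, informative, covariates):
    null = fit_null(y, K, covariates)
    w = null.weights

    def vinv(B, w=w):
        return B / (w[:, None] if B.ndim == 2 else w)

    rss0, rss1, beta = _gls_scan_stats(null.y_rot, null.C_rot, Xstar, vinv)
    return _finalize_scan_row(len(y), rss0, rss1, beta, informative)


def _scan_all_conditioned(
    genotypes: GenotypeData,
    expression: ExpressionData,
    K: Kinship,
    exo: np.ndarray,
    covariates: np.ndarray | None,
) -> AssociationScan:
    """Scan every gene against every variant with one shared conditioning
    matrix as a low-rank random effect (components refit per gene)."""
    t = expression.n_genes
    f = genotypes.n_variants
    pvals = np.full((t, f), np.nan)
    betas = np.full((t, f), np.nan)
    for j in range(t):
        null_c = fit_null_conditioned(
            expression.values[:, j], K, exo, covariates
        )
        pvals[j], betas[j], _ = scan_conditioned(genotypes.dosages, null_c)
    return AssociationScan(
        pvals, betas, expression.gene_ids, genotypes.variant_ids,
        np.full((t, f), exo.shape[1], dtype=int),
    )


# ---------------------------------------------------------------------------
# PCA-based adjustment
# ---------------------------------------------------------------------------

def _expression_pcs(expression: ExpressionData, n_pcs: int) -> np.ndarray:
    """Top PC score vectors of the column-standardized expression matrix,
    standardized to unit variance."""
    Z = _standardize_columns(expression.values)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :n_pcs] * s[:n_pcs]
    return _standardize_columns(scores)


def run_pc_lmm(
    genotypes: GenotypeData,
    expression: ExpressionData,
    K: Kinship,
    n_pcs: int,
    select: bool = False,
    covariates: np.ndarray | None = None,
    qval_cutoff: float = 0.2,
) -> AssociationScan:
    """Mixed-model scan with expression PCs as a second random effect.

    With ``select=True``, each PC is first mapped as a quantitative trait;
    PCs with any Benjamini-Hochberg q-value < ``qval_cutoff`` across the
    PC x variant tests are considered genetically driven and excluded.
    ``n_pcs=0`` (or all PCs excluded) falls back to the plain scan.
    """
    check_paired(genotypes, expression)
    if n_pcs >= genotypes.n_samples:
        raise ValueError("n_pcs must be smaller than the sample size")
    if n_pcs == 0:
        return scan(genotypes, expression, K, covariates)
    scores = _expression_pcs(expression, n_pcs)
    if select:
        pc_expr = ExpressionData(
            values=scores,
            gene_ids=np.array([f"pc{i}" for i in range(scores.shape[1])]),
            chrom=np.array(["0"] * scores.shape[1]),
            tss=np.zeros(scores.shape[1], dtype=np.int64),
        )
        pc_scan = scan(genotypes, pc_expr, K, covariates)
        pv = pc_scan.pvalues
        flat = pv[np.isfinite(pv)]
        qv = np.full_like(pv, np.nan)
        if flat.size:
            qv[np.isfinite(pv)] = multipletests(flat, method="fdr_bh")[1]
        genetic = np.nansum(qv < qval_cutoff, axis=1) > 0
        scores = scores[:, ~genetic]
        if scores.shape[1] == 0:
            warnings.warn(
                "all PCs associated with genotype; falling back to plain LMM",
                stacklevel=2,
            )
            return scan(genotypes, expression, K, covariates)
    return _scan_all_conditioned(genotypes, expression, K, scores, covariates)


def choose_n_pcs(
    genotypes: GenotypeData,
    expression: ExpressionData,
    K: Kinship,
    grid: tuple[int, ...] = PC_GRID,
    select: bool = False,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    trans_window: int = 5_000_000,
) -> tuple[int, AssociationScan]:
    """Pick the PC count from the grid maximizing the number of trans
    associations (Bonferroni-adjusted p < alpha outside the trans window)."""
    same = expression.chrom[:, None] == genotypes.chrom[None, :]
    dist = np.abs(expression.tss[:, None] - genotypes.pos[None, :])
    trans = ~(same & (dist <= trans_window))
    best = (-1, None, None)
    for n_pcs in grid:
        s = run_pc_lmm(genotypes, expression, K, n_pcs, select, covariates)
        adj = np.minimum(s.pvalues * s.pvalues.size, 1.0)
        count = int(np.nansum((adj < alpha) & trans))
        if count > best[0]:
            best = (count, n_pcs, s)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# ICE: empirical expression covariance as random effect
# ---------------------------------------------------------------------------

def run_ice_lmm(
    genotypes: GenotypeData,
    expression: ExpressionData,
    K: Kinship,
    covariates: np.ndarray | None = None,
    exclude_focal: bool = True,
) -> AssociationScan:
    """Scan with the empirical expression covariance of the other genes
    (Y_-j Y_-j^T, genes standardized) as a second random effect, three
    variance components per gene.

    The focal gene is excluded from the covariance by default: with the
    focal gene included the marginal likelihood is unbounded (the low-rank
    term can reproduce y exactly while the profiled noise variance goes to
    zero), so the fit degenerates.  ``exclude_focal=False`` restores the
    all-genes covariance for sensitivity analysis."""
    check_paired(genotypes, expression)
    t = expression.n_genes
    if t < 2:
        raise ValueError("ICE requires at least two genes")
    if not exclude_focal:
        return _scan_all_conditioned(
            genotypes, expression, K, expression.values, covariates
        )
    f = genotypes.n_variants
    pvals = np.full((t, f), np.nan)
    betas = np.full((t, f), np.nan)
    for j in range(t):
        exo = np.delete(expression.values, j, axis=1)
        null_c = fit_null_conditioned(expression.values[:, j], K, exo, covariates)
        pvals[j], betas[j], _ = scan_conditioned(genotypes.dosages, null_c)
    return AssociationScan(
        pvals, betas, expression.gene_ids, genotypes.variant_ids,
        np.full((t, f), t - 1, dtype=int),
    )


# ---------------------------------------------------------------------------
# Oracle models (simulation truth available)
# ---------------------------------------------------------------------------

def run_oracle_lmm(
    genotypes: GenotypeData,
    expression: ExpressionData,
    K: Kinship,
    truth: NetworkTruth,
    mode: str = "ideal",
    covariates: np.ndarray | None = None,
) -> AssociationScan:
    """Condition using the planted network instead of discovered V-structures.

    ``ideal``: for each (variant, gene C) test, condition on the true parents
    of C that are not downstream of the variant, plus the true confounder
    factors loading on C.  ``coreg``: condition on genes co-regulated by the
    variant (other genes downstream of it) — the harmful choice.
    Tests with an empty set fall back to the plain LMM.
    """
    if mode not in ("ideal", "coreg"):
        raise ValueError("mode must be 'ideal' or 'coreg'")
    if truth is None:
        raise ValueError("simulation truth is required for oracle models")
    check_paired(genotypes, expression)
    t = expression.n_genes
    n = expression.n_samples
    f = genotypes.n_variants
    desc = {v: truth.descendants_of_variant(v) for v in range(f)}
    conf_of_gene = [
        np.nonzero(truth.confounder_loadings[:, g])[0] if truth.confounder_loadings.size else np.array([], dtype=int)
        for g in range(t)
    ]

    X = _impute_dosage_mean(genotypes.dosages)
    informative = X.std(axis=0) > 0
    s_eig, U = K.eigendecomposition()
    Xstar = U.T @ X

    pvals = np.full((t, f), np.nan)
    betas = np.full((t, f), np.nan)
    ncond = np.zeros((t, f), dtype=int)
    for g in range(t):
        # snps grouped by identical conditioning set
        groups: dict[tuple, list[int]] = {}
        for v in range(f):
            if mode == "ideal":
                genes = tuple(
                    int(p) for p in truth.parents(g) if int(p) not in desc[v]
                )
                key = (genes, tuple(int(c) for c in conf_of_gene[g]))
            else:
                genes = tuple(sorted(d for d in desc[v] if d != g))
                key = (genes, ())
            groups.setdefault(key, []).append(v)
        for (genes, confs), snps in groups.items():
            cols = []
            if genes:
                cols.append(expression.values[:, list(genes)])
            if confs:
                cols.append(truth.confounder_factors[:, list(confs)])
            if not cols:
                pv, beta = _plain_gene_row(
                    expression.values[:, g], K, Xstar[:, snps],
                    informative[snps], covariates,
                )
            else:
                exo = np.column_stack(cols)
                # confounder factors or duplicated columns can be collinear;
                # drop exact zero-variance columns defensively
                null_c = fit_null_conditioned(
                    expression.values[:, g], K, exo, covariates
                )
                pv, beta, _ = scan_conditioned(genotypes.dosages[:, snps], null_c)
                ncond[g, snps] = exo.shape[1]
            pvals[g, snps] = pv
            betas[g, snps] = beta
    return AssociationScan(
        pvals, betas, expression.gene_ids, genotypes.variant_ids, ncond
    )
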