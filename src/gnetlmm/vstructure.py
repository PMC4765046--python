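"""V-structure (collider) discovery for exogenous-gene selection.

For every association test between a variant (SNP A) and a focal gene C, the
method searches for gene quartets (SNP A, gene A, gene C, gene B) whose
dependence pattern identifies the collider gene A -> gene C <- gene B:

1. gene A and gene C are dependent,
2. gene B and gene C are dependent,
3. gene A and gene B are marginally independent,
4. gene A and gene B become dependent after conditioning on gene C,
5. SNP A is associated with the anchor gene A (cis or trans),
6. SNP A is independent of gene B.

Criterion 6 is a guard: it rules out conditioning on genes that are
themselves under the genetic control of the tested variant, which would
create synthetic associations.  Genes B accepted for a given (SNP A, gene C)
pair are *exogenous* — they carry incoming regulatory or confounding signal
into gene C while being unrelated to the causal path from SNP A — and are
safe to condition on.

Dependence between genes uses a Pearson correlation test; independence is
declared when the raw p-value exceeds a threshold (a pragmatic criterion,
not a calibrated test).  SNP-gene (in)dependence uses the mixed-model
association p-values from the initial scan.  Partial correlations are only
evaluated when the marginal criteria (1)-(3) and the anchor condition
already hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import ExpressionData, GenotypeData
from .lmm import AssociationScan

__all__ = [
    "ThresholdConfig",
    "VStructure",
    "ConditioningSets",
    "correlation_test",
    "partial_correlation_test",
    "find_anchor_genes",
    "find_vstructures",
    "build_conditioning_sets",
]


@dataclass
class ThresholdConfig:
    """(In)dependence thresholds for the V-structure criteria.

    Dependence calls use Bonferroni-adjusted p-values; independence calls use
    raw p-values.  The adjustment family sizes default to the number of gene
    pairs examined per focal gene (dependence) and the total number of
    SNP-gene tests (anchor), and can be overridden.
    """

    p_dep: float = 0.01        # adjusted p for (conditional) gene-gene dependence
    p_ind: float = 0.1         # raw p for gene-gene independence
    p_anchor: float = 0.05     # adjusted p for SNP-anchor association
    p_snp_ind: float = 0.1     # raw p for SNP-exogenous-gene independence
    anchor_mode: str = "cis"   # cis | trans
    cis_window: int = 1_000_000
    dep_family_size: int | None = None     # default: T - 1 per focal gene
    anchor_family_size: int | None = None  # default: T * F
    partial_condition: str = "expression"  # expression | both

    def __post_init__(self) -> None:
        for name in ("p_dep", "p_ind", "p_anchor", "p_snp_ind"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not self.p_dep < self.p_ind:
            raise ValueError("p_dep must be smaller than p_ind")
        if self.anchor_mode not in ("cis", "trans"):
            raise ValueError("anchor_mode must be 'cis' or 'trans'")
        if self.partial_condition not in ("expression", "both"):
            raise ValueError("partial_condition must be 'expression' or 'both'")

    @classmethod
    def basic_preset(cls, **kw) -> "ThresholdConfig":
        """Stricter thresholds for small (few-gene) simulated designs.

        With only a handful of genes the dependence calls use raw p-values
        at p < 0.001 (family size 1) instead of the adjusted p < 0.01 rule.
        """
        kw.setdefault("p_dep", 0.001)
        kw.setdefault("p_ind", 0.1)
        kw.setdefault("p_anchor", 0.001)
        kw.setdefault("dep_family_size", 1)
        kw.setdefault("anchor_family_size", 1)
        return cls(**kw)


@dataclass(frozen=True)
class VStructure:
    """One accepted quartet (SNP A, gene A, gene C, gene B)."""

    snp_index: int
    anchor_gene: int
    focal_gene: int
    exo_gene: int
    r_AC: float
    r_BC: float
    r_AB: float
    r_AB_given_C: float
    p_partial: float

    def __post_init__(self) -> None:
        if len({self.anchor_gene, self.focal_gene, self.exo_gene}) != 3:
            raise ValueError("anchor, focal and exogenous genes must be distinct")


@dataclass
class ConditioningSets:
    """Per-(SNP, focal gene) lists of exogenous gene indices.

    Lists are deduplicated and ordered by ascending partial-correlation
    p-value so that rank truncation is deterministic.
    """

    sets: dict[tuple[int, int], list[int]] = field(default_factory=dict)
    partial_pvalues: dict[tuple[int, int], list[float]] = field(default_factory=dict)

    def genes(self, snp: int, focal: int) -> list[int]:
        return self.sets.get((snp, focal), [])

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, key: tuple[int, int]) -> bool:
        return key in self.sets


# ---------------------------------------------------------------------------
# correlation machinery
# ---------------------------------------------------------------------------

def _corr_pvalue(r: np.ndarray, dof: int) -> np.ndarray:
    """Two-sided p-value of a (partial) correlation from its t statistic."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(dof / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(tstat), df=dof)


def correlation_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with the two-sided t test (N - 2 df)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    n = a.shape[0]
    if n < 4:
        raise ValueError("need at least 4 observations")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input")
    r = float(np.corrcoef(a, b)[0, 1])
    return r, float(_corr_pvalue(r, n - 2))


def partial_correlation_test(
    a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> tuple[float, float]:
    """First-order partial correlation r_AB|C with the t test (N - 3 df).

    r_AB|C = (r_AB - r_AC r_BC) / sqrt((1 - r_AC^2)(1 - r_BC^2)); identical
    to the correlation of the residuals of a and b after regressing out c.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    c = np.asarray(c, dtype=float).ravel()
    n = a.shape[0]
    if n < 5:
        raise ValueError("need at least 5 observations")
    r_ab = np.corrcoef(a, b)[0, 1]
    r_ac = np.corrcoef(a, c)[0, 1]
    r_bc = np.corrcoef(b, c)[0, 1]
    r, p = _partial_from_marginals(r_ab, r_ac, r_bc, n)
    return r, p


def _partial_from_marginals(
    r_ab: float, r_ac: float, r_bc: float, n: int
) -> tuple[float, float]:
    denom = (1.0 - r_ac**2) * (1.0 - r_bc**2)
    if denom <= 1e-12:
        raise ValueError("degenerate conditioning")
    r = (r_ab - r_ac * r_bc) / np.sqrt(denom)
    r = float(np.clip(r, -1.0, 1.0))
    return r, float(_corr_pvalue(r, n - 3))


def _correlation_matrices(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise gene-gene correlations and their raw p-values."""
    n = Y.shape[0]
    R = np.corrcoef(Y, rowvar=False)
    P = _corr_pvalue(R, n - 2)
    np.fill_diagonal(P, 0.0)
    return R, P


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def _in_cis_window(
    genotypes: GenotypeData, expression: ExpressionData, window: int
) -> np.ndarray:
    """Boolean T x F matrix: gene TSS within +-window of the variant
    (inclusive), same chromosome."""
    same_chrom = expression.chrom[:, None] == genotypes.chrom[None, :]
    dist = np.abs(expression.tss[:, None] - genotypes.pos[None, :])
    return same_chrom & (dist <= window)


def find_anchor_genes(
    scan: AssociationScan,
    genotypes: GenotypeData,
    expression: ExpressionData,
    cfg: ThresholdConfig,
) -> dict[int, list[int]]:
    """Map each variant to its anchor genes (criterion 5).

    A gene anchors a SNP when its Bonferroni-adjusted association p-value is
    strictly below ``p_anchor``; in cis mode the gene's TSS must additionally
    lie within ``cis_window`` of the variant.  An empty map is valid and
    makes the downstream algorithm revert to the plain LMM.
    """
    t, f = scan.shape
    family = cfg.anchor_family_size or (t * f)
    with np.errstate(invalid="ignore"):
        adj = np.minimum(scan.pvalues * family, 1.0)
    hit = adj < cfg.p_anchor
    hit &= ~np.isnan(scan.pvalues)
    if cfg.anchor_mode == "cis":
        hit &= _in_cis_window(genotypes, expression, cfg.cis_window)
    anchors: dict[int, list[int]] = {}
    genes, snps = np.nonzero(hit)
    for g, s in zip(genes, snps):
        anchors.setdefault(int(s), []).append(int(g))
    return anchors


# ---------------------------------------------------------------------------
# V-structure search
# ---------------------------------------------------------------------------

def find_vstructures(
    anchors: dict[int, list[int]],
    scan: AssociationScan,
    expression: ExpressionData,
    genotypes: GenotypeData,
    cfg: ThresholdConfig,
) -> list[VStructure]:
    """Exhaustive search over anchored quartets satisfying all six criteria.

    Partial correlations (criterion 4) are computed lazily, only for
    candidates that already satisfy the marginal criteria (1)-(3), the
    anchor condition (5) and the SNP-independence guard (6).  Candidate
    focal genes exclude the anchor gene itself and genes in the cis window
    of the tested variant.
    """
    Y = expression.values
    n, t = Y.shape
    R, P = _correlation_matrices(Y)
    dep_family = cfg.dep_family_size or max(t - 1, 1)
    P_adj = np.minimum(P * dep_family, 1.0)
    dep = P_adj < cfg.p_dep
    cis_mask = _in_cis_window(genotypes, expression, cfg.cis_window)

    x_c_cache: dict[int, np.ndarray | None] = {}

    def best_cis_variant(focal: int, snp: int) -> np.ndarray | None:
        # strongest scan hit within the focal gene's cis window (optional
        # extra conditioning variable for the sensitivity switch)
        if focal not in x_c_cache:
            cand = np.nonzero(cis_mask[focal])[0]
            if len(cand) == 0:
                x_c_cache[focal] = None
            else:
                pv = scan.pvalues[focal, cand]
                if np.all(np.isnan(pv)):
                    x_c_cache[focal] = None
                else:
                    x_c_cache[focal] = genotypes.dosages[
                        :, cand[int(np.nanargmin(pv))]
                    ]
        return x_c_cache[focal]

    out: list[VStructure] = []
    for snp, anchor_genes in sorted(anchors.items()):
        snp_p = scan.pvalues[:, snp]
        for a in sorted(anchor_genes):
            # focal candidates: dependent on the anchor, outside the cis
            # region of the tested variant, not the anchor itself
            focal_ok = dep[a] & ~cis_mask[:, snp]
            focal_ok[a] = False
            for c in np.nonzero(focal_ok)[0]:
                b_ok = (
                    dep[:, c]                      # (2) dep(y_B, y_C)
                    & (P[a] >= cfg.p_ind)          # (3) ind(y_A, y_B), raw p
                    & (snp_p >= cfg.p_snp_ind)     # (6) ind(x_A, y_B), raw p
                )
                b_ok[[a, c]] = False
                for b in np.nonzero(b_ok)[0]:
                    try:
                        r_abc, p_abc = _partial_from_marginals(
                            R[a, b], R[a, c], R[b, c], n
                        )
                    except ValueError:
                        continue  # degenerate conditioning; cannot accept
                    if min(p_abc * dep_family, 1.0) >= cfg.p_dep:
                        continue
                    if cfg.partial_condition == "both":
                        xc = best_cis_variant(int(c), snp)
                        if xc is not None and xc.std() > 0:
                            _, p_x = partial_correlation_test(Y[:, a], Y[:, b], xc)
                            if min(p_x * dep_family, 1.0) >= cfg.p_dep:
                                continue
                    out.append(
                        VStructure(
                            snp_index=int(snp),
                            anchor_gene=int(a),
                            focal_gene=int(c),
                            exo_gene=int(b),
                            r_AC=float(R[a, c]),
                            r_BC=float(R[b, c]),
                            r_AB=float(R[a, b]),
                            r_AB_given_C=r_abc,
                            p_partial=p_abc,
                        )
                    )
    return out


def build_conditioning_sets(vstructures: list[VStructure]) -> ConditioningSets:
    """Group exogenous genes by (SNP, focal gene), deduplicated and ordered
    by ascending partial-correlation p-value (ties broken by gene index)."""
    acc: dict[tuple[int, int], dict[int, float]] = {}
    for v in vstructures:
        key = (v.snp_index, v.focal_gene)
        genes = acc.setdefault(key, {})
        prev = genes.get(v.exo_gene)
        if prev is None or v.p_partial < prev:
            genes[v.exo_gene] = v.p_partial
    cs = ConditioningSets()
    for key, genes in acc.items():
        ordered = sorted(genes.items(), key=lambda kv: (kv[1], kv[0]))
        cs.sets[key] = [g for g, _ in ordered]
        cs.partial_pvalues[key] = [p for _, p in ordered]
    return cs
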