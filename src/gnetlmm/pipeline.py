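"""Three-step orchestration of the network-guided association scan.

Step 1  Genome-wide mixed-model eQTL scan (all genes x all variants).
Step 2  Anchor detection and V-structure search, yielding per-(SNP, gene)
        conditioning sets of exogenous genes.
Step 3  Re-test every (SNP, gene) pair that received a nonempty conditioning
        set, with the exogenous genes as an extra low-rank random effect;
        all other entries are copied unchanged from Step 1.

Tests in Step 3 are grouped by unique (focal gene, conditioning set) so the
three variance components are fit once per group and reused across that
group's variants.  When no anchor or no V-structure is found the updated
scan is identical to the Step-1 scan (the method reverts to a plain LMM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as gio
from .data import ExpressionData, GenotypeData, check_paired
from .lmm import (
    AssociationScan,
    Kinship,
    fit_null,
    fit_null_conditioned,
    realized_relationship,
    scan,
    scan_conditioned,
    _gls_scan_stats,
    _finalize_scan_row,
    _impute_dosage_mean,
)
from .vstructure import (
    ConditioningSets,
    ThresholdConfig,
    VStructure,
    build_conditioning_sets,
    find_anchor_genes,
    find_vstructures,
)

logger = logging.getLogger("gnetlmm")

__all__ = ["GNetLMMResult", "run_gnetlmm", "permutation_calibration"]

CHECKPOINT_SCAN = "scan_step1.tsv"
CHECKPOINT_VSTRUCT = "vstructures.tsv"
CHECKPOINT_UPDATED = "scan_updated.tsv"


@dataclass
class GNetLMMResult:
    """Full output of one run: both scans, the V-structures, the
    conditioning sets and a provenance record (config snapshot + seed)."""

    initial_scan: AssociationScan
    updated_scan: AssociationScan
    vstructures: list[VStructure]
    conditioning: ConditioningSets
    provenance: dict = field(default_factory=dict)
    kinship: Kinship | None = None


def _conditioning_groups(
    conditioning: ConditioningSets, max_rank: int
) -> dict[tuple[int, tuple[int, ...]], list[int]]:
    """Group (snp, focal) keys by unique truncated conditioning set."""
    groups: dict[tuple[int, tuple[int, ...]], list[int]] = {}
    for (snp, focal) in sorted(conditioning.sets):
        genes = tuple(conditioning.sets[(snp, focal)][:max_rank])
        groups.setdefault((focal, genes), []).append(snp)
    return groups


def run_gnetlmm(
    genotypes: GenotypeData,
    expression: ExpressionData,
    covariates: np.ndarray | None = None,
    cfg: ThresholdConfig | None = None,
    K: Kinship | None = None,
    max_rank: int = 10,
    seed: int = 0,
    out_dir=None,
) -> GNetLMMResult:
    """Run the full three-step algorithm.

    ``out_dir`` enables per-step TSV checkpoints; an interrupted run resumes
    from whichever checkpoints exist and produces results identical to an
    uninterrupted run.
    """
    check_paired(genotypes, expression)
    cfg = cfg or ThresholdConfig()
    if K is None:
        K = realized_relationship(genotypes)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # Step 1: genome-wide scan
    ckpt = out / CHECKPOINT_SCAN if out else None
    if ckpt is not None and ckpt.exists():
        logger.info("resuming Step 1 scan from %s", ckpt)
        initial = gio.read_scan(ckpt)
    else:
        initial = scan(genotypes, expression, K, covariates)
        if ckpt is not None:
            gio.write_scan(initial, ckpt)

    # Step 2: anchors and V-structures
    ckpt = out / CHECKPOINT_VSTRUCT if out else None
    if ckpt is not None and ckpt.exists():
        logger.info("resuming Step 2 V-structures from %s", ckpt)
        vstructs = gio.read_vstructures(ckpt, genotypes, expression)
    else:
        anchors = find_anchor_genes(initial, genotypes, expression, cfg)
        vstructs = find_vstructures(anchors, initial, expression, genotypes, cfg)
        if ckpt is not None:
            gio.write_vstructures(vstructs, ckpt, genotypes, expression)
    conditioning = build_conditioning_sets(vstructs)

    # Step 3: conditioned re-tests, grouped by unique conditioning set
    ckpt = out / CHECKPOINT_UPDATED if out else None
    if ckpt is not None and ckpt.exists():
        logger.info("resuming Step 3 update from %s", ckpt)
        updated = gio.read_scan(ckpt)
    else:
        updated = initial.copy()
        groups = _conditioning_groups(conditioning, max_rank)
        for (focal, genes), snps in groups.items():
            exo = expression.values[:, list(genes)]
            null_c = fit_null_conditioned(
                expression.values[:, focal], K, exo, covariates
            )
            pv, beta, _ = scan_conditioned(genotypes.dosages[:, snps], null_c)
            updated.pvalues[focal, snps] = pv
            updated.betas[focal, snps] = beta
            updated.n_conditioned[focal, snps] = len(genes)
        if ckpt is not None:
            gio.write_scan(updated, ckpt)

    provenance = {
        "seed": seed,
        "max_rank": max_rank,
        "thresholds": {
            k: v for k, v in vars(cfg).items() if not k.startswith("_")
        },
        "kinship_kind": K.kind,
        "n_vstructures": len(vstructs),
        "n_conditioning_sets": len(conditioning),
    }
    return GNetLMMResult(initial, updated, vstructs, conditioning, provenance, K)


def permutation_calibration(
    genotypes: GenotypeData,
    expression: ExpressionData,
    result: GNetLMMResult,
    n_perm: int = 10,
    seed: int = 0,
    covariates: np.ndarray | None = None,
    max_rank: int = 10,
    pairs_per_stratum: int | None = None,
) -> dict[str, np.ndarray]:
    """Empirical null for the final association tests.

    The sample order of each tested genotype vector is permuted (breaking
    any SNP-gene link while preserving the expression covariance and the
    identified conditioning sets), and only the final association tests are
    re-run with the variance components held at their unpermuted fits.
    Returns the permuted p-values stratified by presence ("with_exo") or
    absence ("without_exo") of exogenous genes.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    check_paired(genotypes, expression)
    rng = np.random.default_rng(seed)
    K = result.kinship or realized_relationship(genotypes)
    n = genotypes.n_samples
    X = _impute_dosage_mean(genotypes.dosages)
    perms = [rng.permutation(n) for _ in range(n_perm)]

    groups = _conditioning_groups(result.conditioning, max_rank)
    with_pairs = [
        (snp, focal) for (focal, _), snps in groups.items() for snp in snps
    ]

    # conditioned stratum
    p_with: list[np.ndarray] = []
    for (focal, genes), snps in groups.items():
        exo = expression.values[:, list(genes)]
        null_c = fit_null_conditioned(
            expression.values[:, focal], K, exo, covariates
        )
        for perm in perms:
            pv, _, _ = scan_conditioned(X[perm][:, snps], null_c)
            p_with.append(pv)

    # unconditioned stratum: sample pairs without exogenous genes
    t, f = result.updated_scan.shape
    taken = set(with_pairs)
    all_pairs = [
        (s, g) for g in range(t) for s in range(f) if (s, g) not in taken
    ]
    k = pairs_per_stratum or max(len(with_pairs), 1)
    k = min(k, len(all_pairs))
    idx = rng.choice(len(all_pairs), size=k, replace=False)
    chosen = [all_pairs[i] for i in sorted(idx)]
    by_gene: dict[int, list[int]] = {}
    for s, g in chosen:
        by_gene.setdefault(g, []).append(s)
    p_without: list[np.ndarray] = []
    for g, snps in by_gene.items():
        null = fit_null(expression.values[:, g], K, covariates)
        s_eig, U = null.rotation
        w = null.weights

        def vinv(B, w=w):
            return B / (w[:, None] if B.ndim == 2 else w)

        for perm in perms:
            Xp = U.T @ X[perm][:, snps]
            informative = X[perm][:, snps].std(axis=0) > 0
            rss0, rss1, beta = _gls_scan_stats(null.y_rot, null.C_rot, Xp, vinv)
            pv, _ = _finalize_scan_row(n, rss0, rss1, beta, informative)
            p_without.append(pv)

    return {
        "with_exo": np.concatenate(p_with) if p_with else np.array([]),
        "without_exo": np.concatenate(p_without) if p_without else np.array([]),
    }
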