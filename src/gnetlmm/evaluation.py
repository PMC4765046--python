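"""Benchmark evaluation: truth labelling, partial-AUC power, hotspot
stratification and calibration summaries.

Power is the area under the ROC curve restricted to false-positive rates
below 5 %, reported both raw and normalized by the FPR cap (so a perfect
ranking scores 1).  An association (variant, gene C) counts as a true
positive when some direct regulator of gene C has a planted cis anchor
within +-2 kb of the tested variant; associations within +-5 Mb of the
focal gene's own locus are treated as putative cis signals and excluded
from the ROC.  All windows are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionData, GenotypeData
from .lmm import AssociationScan
from .simulate import NetworkTruth

__all__ = [
    "LabelledAssociations",
    "PowerResult",
    "label_truth",
    "partial_auc",
    "hotspot_table",
    "qq_calibration",
    "roc_curve",
]

TP = "TP"
FP = "FP"
EXCLUDED = "excluded-cis"


@dataclass
class LabelledAssociations:
    """Long-format records (snp, gene, pvalue, label)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"snp_index", "gene_index", "pvalue", "label"}
        if not required <= set(self.records.columns):
            raise ValueError(f"records must carry columns {sorted(required)}")

    def roc_records(self) -> pd.DataFrame:
        """TP/FP records with finite p-values; excluded-cis never enters."""
        r = self.records
        mask = r["label"].isin([TP, FP]) & np.isfinite(r["pvalue"])
        return r[mask]


@dataclass
class PowerResult:
    partial_auc_raw: float
    power: float
    n_tp: int
    n_fp: int


def label_truth(
    scan: AssociationScan,
    truth: NetworkTruth,
    genotypes: GenotypeData,
    expression: ExpressionData,
    tp_window_bp: int = 2_000,
    cis_exclusion_bp: int = 5_000_000,
) -> LabelledAssociations:
    """Label every scan entry as TP, FP or excluded-cis.

    A gene's genomic position is that of its planted cis-anchor variant when
    one exists, its annotated TSS otherwise.
    """
    t, f = scan.shape
    pos_v = genotypes.pos
    chrom_v = genotypes.chrom
    gene_pos = np.array(
        [
            pos_v[truth.cis_anchor[g]] if g in truth.cis_anchor else expression.tss[g]
            for g in range(t)
        ]
    )
    gene_chrom = np.array(
        [
            chrom_v[truth.cis_anchor[g]] if g in truth.cis_anchor else expression.chrom[g]
            for g in range(t)
        ]
    )
    # cis-exclusion mask: variant near the focal gene's own locus
    cis_excl = (gene_chrom[:, None] == chrom_v[None, :]) & (
        np.abs(gene_pos[:, None] - pos_v[None, :]) <= cis_exclusion_bp
    )
    # TP mask: variant within tp_window of the anchor of a direct regulator
    tp_mask = np.zeros((t, f), dtype=bool)
    for g in range(t):
        for parent in np.nonzero(truth.adjacency[:, g])[0]:
            if int(parent) not in truth.cis_anchor:
                continue
            a = truth.cis_anchor[int(parent)]
            near = (chrom_v == chrom_v[a]) & (
                np.abs(pos_v - pos_v[a]) <= tp_window_bp
            )
            tp_mask[g] |= near
    label = np.where(cis_excl, EXCLUDED, np.where(tp_mask, TP, FP))
    gi, vi = np.meshgrid(np.arange(t), np.arange(f), indexing="ij")
    records = pd.DataFrame(
        {
            "snp_index": vi.ravel(),
            "gene_index": gi.ravel(),
            "pvalue": scan.pvalues.ravel(),
            "label": label.ravel(),
        }
    )
    return LabelledAssociations(records)


def roc_curve(labels: LabelledAssociations) -> pd.DataFrame:
    """Full ROC coordinates (fpr, tpr, pvalue threshold) for plotting.

    Same ranking and tie-block convention as :func:`partial_auc`.
    """
    rec = labels.roc_records()
    n_tp = int((rec["label"] == TP).sum())
    n_fp = int((rec["label"] == FP).sum())
    if n_tp == 0 or n_fp == 0:
        raise ValueError("ROC requires at least one TP and one FP")
    order = np.argsort(rec["pvalue"].to_numpy(), kind="mergesort")
    p = rec["pvalue"].to_numpy()[order]
    is_tp = (rec["label"].to_numpy() == TP)[order]
    thresholds, block_start = np.unique(p, return_index=True)
    block_end = np.append(block_start[1:], len(p))
    rows = [{"fpr": 0.0, "tpr": 0.0, "pvalue": 0.0}]
    ctp = cfp = 0
    for thr, s, e in zip(thresholds, block_start, block_end):
        ctp += int(is_tp[s:e].sum())
        cfp += int((~is_tp[s:e]).sum())
        rows.append({"fpr": cfp / n_fp, "tpr": ctp / n_tp, "pvalue": thr})
    return pd.DataFrame(rows)


def partial_auc(
    labels: LabelledAssociations, fpr_max: float = 0.05
) -> PowerResult:
    """Partial area under the ROC for FPR in [0, fpr_max].

    Associations are ranked by ascending p-value; tied p-values are
    processed as a block (linear ROC segment, i.e. the averaged step).
    ``power`` normalizes the area by fpr_max so a perfect ranking scores 1.
    """
    rec = labels.roc_records()
    n_tp = int((rec["label"] == TP).sum())
    n_fp = int((rec["label"] == FP).sum())
    if n_tp == 0:
        raise ValueError("undefined power: no true positives")
    if n_fp == 0:
        raise ValueError("undefined power: no false positives")
    order = np.argsort(rec["pvalue"].to_numpy(), kind="mergesort")
    p = rec["pvalue"].to_numpy()[order]
    is_tp = (rec["label"].to_numpy() == TP)[order]
    # tie blocks
    _, block_start = np.unique(p, return_index=True)
    block_end = np.append(block_start[1:], len(p))
    tpr = [0.0]
    fpr = [0.0]
    ctp = cfp = 0
    for s, e in zip(block_start, block_end):
        ctp += int(is_tp[s:e].sum())
        cfp += int((~is_tp[s:e]).sum())
        tpr.append(ctp / n_tp)
        fpr.append(cfp / n_fp)
    fpr = np.asarray(fpr)
    tpr = np.asarray(tpr)
    if fpr_max < fpr[-1]:
        tpr_cap = float(np.interp(fpr_max, fpr, tpr))
        keep = fpr <= fpr_max
        fpr = np.append(fpr[keep], fpr_max)
        tpr = np.append(tpr[keep], tpr_cap)
    area = float(np.trapezoid(tpr, fpr))
    return PowerResult(area, area / fpr_max, n_tp, n_fp)


def hotspot_table(
    scan: AssociationScan,
    genotypes: GenotypeData,
    expression: ExpressionData,
    significance_grid: tuple[float, ...] = (1e-4, 1e-6, 1e-8),
    trans_window_bp: int = 5_000_000,
) -> pd.DataFrame:
    """Per-variant counts of trans-regulated genes at each threshold.

    An association counts as trans only when the gene's TSS lies outside
    ``trans_window_bp`` of the variant (or on another chromosome).  Returns
    a long table (threshold, variant_id, n_regulated_genes); summing the
    counts per threshold gives the total number of trans associations.
    """
    same = expression.chrom[:, None] == genotypes.chrom[None, :]
    dist = np.abs(expression.tss[:, None] - genotypes.pos[None, :])
    trans = ~(same & (dist <= trans_window_bp))
    rows = []
    pv = scan.pvalues
    for thr in significance_grid:
        with np.errstate(invalid="ignore"):
            hits = (pv < thr) & trans & np.isfinite(pv)
        counts = hits.sum(axis=0)
        for v in range(scan.shape[1]):
            rows.append(
                {
                    "threshold": thr,
                    "variant_id": scan.variant_ids[v],
                    "n_regulated_genes": int(counts[v]),
                }
            )
    return pd.DataFrame(rows)


def qq_calibration(pvalues: np.ndarray) -> tuple[float, float, float]:
    """Calibration summary of null p-values.

    Returns the Kolmogorov-Smirnov statistic and p-value against U(0, 1)
    and the fraction of p-values below the nominal 0.05 level.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("need at least 100 null p-values")
    ks = stats.kstest(p, "uniform")
    return float(ks.statistic), float(ks.pvalue), float(np.mean(p < 0.05))
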