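"""Core data containers: genotype and expression matrices with genomic annotation.

Conventions
-----------
* Samples index rows everywhere: genotypes are ``N x F`` (samples x variants),
  expression is ``N x T`` (samples x genes).
* Dosages use the additive {0, 1, 2} minor-allele count coding.  Missing
  genotypes are stored as ``numpy.nan``; imputation is deferred to the model
  layer.
* All genomic coordinates are 1-based and windows are inclusive of both
  endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeData", "ExpressionData"]

#: Sentinel used for missing dosages in text formats (out of the {0,1,2} range).
MISSING_DOSAGE_CODE = -9


@dataclass
class GenotypeData:
    """Sample-by-variant dosage matrix with per-variant genomic annotation.

    Parameters
    ----------
    dosages
        ``N x F`` array with entries in {0, 1, 2} or NaN for missing.
    variant_ids
        ``F`` unique variant identifiers.
    chrom
        ``F`` chromosome labels.
    pos
        ``F`` 1-based base-pair positions.
    """

    dosages: np.ndarray
    variant_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x variants matrix")
        self.variant_ids = np.asarray(self.variant_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, f = self.dosages.shape
        if n < 2:
            raise ValueError("need at least two samples")
        for name, arr in (
            ("variant_ids", self.variant_ids),
            ("chrom", self.chrom),
            ("pos", self.pos),
        ):
            if arr.shape != (f,):
                raise ValueError(f"{name} must have length F={f}")
        if len(set(self.variant_ids.tolist())) != f:
            raise ValueError("variant_ids must be unique")
        if np.any(self.pos < 0):
            raise ValueError("positions must be non-negative")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.all(np.isin(observed, (0.0, 1.0, 2.0))):
            raise ValueError("non-missing dosages must lie in {0, 1, 2}")
        if self.sample_ids is not None:
            self.sample_ids = np.asarray(self.sample_ids)
            if self.sample_ids.shape != (n,):
                raise ValueError("sample_ids must have length N")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class ExpressionData:
    """Sample-by-gene expression matrix with per-gene TSS annotation."""

    values: np.ndarray
    gene_ids: np.ndarray
    chrom: np.ndarray
    tss: np.ndarray
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes matrix")
        self.gene_ids = np.asarray(self.gene_ids)
        self.chrom = np.asarray(self.chrom)
        self.tss = np.asarray(self.tss, dtype=np.int64)
        n, t = self.values.shape
        for name, arr in (
            ("gene_ids", self.gene_ids),
            ("chrom", self.chrom),
            ("tss", self.tss),
        ):
            if arr.shape != (t,):
                raise ValueError(f"{name} must have length T={t}")
        if len(set(self.gene_ids.tolist())) != t:
            raise ValueError("gene_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.sample_ids is not None:
            self.sample_ids = np.asarray(self.sample_ids)
            if self.sample_ids.shape != (n,):
                raise ValueError("sample_ids must have length N")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


def check_paired(genotypes: GenotypeData, expression: ExpressionData) -> None:
    """Raise if the two datasets do not share the sample dimension."""
    if genotypes.n_samples != expression.n_samples:
        raise ValueError(
            f"sample dimension mismatch: {genotypes.n_samples} genotype rows "
            f"vs {expression.n_samples} expression rows"
        )
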