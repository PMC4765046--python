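"""Readers and writers for the supported on-disk formats.

Formats
-------
Genotypes
    * TSV matrix: rows are variants, first column ``variant_id``, remaining
      header fields are sample ids; values in {0, 1, 2} or the missing
      sentinel ``-9``.  A companion annotation TSV has columns
      ``variant_id, chrom, pos`` (1-based positions).
    * PLINK BED/BIM/FAM (variant-major BED); dosages count the A1 allele
      (conventionally the minor allele), PLINK missing codes honoured.
Expression
    TSV matrix: rows are genes, first column ``gene_id``, header sample ids;
    companion annotation TSV with columns ``gene_id, chrom, tss``.
Association scans
    Long-format TSV: ``gene_id, variant_id, beta, pvalue, n_conditioned``.
V-structures
    TSV: ``snp_id, anchor_gene, focal_gene, exo_gene, r_AC, r_BC, r_AB,
    r_AB_given_C, p_partial``.

Imputation of missing genotypes happens in the model layer, not at read
time.  All writers emit files their paired readers parse back to equal
in-memory values.
"""

from __future__ import annotations

import dataclasses
import logging
import struct
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data import MISSING_DOSAGE_CODE, ExpressionData, GenotypeData
from .lmm import AssociationScan
from .simulate import SimParams
from .vstructure import ThresholdConfig, VStructure

logger = logging.getLogger("gnetlmm")

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_expression",
    "write_expression",
    "read_scan",
    "write_scan",
    "read_vstructures",
    "write_vstructures",
    "quantile_normalize",
    "residualize_and_normalize",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _read_annotation(path, id_col: str, cols: tuple[str, str]) -> pd.DataFrame:
    anno = pd.read_csv(path, sep="\t", dtype={id_col: str, cols[0]: str})
    missing = {id_col, *cols} - set(anno.columns)
    if missing:
        raise ValueError(f"annotation {path} lacks columns {sorted(missing)}")
    return anno.set_index(id_col)


def read_genotypes(
    path,
    format: str = "tsv",
    anno_path=None,
) -> GenotypeData:
    """Load genotypes from a TSV matrix + annotation, or PLINK BED/BIM/FAM.

    For ``format="plink-bed"`` pass the path of the ``.bed`` file (or its
    prefix); the ``.bim``/``.fam`` companions must sit alongside it.
    """
    if format == "plink-bed":
        return _read_plink_bed(path)
    if format != "tsv":
        raise ValueError(f"unknown genotype format: {format!r}")
    if anno_path is None:
        raise ValueError("TSV genotypes require an annotation path")
    mat = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = mat.columns[0]
    variant_ids = mat[id_col].astype(str).to_numpy()
    values = mat.drop(columns=[id_col]).to_numpy(dtype=float).T  # N x F
    values[values == MISSING_DOSAGE_CODE] = np.nan
    bad = values[~np.isnan(values)]
    if bad.size and not np.all(np.isin(bad, (0.0, 1.0, 2.0))):
        raise ValueError(
            "genotype TSV contains values outside {0,1,2} and the missing "
            f"sentinel {MISSING_DOSAGE_CODE}"
        )
    anno = _read_annotation(anno_path, "variant_id", ("chrom", "pos"))
    missing = [v for v in variant_ids if v not in anno.index]
    if missing:
        raise ValueError(f"variants lacking annotation: {missing[:5]} ...")
    anno = anno.loc[variant_ids]
    sample_ids = np.array([str(c) for c in mat.columns[1:]])
    return GenotypeData(
        dosages=values,
        variant_ids=variant_ids,
        chrom=anno["chrom"].to_numpy(),
        pos=anno["pos"].to_numpy(dtype=np.int64),
        sample_ids=sample_ids,
    )


def write_genotypes(geno: GenotypeData, path, anno_path) -> None:
    sample_ids = (
        geno.sample_ids
        if geno.sample_ids is not None
        else np.array([f"s{i}" for i in range(geno.n_samples)])
    )
    values = geno.dosages.T.copy()  # F x N
    values[np.isnan(values)] = MISSING_DOSAGE_CODE
    df = pd.DataFrame(values.astype(int), columns=sample_ids)
    df.insert(0, "variant_id", geno.variant_ids)
    df.to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        {"variant_id": geno.variant_ids, "chrom": geno.chrom, "pos": geno.pos}
    ).to_csv(anno_path, sep="\t", index=False)


def _read_plink_bed(path) -> GenotypeData:
    """Minimal variant-major PLINK1 BED reader (with .bim/.fam)."""
    path = Path(path)
    prefix = path.with_suffix("") if path.suffix == ".bed" else path
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "variant_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "variant_id": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n = len(fam)
    f = len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if len(raw) < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise ValueError("malformed PLINK BED magic bytes")
    if raw[2] != 0x01:
        raise ValueError("only variant-major PLINK BED files are supported")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_variant * f:
        raise ValueError("PLINK BED size does not match BIM/FAM dimensions")
    body = body.reshape(f, bytes_per_variant)
    # unpack 2-bit genotype codes, sample-fastest within each byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(f, -1)[:, :n]
    # 00 -> 2 copies of A1, 10 -> 1, 11 -> 0, 01 -> missing
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[codes].T  # N x F
    sample_ids = fam[1].astype(str).to_numpy()
    return GenotypeData(
        dosages=dosages,
        variant_ids=bim["variant_id"].to_numpy(),
        chrom=bim["chrom"].to_numpy(),
        pos=bim["pos"].to_numpy(dtype=np.int64),
        sample_ids=sample_ids,
    )


def write_plink_bed(geno: GenotypeData, prefix) -> None:
    """Write variant-major PLINK1 BED/BIM/FAM (round-trip companion)."""
    prefix = Path(prefix)
    n, f = geno.dosages.shape
    sample_ids = (
        geno.sample_ids
        if geno.sample_ids is not None
        else np.array([f"s{i}" for i in range(n)])
    )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for i in range(f):
            fh.write(
                f"{geno.chrom[i]}\t{geno.variant_ids[i]}\t0\t{geno.pos[i]}\tA\tG\n"
            )
    code_of = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    out = bytearray(struct.pack("3B", 0x6C, 0x1B, 0x01))
    for i in range(f):
        col = geno.dosages[:, i]
        byte = 0
        for j in range(n):
            v = col[j]
            code = 0b01 if np.isnan(v) else code_of[float(v)]
            byte |= code << ((j % 4) * 2)
            if j % 4 == 3:
                out.append(byte)
                byte = 0
        if n % 4:
            out.append(byte)
    prefix.with_suffix(".bed").write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression(path, anno_path) -> ExpressionData:
    """Load an expression matrix and align it with its gene annotation.

    Genes without an annotation entry are dropped (logged); duplicated gene
    ids are an error.  The result is invariant to annotation row order.
    """
    mat = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = mat.columns[0]
    gene_ids = mat[id_col].astype(str).to_numpy()
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicated gene ids in expression matrix")
    values = mat.drop(columns=[id_col]).to_numpy(dtype=float).T  # N x T
    anno = _read_annotation(anno_path, "gene_id", ("chrom", "tss"))
    keep = np.array([g in anno.index for g in gene_ids])
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d genes lacking annotation", n_drop)
    gene_ids = gene_ids[keep]
    values = values[:, keep]
    anno = anno.loc[gene_ids]
    sample_ids = np.array([str(c) for c in mat.columns[1:]])
    return ExpressionData(
        values=values,
        gene_ids=gene_ids,
        chrom=anno["chrom"].to_numpy(),
        tss=anno["tss"].to_numpy(dtype=np.int64),
        sample_ids=sample_ids,
    )


def write_expression(expr: ExpressionData, path, anno_path) -> None:
    sample_ids = (
        expr.sample_ids
        if expr.sample_ids is not None
        else np.array([f"s{i}" for i in range(expr.n_samples)])
    )
    df = pd.DataFrame(expr.values.T, columns=sample_ids)
    df.insert(0, "gene_id", expr.gene_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(
        {"gene_id": expr.gene_ids, "chrom": expr.chrom, "tss": expr.tss}
    ).to_csv(anno_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# association scans
# ---------------------------------------------------------------------------

def write_scan(scan: AssociationScan, path) -> None:
    t, f = scan.shape
    gi, vi = np.meshgrid(np.arange(t), np.arange(f), indexing="ij")
    pd.DataFrame(
        {
            "gene_id": scan.gene_ids[gi.ravel()],
            "variant_id": scan.variant_ids[vi.ravel()],
            "beta": scan.betas.ravel(),
            "pvalue": scan.pvalues.ravel(),
            "n_conditioned": scan.n_conditioned.ravel(),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scan(path) -> AssociationScan:
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "variant_id": str},
        float_precision="round_trip",
    )
    gene_ids = df["gene_id"].drop_duplicates().to_numpy()
    variant_ids = df["variant_id"].drop_duplicates().to_numpy()
    t, f = len(gene_ids), len(variant_ids)
    if len(df) != t * f:
        raise ValueError("scan TSV is not a complete gene x variant grid")
    shape = (t, f)
    return AssociationScan(
        pvalues=df["pvalue"].to_numpy().reshape(shape),
        betas=df["beta"].to_numpy().reshape(shape),
        gene_ids=gene_ids,
        variant_ids=variant_ids,
        n_conditioned=df["n_conditioned"].to_numpy(dtype=int).reshape(shape),
    )


# ---------------------------------------------------------------------------
# V-structures
# ---------------------------------------------------------------------------

def write_vstructures(
    vstructures: list[VStructure],
    path,
    genotypes: GenotypeData,
    expression: ExpressionData,
) -> None:
    rows = [
        {
            "snp_id": genotypes.variant_ids[v.snp_index],
            "anchor_gene": expression.gene_ids[v.anchor_gene],
            "focal_gene": expression.gene_ids[v.focal_gene],
            "exo_gene": expression.gene_ids[v.exo_gene],
            "r_AC": v.r_AC,
            "r_BC": v.r_BC,
            "r_AB": v.r_AB,
            "r_AB_given_C": v.r_AB_given_C,
            "p_partial": v.p_partial,
        }
        for v in vstructures
    ]
    cols = [
        "snp_id", "anchor_gene", "focal_gene", "exo_gene",
        "r_AC", "r_BC", "r_AB", "r_AB_given_C", "p_partial",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_vstructures(
    path, genotypes: GenotypeData, expression: ExpressionData
) -> list[VStructure]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    snp_idx = {v: i for i, v in enumerate(genotypes.variant_ids)}
    gene_idx = {g: i for i, g in enumerate(expression.gene_ids)}
    return [
        VStructure(
            snp_index=snp_idx[row.snp_id],
            anchor_gene=gene_idx[row.anchor_gene],
            focal_gene=gene_idx[row.focal_gene],
            exo_gene=gene_idx[row.exo_gene],
            r_AC=float(row.r_AC),
            r_BC=float(row.r_BC),
            r_AB=float(row.r_AB),
            r_AB_given_C=float(row.r_AB_given_C),
            p_partial=float(row.p_partial),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# covariates and simulation truth
# ---------------------------------------------------------------------------

def read_covariates(path) -> np.ndarray:
    """Covariate TSV: header row, first column sample id, numeric columns."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return df.drop(columns=[df.columns[0]]).to_numpy(dtype=float)


def write_truth(truth, prefix) -> None:
    """Serialize a :class:`~gnetlmm.simulate.NetworkTruth` as a TSV trio
    (edges, anchors, confounder loadings) plus a JSON variance record."""
    import json

    prefix = Path(prefix)
    src, dst = np.nonzero(truth.adjacency)
    pd.DataFrame(
        {"src": src, "dst": dst, "weight": truth.weights[src, dst]}
    ).to_csv(f"{prefix}.edges.tsv", sep="\t", index=False, float_format="%.17g")
    items = sorted(truth.cis_anchor.items())
    pd.DataFrame(
        {"gene": [g for g, _ in items], "variant": [v for _, v in items]}
    ).to_csv(f"{prefix}.anchors.tsv", sep="\t", index=False)
    ci, gi = np.nonzero(truth.confounder_loadings)
    pd.DataFrame(
        {"confounder": ci, "gene": gi,
         "loading": truth.confounder_loadings[ci, gi]}
    ).to_csv(f"{prefix}.loadings.tsv", sep="\t", index=False, float_format="%.17g")
    record = {
        "n_genes": int(truth.n_genes),
        "n_confounders": int(truth.confounder_loadings.shape[0]),
        "variance_fractions": truth.variance_fractions.tolist(),
        "confounder_factors": truth.confounder_factors.tolist(),
    }
    Path(f"{prefix}.variance.json").write_text(json.dumps(record))


def read_truth(prefix):
    import json

    from .simulate import NetworkTruth

    prefix = Path(prefix)
    record = json.loads(Path(f"{prefix}.variance.json").read_text())
    t = record["n_genes"]
    c = record["n_confounders"]
    edges = pd.read_csv(f"{prefix}.edges.tsv", sep="\t")
    adjacency = np.zeros((t, t), dtype=int)
    weights = np.zeros((t, t))
    adjacency[edges["src"], edges["dst"]] = 1
    weights[edges["src"], edges["dst"]] = edges["weight"]
    anchors = pd.read_csv(f"{prefix}.anchors.tsv", sep="\t")
    cis_anchor = dict(zip(anchors["gene"].astype(int), anchors["variant"].astype(int)))
    loadings = np.zeros((c, t))
    ld = pd.read_csv(f"{prefix}.loadings.tsv", sep="\t")
    if len(ld):
        loadings[ld["confounder"], ld["gene"]] = ld["loading"]
    return NetworkTruth(
        adjacency=adjacency,
        weights=weights,
        cis_anchor=cis_anchor,
        confounder_loadings=loadings,
        variance_fractions=np.array(record["variance_fractions"]),
        confounder_factors=np.array(record["confounder_factors"]).reshape(
            -1, c if c else 0
        ),
    )


# ---------------------------------------------------------------------------
# preprocessing utilities
# ---------------------------------------------------------------------------

def quantile_normalize(y: np.ndarray) -> np.ndarray:
    """Map ranks to standard-normal quantiles: Phi^-1((rank - 0.5) / n).

    Ties receive the average rank.  The output is the same multiset of
    normal quantiles for any permutation of the input.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if np.all(y == y[0]):
        raise ValueError("cannot quantile-normalize a constant vector")
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - 0.5) / y.shape[0])


def residualize_and_normalize(
    y: np.ndarray, covariates: np.ndarray
) -> np.ndarray:
    """Regress covariates out of y, then quantile-normalize the residuals."""
    y = np.asarray(y, dtype=float).ravel()
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != y.shape[0]:
        C = C.T
    C = np.column_stack([np.ones(y.shape[0]), C])
    coef, *_ = np.linalg.lstsq(C, y, rcond=None)
    return quantile_normalize(y - C @ coef)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Flat key=value run configuration (dotted keys for nested sections)."""

    geno: str = ""
    expr: str = ""
    geno_anno: str = ""
    expr_anno: str = ""
    covar: str = ""
    out: str = ""
    seed: int = 0
    max_rank: int = 10
    log_level: str = "INFO"
    thresholds: ThresholdConfig = dataclasses.field(default_factory=ThresholdConfig)
    sim: SimParams = dataclasses.field(default_factory=SimParams)

    _SECTIONS = {"thresholds": ThresholdConfig, "sim": SimParams}

    def to_file(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            if f.name in self._SECTIONS:
                sub = getattr(self, f.name)
                for sf in dataclasses.fields(sub):
                    val = getattr(sub, sf.name)
                    if isinstance(val, tuple):
                        val = ",".join(str(v) for v in val)
                    lines.append(f"{f.name}.{sf.name}={val}")
            else:
                lines.append(f"{f.name}={getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cfg = cls()
        field_types = {f.name: f for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if "." in key:
                section, _, sub = key.partition(".")
                if section not in cls._SECTIONS:
                    raise ValueError(f"unknown config section: {section!r}")
                target = getattr(cfg, section)
                sub_fields = {f.name: f for f in dataclasses.fields(target)}
                if sub not in sub_fields:
                    raise ValueError(f"unknown config key: {key!r}")
                setattr(target, sub, _coerce(raw, getattr(target, sub)))
            else:
                if key not in field_types or key in cls._SECTIONS:
                    raise ValueError(f"unknown config key: {key!r}")
                setattr(cfg, key, _coerce(raw, getattr(cfg, key)))
        cfg.thresholds.__post_init__()
        cfg.sim.__post_init__()
        return cfg


def _coerce(raw: str, template):
    if isinstance(template, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(template, int):
        return int(raw)
    if isinstance(template, float):
        return float(raw)
    if isinstance(template, tuple):
        parts = [p for p in raw.split(",") if p]
        return tuple(type(template[0])(p) for p in parts)
    if template is None:
        if raw == "None":
            return None
        for cast in (int, float):
            try:
                return cast(raw)
            except ValueError:
                pass
        return raw
    if isinstance(template, str):
        return raw
    raise ValueError(f"cannot coerce config value {raw!r}")
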