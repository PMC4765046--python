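"""Synthetic eQTL data generation with planted regulatory networks.

The generator emulates the statistical structure of population eQTL panels:
quasi-independent common variants, per-gene cis anchor variants, directed
gene-gene regulatory networks (sparse random or star-shaped with hubs),
shared confounding factors and iid noise.  Gene expression is assembled in
topological order as a linear function of incoming edges, the cis variant,
confounders and noise, with each component rescaled so that its realized
sample-variance share equals the drawn budget exactly (the realized shares
are recorded in :class:`NetworkTruth` for evaluation).

Two families of designs are provided:

``simulate_basic``
    Four-gene motifs around a single causal variant (SNP A): the mediated
    power motif SNP A -> gene A; {gene A, gene B} -> gene C; gene C -> gene D,
    direct/trans variants with an ``alpha`` split of the SNP variance, and a
    confounder-driven null motif used for calibration studies (optionally
    with SNP A -> gene B, the synthetic-association guard design).

``simulate_network``
    100-gene networks (default), either sparse Bernoulli-edge DAGs or
    star-shaped topologies with nine hub regulators, each regulating
    20-50 % of the other genes.  Edge weights are drawn from an equal
    mixture of N(+1, 0.1^2) and N(-1, 0.1^2) so that edges have nonzero
    weight and balanced signs.

Genomic layout: one synthetic chromosome, variants spaced 20 Mb apart so
cis/trans windows (cis classification +-1 Mb, cis exclusion +-5 Mb, true
positive window +-2 kb) separate cleanly; an anchored gene's TSS sits 500 bp
downstream of its cis variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionData, GenotypeData

__all__ = [
    "SimParams",
    "NetworkTruth",
    "simulate_genotypes",
    "simulate_basic",
    "simulate_network",
]

#: Base-pair spacing between adjacent synthetic variants (one chromosome).
VARIANT_SPACING = 20_000_000
#: Offset of an anchored gene's TSS from its cis variant.
TSS_OFFSET = 500

BASIC_MOTIFS = ("power", "direct", "trans", "confounding")


@dataclass
class SimParams:
    """Simulation settings; defaults are the study conditions.

    Variance parameters are population-variance shares of a unit-variance
    gene: ``var_cis`` per cis anchor, ``var_network`` the joint share of
    network plus confounding, of which ``conf_fraction`` is confounding.
    """

    n_samples: int = 379
    n_variants: int | None = None
    n_genes: int = 100
    topology: str = "sparse"  # sparse | star
    var_cis: float = 0.10
    var_network: float = 0.80
    conf_fraction: float = 0.20
    n_confounders: int = 3
    conf_per_gene: float = 1.0
    alpha: float = 0.5
    p_edge: float = 0.02
    n_hubs: int = 9
    hub_frac_range: tuple[float, float] = (0.2, 0.5)
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.var_cis + self.var_network > 1.0 + 1e-12:
            raise ValueError("infeasible variance budget: var_cis + var_network > 1")
        if not 0.0 <= self.conf_fraction <= 1.0:
            raise ValueError("conf_fraction must lie in [0, 1]")
        if self.topology not in ("sparse", "star"):
            raise ValueError(f"unknown topology: {self.topology!r}")


@dataclass
class NetworkTruth:
    """Planted ground truth of one simulated dataset.

    ``adjacency[j, t] = 1`` means gene j regulates gene t (a directed acyclic
    graph).  ``cis_anchor`` maps gene index -> variant index of its planted
    cis variant.  ``variance_fractions`` records the realized per-gene shares
    (cis, network, confounding, noise).  ``confounder_factors`` holds the
    simulated factor values (N x C) so that oracle models can condition on
    the true confounders.
    """

    adjacency: np.ndarray
    weights: np.ndarray
    cis_anchor: dict[int, int]
    confounder_loadings: np.ndarray
    variance_fractions: np.ndarray  # T x 4: cis, network, confounding, noise
    confounder_factors: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=int)
        t = self.adjacency.shape[0]
        if self.adjacency.shape != (t, t):
            raise ValueError("adjacency must be square")
        if not np.array_equal(
            self.adjacency != 0, np.asarray(self.weights) != 0
        ):
            raise ValueError("weights must be nonzero exactly on adjacency edges")
        self.assert_acyclic()

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]

    def assert_acyclic(self) -> None:
        """Kahn's algorithm; raises if the adjacency contains a cycle."""
        adj = self.adjacency
        indeg = adj.sum(axis=0).astype(int).copy()
        queue = [i for i in range(len(indeg)) if indeg[i] == 0]
        seen = 0
        while queue:
            i = queue.pop()
            seen += 1
            for j in np.nonzero(adj[i])[0]:
                indeg[j] -= 1
                if indeg[j] == 0:
                    queue.append(int(j))
        if seen != len(indeg):
            raise ValueError("adjacency contains a cycle")

    def parents(self, gene: int) -> np.ndarray:
        return np.nonzero(self.adjacency[:, gene])[0]

    def descendants_of_variant(self, variant: int) -> set[int]:
        """All genes downstream of a variant's cis gene (inclusive)."""
        roots = [g for g, v in self.cis_anchor.items() if v == variant]
        out: set[int] = set()
        stack = list(roots)
        while stack:
            g = stack.pop()
            if g in out:
                continue
            out.add(g)
            stack.extend(int(j) for j in np.nonzero(self.adjacency[g])[0])
        return out


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _variant_positions(f: int) -> np.ndarray:
    return 1 + VARIANT_SPACING * np.arange(f, dtype=np.int64)


def simulate_genotypes(
    n: int = 379,
    f: int = 4030,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.Generator = 0,
) -> GenotypeData:
    """Independent common variants: dosage ~ Binomial(2, maf), maf ~ U(range).

    Default dimensions mirror a chromosome-wide panel of 379 individuals and
    4030 quasi-independent common variants.  Variants sit on one synthetic
    chromosome at 20 Mb spacing.
    """
    lo, hi = maf_range
    if not (0.05 - 1e-12 <= lo <= hi <= 0.5 + 1e-12):
        raise ValueError("maf_range must satisfy 0.05 <= lo <= hi <= 0.5")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=f)
    dosages = rng.binomial(2, maf, size=(n, f)).astype(float)
    return GenotypeData(
        dosages=dosages,
        variant_ids=np.array([f"snp{i}" for i in range(f)]),
        chrom=np.array(["1"] * f),
        pos=_variant_positions(f),
    )


def load_vcf_genotypes(
    path,
    maf_min: float = 0.05,
    ld_r2_max: float = 0.9,
    ld_window: int = 50,
    ld_step: int = 5,
) -> GenotypeData:
    """Optional real-genotype loader: VCF with MAF filtering and LD pruning.

    Variants with minor allele frequency below ``maf_min`` are discarded;
    local linkage disequilibrium is limited to r^2 <= ``ld_r2_max`` by
    greedy pruning within sliding windows of ``ld_window`` variants advanced
    by ``ld_step``, yielding a quasi-independent panel.  Requires ``cyvcf2``
    (only imported here; the simulator never needs it).
    """
    from cyvcf2 import VCF  # deferred optional dependency

    vcf = VCF(str(path), gts012=True)
    sample_ids = np.array(vcf.samples)
    rows, ids, chroms, poss = [], [], [], []
    for var in vcf:
        g = np.asarray(var.gt_types, dtype=float)  # 0/1/2, 3 = missing
        g[g == 3] = np.nan
        af = np.nanmean(g) / 2 if np.isfinite(g).any() else 0.0
        if min(af, 1 - af) < maf_min:
            continue
        rows.append(g)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if not rows:
        raise ValueError("no variants pass the MAF filter")
    X = np.asarray(rows).T  # N x F
    # greedy windowed LD pruning on the standardized dosages
    Xi = X.copy()
    nan_mask = np.isnan(Xi)
    if nan_mask.any():
        col_mean = np.where(
            np.all(nan_mask, axis=0), 0.0, np.nanmean(Xi, axis=0)
        )
        Xi[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    sd = Xi.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xi - Xi.mean(axis=0)) / sd
    f = Z.shape[1]
    keep = np.ones(f, dtype=bool)
    for start in range(0, max(f - ld_step, 1), ld_step):
        idx = [j for j in range(start, min(start + ld_window, f)) if keep[j]]
        for a_pos, a in enumerate(idx):
            if not keep[a]:
                continue
            for b in idx[a_pos + 1:]:
                if not keep[b]:
                    continue
                r = Z[:, a] @ Z[:, b] / Z.shape[0]
                if r * r > ld_r2_max:
                    keep[b] = False
    keep &= Xi.std(axis=0) > 0
    return GenotypeData(
        dosages=X[:, keep],
        variant_ids=np.asarray(ids)[keep],
        chrom=np.asarray(chroms)[keep],
        pos=np.asarray(poss, dtype=np.int64)[keep],
        sample_ids=sample_ids,
    )


# ---------------------------------------------------------------------------
# shared assembly helpers
# ---------------------------------------------------------------------------

def _std(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    sd = v.std()
    return v / sd if sd > 0 else v


def _mixture_weights(rng: np.random.Generator, size: int) -> np.ndarray:
    """Equal mixture of N(+1, 0.1^2) and N(-1, 0.1^2)."""
    signs = np.where(rng.random(size) < 0.5, 1.0, -1.0)
    return signs + 0.1 * rng.normal(size=size)


def _expression_meta(t: int, tss: np.ndarray) -> dict:
    return {
        "gene_ids": np.array([f"gene{i}" for i in range(t)]),
        "chrom": np.array(["1"] * t),
        "tss": tss.astype(np.int64),
    }


class _GeneAssembler:
    """Accumulate standardized components scaled to exact variance shares."""

    def __init__(self, n: int, rng_noise: np.random.Generator):
        self.n = n
        self.rng_noise = rng_noise
        self.components: list[np.ndarray] = []
        self.shares: list[float] = []

    def add(self, vector: np.ndarray, share: float, sign: float = 1.0) -> None:
        if share <= 0:
            return
        self.components.append(np.sign(sign) * _std(vector) * np.sqrt(share))
        self.shares.append(share)

    def finish(self) -> tuple[np.ndarray, float]:
        used = sum(self.shares)
        noise_share = max(1.0 - used, 0.0)
        noise = _std(self.rng_noise.normal(size=self.n)) * np.sqrt(noise_share)
        y = noise + sum(self.components, np.zeros(self.n))
        return y, noise_share


# ---------------------------------------------------------------------------
# basic four-gene motifs
# ---------------------------------------------------------------------------

def simulate_basic(
    motif: str,
    params: SimParams | None = None,
    seed: int | None = None,
    n_null_variants: int = 99,
    snp_to_b: bool = False,
) -> tuple[GenotypeData, ExpressionData, NetworkTruth]:
    """Simulate one of the four-gene motif designs around a single SNP A.

    motif = "power":       SNP A -> gene A; {gene A, gene B} -> gene C;
                           gene C -> gene D.  Cis anchor and every regulating
                           edge each explain 10-20 % of the target variance.
    motif = "direct":      SNP A -> {gene A, gene C}; {gene A, gene B} -> gene C;
                           the SNP variance share is split alpha : (1 - alpha)
                           between gene A and gene C.
    motif = "trans":       SNP A -> {gene A, gene D}; {gene A, gene B, gene D}
                           -> gene C; alpha splits the SNP share between gene A
                           and gene D.
    motif = "confounding": SNP A -> gene A (and gene B when ``snp_to_b``);
                           confounder A -> {gene A, gene C}; confounder B ->
                           {gene B, gene C}; the confounders jointly explain
                           50-70 % of each affected gene.  No SNP -> gene C
                           effect: a null design for calibration, and with
                           ``snp_to_b`` the synthetic-association guard design.
    """
    if motif not in BASIC_MOTIFS:
        raise ValueError(f"motif must be one of {BASIC_MOTIFS}")
    params = params or SimParams()
    seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_geno, rng_net, rng_conf, rng_noise = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    n = params.n_samples
    f = 1 + n_null_variants
    geno = simulate_genotypes(n, f, params.maf_range, rng_geno)
    x_a = geno.dosages[:, 0]

    t = 3 if motif == "confounding" else 4
    A, B, C = 0, 1, 2
    D = 3 if t == 4 else None

    adjacency = np.zeros((t, t), dtype=int)
    weights = np.zeros((t, t))
    cis_anchor = {A: 0}
    frac = np.zeros((t, 4))  # cis, network, confounding, noise
    Y = np.zeros((n, t))

    def edge_share() -> float:
        return rng_net.uniform(0.10, 0.20)

    def edge_sign() -> float:
        return float(np.sign(_mixture_weights(rng_net, 1)[0]))

    def put_edge(src: int, dst: int, w: float) -> None:
        adjacency[src, dst] = 1
        weights[src, dst] = w

    conf_factors = np.zeros((n, 0))
    conf_loadings = np.zeros((0, t))

    if motif == "confounding":
        conf_factors = rng_conf.normal(size=(n, 2))
        conf_loadings = np.zeros((2, t))
        # gene A: cis + confounder A
        asm = _GeneAssembler(n, rng_noise)
        cis_a = edge_share()
        asm.add(x_a, cis_a)
        ca = rng_conf.uniform(0.50, 0.70)
        asm.add(conf_factors[:, 0], ca)
        conf_loadings[0, A] = np.sqrt(ca)
        Y[:, A], noise_a = asm.finish()
        frac[A] = (cis_a, 0.0, ca, noise_a)
        # gene B: confounder B (+ optional cis from SNP A: the guard design)
        asm = _GeneAssembler(n, rng_noise)
        cis_b = 0.0
        if snp_to_b:
            cis_b = edge_share()
            asm.add(x_a, cis_b)
            cis_anchor[B] = 0
        cb = rng_conf.uniform(0.50, 0.70)
        asm.add(conf_factors[:, 1], cb)
        conf_loadings[1, B] = np.sqrt(cb)
        Y[:, B], noise_b = asm.finish()
        frac[B] = (cis_b, 0.0, cb, noise_b)
        # gene C: both confounders jointly 50-70 %, no genetic effect
        asm = _GeneAssembler(n, rng_noise)
        cc = rng_conf.uniform(0.50, 0.70)
        asm.add(conf_factors[:, 0], cc / 2)
        asm.add(conf_factors[:, 1], cc / 2)
        conf_loadings[0, C] = np.sqrt(cc / 2)
        conf_loadings[1, C] = np.sqrt(cc / 2)
        Y[:, C], noise_c = asm.finish()
        frac[C] = (0.0, 0.0, cc, noise_c)
    else:
        snp_share = edge_share()
        alpha = params.alpha
        # gene A
        asm = _GeneAssembler(n, rng_noise)
        cis_a = snp_share * alpha if motif in ("direct", "trans") else snp_share
        asm.add(x_a, cis_a)
        Y[:, A], noise_a = asm.finish()
        frac[A] = (cis_a, 0.0, 0.0, noise_a)
        # gene B: pure root
        asm = _GeneAssembler(n, rng_noise)
        Y[:, B], noise_b = asm.finish()
        frac[B] = (0.0, 0.0, 0.0, noise_b)
        # gene D first for the trans motif (it feeds gene C there)
        if motif == "trans":
            asm = _GeneAssembler(n, rng_noise)
            cis_d = snp_share * (1 - alpha)
            asm.add(x_a, cis_d)
            Y[:, D], noise_d = asm.finish()
            frac[D] = (cis_d, 0.0, 0.0, noise_d)
            cis_anchor[D] = 0
        # gene C
        asm = _GeneAssembler(n, rng_noise)
        net_c = 0.0
        for src in (A, B) + ((D,) if motif == "trans" else ()):
            share = edge_share()
            sign = edge_sign()
            asm.add(Y[:, src], share, sign)
            put_edge(src, C, sign * np.sqrt(share))
            net_c += share
        cis_c = 0.0
        if motif == "direct":
            cis_c = snp_share * (1 - alpha)
            asm.add(x_a, cis_c)
            cis_anchor[C] = 0
        Y[:, C], noise_c = asm.finish()
        frac[C] = (cis_c, net_c, 0.0, noise_c)
        # gene D downstream of gene C (power / direct motifs)
        if motif in ("power", "direct"):
            asm = _GeneAssembler(n, rng_noise)
            share = edge_share()
            sign = edge_sign()
            asm.add(Y[:, C], share, sign)
            put_edge(C, D, sign * np.sqrt(share))
            Y[:, D], noise_d = asm.finish()
            frac[D] = (0.0, share, 0.0, noise_d)

    # genomic layout: anchored genes sit by their variant, others far beyond
    tss = np.zeros(t, dtype=np.int64)
    far = _variant_positions(f)[-1] + VARIANT_SPACING
    for g in range(t):
        if g in cis_anchor:
            tss[g] = geno.pos[cis_anchor[g]] + TSS_OFFSET
        else:
            tss[g] = far + g * VARIANT_SPACING
    expr = ExpressionData(values=Y, **_expression_meta(t, tss))
    truth = NetworkTruth(
        adjacency=adjacency,
        weights=weights,
        cis_anchor=cis_anchor,
        confounder_loadings=conf_loadings,
        variance_fractions=frac,
        confounder_factors=conf_factors,
    )
    return geno, expr, truth


# ---------------------------------------------------------------------------
# 100-gene networks
# ---------------------------------------------------------------------------

def _draw_topology(params: SimParams, rng: np.random.Generator):
    """Adjacency + weights over a random topological order (acyclic)."""
    t = params.n_genes
    adjacency = np.zeros((t, t), dtype=int)
    order = rng.permutation(t)
    if params.topology == "sparse":
        for i in range(t):
            for j in range(i + 1, t):
                if rng.random() < params.p_edge:
                    adjacency[order[i], order[j]] = 1
    else:  # star
        n_hubs = min(params.n_hubs, t - 1)
        hubs = order[:n_hubs]
        others = order[n_hubs:]
        lo, hi = params.hub_frac_range
        for h in hubs:
            k = int(np.round(rng.uniform(lo, hi) * (t - 1)))
            k = min(k, len(others))
            targets = rng.choice(others, size=k, replace=False)
            adjacency[h, targets] = 1
    weights = np.zeros((t, t))
    edge_idx = np.nonzero(adjacency)
    weights[edge_idx] = _mixture_weights(rng, len(edge_idx[0]))
    return adjacency, weights, order


def simulate_network(
    params: SimParams | None = None,
    seed: int | None = None,
) -> tuple[GenotypeData, ExpressionData, NetworkTruth]:
    """Simulate a 100-gene regulatory network dataset (sparse or star).

    Every gene receives a cis variant explaining ``var_cis`` of its variance.
    The joint network + confounding share is ``var_network``, apportioned by
    ``conf_fraction``; the network part of a gene is split among its parents
    proportionally to the squared mixture weights, and unused shares (genes
    without parents or confounders) return to the noise budget.
    """
    params = params or SimParams()
    seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_geno, rng_net, rng_conf, rng_noise = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    t = params.n_genes
    n = params.n_samples
    f = params.n_variants or t
    if f < t:
        raise ValueError("need at least one variant per gene")
    geno = simulate_genotypes(n, f, params.maf_range, rng_geno)
    adjacency, weights, order = _draw_topology(params, rng_net)
    cis_anchor = {g: g for g in range(t)}

    conf_share_total = params.var_network * params.conf_fraction
    net_share_total = params.var_network - conf_share_total

    c = params.n_confounders
    if c > 0 and conf_share_total > 0:
        conf_factors = rng_conf.normal(size=(n, c))
        membership = rng_conf.random((c, t)) < min(params.conf_per_gene / c, 1.0)
        raw_load = _mixture_weights(rng_conf, c * t).reshape(c, t)
    else:
        conf_factors = np.zeros((n, 0))
        membership = np.zeros((0, t), dtype=bool)
        raw_load = np.zeros((0, t))

    Y = np.zeros((n, t))
    frac = np.zeros((t, 4))
    conf_loadings = np.zeros_like(raw_load)
    for g in order:  # topological order: parents are simulated first
        asm = _GeneAssembler(n, rng_noise)
        asm.add(geno.dosages[:, cis_anchor[g]], params.var_cis)
        parents = np.nonzero(adjacency[:, g])[0]
        net_g = 0.0
        if len(parents) and net_share_total > 0:
            w = weights[parents, g]
            shares = net_share_total * w**2 / np.sum(w**2)
            for p, share, wj in zip(parents, shares, w):
                asm.add(Y[:, p], share, np.sign(wj))
            net_g = net_share_total
        confs = np.nonzero(membership[:, g])[0] if membership.size else []
        conf_g = 0.0
        if len(confs) and conf_share_total > 0:
            lw = raw_load[confs, g]
            shares = conf_share_total * lw**2 / np.sum(lw**2)
            for ci, share, lj in zip(confs, shares, lw):
                asm.add(conf_factors[:, ci], share, np.sign(lj))
                conf_loadings[ci, g] = np.sign(lj) * np.sqrt(share)
            conf_g = conf_share_total
        Y[:, g], noise_g = asm.finish()
        frac[g] = (params.var_cis, net_g, conf_g, noise_g)

    tss = geno.pos[[cis_anchor[g] for g in range(t)]] + TSS_OFFSET
    expr = ExpressionData(values=Y, **_expression_meta(t, tss))
    truth = NetworkTruth(
        adjacency=adjacency,
        weights=weights,
        cis_anchor=cis_anchor,
        confounder_loadings=conf_loadings,
        variance_fractions=frac,
        confounder_factors=conf_factors,
    )
    return geno, expr, truth
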