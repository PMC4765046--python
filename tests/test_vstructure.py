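"""Collider discovery: correlation machinery, anchor detection and the six
(in)dependence criteria, checked against brute-force re-evaluation."""

import numpy as np
import pytest
from scipy import stats

from gnetlmm import (
    SimParams,
    ThresholdConfig,
    build_conditioning_sets,
    correlation_test,
    find_anchor_genes,
    find_vstructures,
    partial_correlation_test,
    realized_relationship,
    scan,
    simulate_basic,
)
from gnetlmm.lmm import AssociationScan
from gnetlmm.vstructure import VStructure


class TestCorrelationTest:
    def test_perfect_correlation(self, rng):
        a = rng.normal(size=10)
        r, p = correlation_test(a, a)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_orthogonal_vectors_give_p_one(self):
        a = np.array([1.0, -1.0] * 5)
        b = np.array([1.0, 1.0, -1.0, -1.0] * 2 + [0.0, 0.0])
        r, p = correlation_test(a, b)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_permutation_null(self, rng):
        a = rng.normal(size=50)
        b = 0.3 * a + rng.normal(size=50)
        r_obs, p_t = correlation_test(a, b)
        n_perm = 100_000
        perm_r = np.empty(n_perm)
        bc = b - b.mean()
        ac = a - a.mean()
        denom = np.sqrt((ac @ ac) * (bc @ bc))
        for i in range(n_perm):
            perm_r[i] = ac @ rng.permutation(bc) / denom
        p_perm = (1 + np.sum(np.abs(perm_r) >= abs(r_obs))) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_t - p_perm) <= 3 * se + 1e-4

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_test(np.ones(10), np.arange(10.0))

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="at least 4"):
            correlation_test(np.arange(3.0), np.arange(3.0))


class TestPartialCorrelation:
    def test_algebraic_zero_when_r_ab_equals_product(self, rng):
        # construct c, then a and b with r_ab = r_ac * r_bc via shared c-part
        n = 2000
        c = rng.normal(size=n)
        a = 0.6 * c + rng.normal(size=n) * 0.8
        b = 0.4 * c + rng.normal(size=n) * np.sqrt(1 - 0.16)
        r, _ = partial_correlation_test(a, b, c)
        # population partial correlation is exactly 0; sample value is small
        r_ab = np.corrcoef(a, b)[0, 1]
        r_ac = np.corrcoef(a, c)[0, 1]
        r_bc = np.corrcoef(b, c)[0, 1]
        expected = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_collider_formula_instantiation(self, rng):
        n = 300
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        c = a + b + 0.5 * rng.normal(size=n)
        r, _ = partial_correlation_test(a, b, c)
        r_ab = np.corrcoef(a, b)[0, 1]
        r_ac = np.corrcoef(a, c)[0, 1]
        r_bc = np.corrcoef(b, c)[0, 1]
        expected = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        assert r == pytest.approx(expected, abs=1e-10)

    def test_equals_residual_regression_correlation(self, rng):
        n = 80
        a, b, c = rng.normal(size=(3, n))
        b = b + 0.5 * c
        a = a + 0.3 * c
        r, p = partial_correlation_test(a, b, c)
        # oracle: correlate OLS residuals of a~c and b~c
        C = np.column_stack([np.ones(n), c])
        ra = a - C @ np.linalg.lstsq(C, a, rcond=None)[0]
        rb = b - C @ np.linalg.lstsq(C, b, rcond=None)[0]
        assert r == pytest.approx(np.corrcoef(ra, rb)[0, 1], abs=1e-10)
        t = r * np.sqrt((n - 3) / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), n - 3), abs=1e-12)

    def test_degenerate_conditioning_errors(self, rng):
        c = rng.normal(size=20)
        with pytest.raises(ValueError, match="degenerate"):
            partial_correlation_test(c, rng.normal(size=20), c)


class TestAnchors:
    def _scan_with_p(self, p_matrix, geno, expr):
        t, f = p_matrix.shape
        return AssociationScan(
            p_matrix, np.zeros((t, f)), expr.gene_ids, geno.variant_ids
        )

    def test_empty_map_when_nothing_significant(self, power_motif):
        geno, expr, _ = power_motif
        p = np.full((expr.n_genes, geno.n_variants), 0.5)
        anchors = find_anchor_genes(
            self._scan_with_p(p, geno, expr), geno, expr, ThresholdConfig()
        )
        assert anchors == {}

    def test_boundary_is_strict(self, power_motif):
        geno, expr, _ = power_motif
        t, f = expr.n_genes, geno.n_variants
        cfg = ThresholdConfig(p_anchor=0.05)
        p = np.full((t, f), 1.0)
        p[0, 0] = 0.05 / (t * f)  # adjusted p == threshold exactly
        anchors = find_anchor_genes(
            self._scan_with_p(p, geno, expr), geno, expr, cfg
        )
        assert anchors == {}
        p[0, 0] *= 0.999
        anchors = find_anchor_genes(
            self._scan_with_p(p, geno, expr), geno, expr, cfg
        )
        assert anchors == {0: [0]}

    def test_cis_mode_requires_proximity(self, power_motif):
        geno, expr, _ = power_motif
        t, f = expr.n_genes, geno.n_variants
        p = np.full((t, f), 1.0)
        p[2, 0] = 1e-30  # gene C is far from snp0: trans, not cis
        cfg_cis = ThresholdConfig(anchor_mode="cis")
        cfg_trans = ThresholdConfig(anchor_mode="trans")
        s = self._scan_with_p(p, geno, expr)
        assert find_anchor_genes(s, geno, expr, cfg_cis) == {}
        assert find_anchor_genes(s, geno, expr, cfg_trans) == {0: [2]}

    def test_planted_cis_anchor_recovered(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            geno, expr, _ = simulate_basic(
                "power", SimParams(n_samples=379), seed=300 + seed
            )
            K = realized_relationship(geno)
            s = scan(geno, expr, K)
            anchors = find_anchor_genes(s, geno, expr, ThresholdConfig())
            hits += 0 in anchors.get(0, [])
        assert hits >= int(0.95 * n_seeds)


def brute_force_vstructures(scan_obj, expr, geno, cfg):
    """Exhaustive re-evaluation of all six criteria, one triplet at a time."""
    anchors = find_anchor_genes(scan_obj, geno, expr, cfg)
    t = expr.n_genes
    dep_family = cfg.dep_family_size or max(t - 1, 1)
    out = set()
    for snp, genes_a in anchors.items():
        for a in genes_a:
            for c in range(t):
                if c == a:
                    continue
                if (
                    expr.chrom[c] == geno.chrom[snp]
                    and abs(expr.tss[c] - geno.pos[snp]) <= cfg.cis_window
                ):
                    continue
                _, p_ac = correlation_test(expr.values[:, a], expr.values[:, c])
                if min(p_ac * dep_family, 1.0) >= cfg.p_dep:
                    continue
                for b in range(t):
                    if b in (a, c):
                        continue
                    _, p_bc = correlation_test(expr.values[:, b], expr.values[:, c])
                    if min(p_bc * dep_family, 1.0) >= cfg.p_dep:
                        continue
                    _, p_ab = correlation_test(expr.values[:, a], expr.values[:, b])
                    if p_ab < cfg.p_ind:
                        continue
                    if not scan_obj.pvalues[b, snp] >= cfg.p_snp_ind:
                        continue
                    try:
                        _, p_part = partial_correlation_test(
                            expr.values[:, a], expr.values[:, b], expr.values[:, c]
                        )
                    except ValueError:
                        continue
                    if min(p_part * dep_family, 1.0) < cfg.p_dep:
                        out.add((snp, a, c, b))
    return out


class TestFindVStructures:
    def test_lazy_equals_exhaustive(self):
        geno, expr, _ = simulate_basic("power", SimParams(n_samples=379), seed=7)
        K = realized_relationship(geno)
        s = scan(geno, expr, K)
        cfg = ThresholdConfig.basic_preset()
        lazy = {
            (v.snp_index, v.anchor_gene, v.focal_gene, v.exo_gene)
            for v in find_vstructures(
                find_anchor_genes(s, geno, expr, cfg), s, expr, geno, cfg
            )
        }
        assert lazy == brute_force_vstructures(s, expr, geno, cfg)

    def test_collider_recovered_and_helps(self):
        """Strong mediated effects: gene B is identified as exogenous for
        (SNP A, gene C) in a clear majority of replicates."""
        recovered = 0
        n_seeds = 40
        for seed in range(n_seeds):
            geno, expr, truth = simulate_basic(
                "power", SimParams(n_samples=379), seed=500 + seed
            )
            K = realized_relationship(geno)
            s = scan(geno, expr, K)
            cfg = ThresholdConfig.basic_preset()
            vs = find_vstructures(
                find_anchor_genes(s, geno, expr, cfg), s, expr, geno, cfg
            )
            cs = build_conditioning_sets(vs)
            recovered += 1 in cs.genes(0, 2)
        assert recovered > n_seeds // 4

    def test_guard_blocks_snp_associated_exo_gene(self):
        """Gene B regulated by SNP A: the SNP-independence criterion refuses
        the V-structure, avoiding synthetic associations."""
        for seed in range(25):
            geno, expr, _ = simulate_basic(
                "confounding", SimParams(n_samples=379), seed=seed, snp_to_b=True
            )
            K = realized_relationship(geno)
            s = scan(geno, expr, K)
            cfg = ThresholdConfig.basic_preset()
            vs = find_vstructures(
                find_anchor_genes(s, geno, expr, cfg), s, expr, geno, cfg
            )
            cs = build_conditioning_sets(vs)
            assert 1 not in cs.genes(0, 2)

    def test_dominant_factor_yields_no_vstructures(self, rng):
        """One factor driving all genes: no marginal independence, no
        V-structures (the tight-correlation failure mode)."""
        from gnetlmm import ExpressionData, simulate_genotypes

        n = 379
        geno = simulate_genotypes(n, 20, seed=1)
        factor = rng.normal(size=n)
        Y = 0.9 * factor[:, None] + 0.3 * rng.normal(size=(n, 5))
        x = geno.dosages[:, 0]
        Y[:, 0] += np.sqrt(0.3) * (x - x.mean()) / x.std()  # anchored gene
        expr = ExpressionData(
            Y, [f"g{i}" for i in range(5)], ["1"] * 5,
            [geno.pos[0] + 500] + [10**9 + i * 10**7 for i in range(4)],
        )
        s = scan(geno, expr, realized_relationship(geno))
        cfg = ThresholdConfig.basic_preset()
        vs = find_vstructures(
            find_anchor_genes(s, geno, expr, cfg), s, expr, geno, cfg
        )
        assert vs == []

    def test_threshold_monotonicity(self):
        """Stricter dependence or independence thresholds never add
        V-structures."""
        geno, expr, _ = simulate_basic("power", SimParams(n_samples=379), seed=17)
        K = realized_relationship(geno)
        s = scan(geno, expr, K)

        def vs_set(cfg):
            return {
                (v.snp_index, v.anchor_gene, v.focal_gene, v.exo_gene)
                for v in find_vstructures(
                    find_anchor_genes(s, geno, expr, cfg), s, expr, geno, cfg
                )
            }

        base = ThresholdConfig(p_dep=0.05, p_ind=0.1, dep_family_size=1,
                               anchor_family_size=1, p_anchor=0.001)
        stricter_dep = ThresholdConfig(p_dep=0.005, p_ind=0.1, dep_family_size=1,
                                       anchor_family_size=1, p_anchor=0.001)
        stricter_ind = ThresholdConfig(p_dep=0.05, p_ind=0.3, dep_family_size=1,
                                       anchor_family_size=1, p_anchor=0.001)
        assert vs_set(stricter_dep) <= vs_set(base)
        assert vs_set(stricter_ind) <= vs_set(base)

    def test_null_data_rarely_produces_vstructures(self, rng):
        from tests.conftest import iid_expression
        from gnetlmm import simulate_genotypes

        total = 0
        for seed in range(10):
            geno = simulate_genotypes(150, 30, seed=seed)
            expr = iid_expression(np.random.default_rng(seed), 150, 10)
            s = scan(geno, expr, realized_relationship(geno))
            cfg = ThresholdConfig()
            total += len(
                find_vstructures(
                    find_anchor_genes(s, geno, expr, cfg), s, expr, geno, cfg
                )
            )
        assert total <= 5


class TestConditioningSets:
    def test_empty_input(self):
        assert len(build_conditioning_sets([])) == 0

    def test_dedup_across_anchors(self):
        v1 = VStructure(0, 1, 2, 3, 0.5, 0.5, 0.0, -0.3, 0.01)
        v2 = VStructure(0, 4, 2, 3, 0.6, 0.5, 0.0, -0.4, 0.002)
        cs = build_conditioning_sets([v1, v2])
        assert cs.genes(0, 2) == [3]
        assert cs.partial_pvalues[(0, 2)] == [0.002]  # keeps the smaller p

    def test_ordered_by_partial_pvalue(self):
        vs = [
            VStructure(1, 0, 5, 7, 0.5, 0.5, 0.0, -0.2, 0.04),
            VStructure(1, 0, 5, 6, 0.5, 0.5, 0.0, -0.4, 0.001),
            VStructure(1, 0, 5, 8, 0.5, 0.5, 0.0, -0.3, 0.01),
        ]
        cs = build_conditioning_sets(vs)
        assert cs.genes(1, 5) == [6, 8, 7]

    def test_members_satisfy_all_criteria_when_retested(self):
        """Self-consistency: every accepted exogenous gene passes the six
        criteria under independent re-testing."""
        geno, expr, _ = simulate_basic("power", SimParams(n_samples=379), seed=23)
        K = realized_relationship(geno)
        s = scan(geno, expr, K)
        cfg = ThresholdConfig.basic_preset()
        vs = find_vstructures(
            find_anchor_genes(s, geno, expr, cfg), s, expr, geno, cfg
        )
        brute = brute_force_vstructures(s, expr, geno, cfg)
        cs = build_conditioning_sets(vs)
        for (snp, focal), genes in cs.sets.items():
            for b in genes:
                assert any(
                    (snp, a, focal, b) in brute for a in range(expr.n_genes)
                )


class TestThresholdConfig:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ThresholdConfig(p_dep=0.0)
        with pytest.raises(ValueError):
            ThresholdConfig(p_dep=0.2, p_ind=0.1)
        with pytest.raises(ValueError):
            ThresholdConfig(anchor_mode="both")
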