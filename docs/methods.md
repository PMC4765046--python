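# Methods

## Model

### Step 1 — genome-wide mixed-model scan

Each gene's expression vector y (length N) is tested against every variant
x under

    y ~ N(x β + C α,  σ²_bg K + σ²_n I),

where C is the fixed-effect design (an intercept is always included;
user covariates are appended), K is the background covariance and I models
iid measurement noise. In all shipped analyses K is the realized
relationship matrix (RRM): dosages are mean-imputed per variant, centred,
scaled to unit variance (monomorphic variants dropped with a warning) and
K = Z Zᵀ / F.

The variance ratio δ = σ²_n/σ²_bg is fit once per gene on the null model
(no variant term) by maximum likelihood — not REML — and then held fixed
for every variant tested against that gene. After rotating by the
eigenvectors of K, the covariance is diagonal, σ²_bg diag(s + δ), and the
profiled ML log-likelihood is a 1-D function of δ: it is maximized on a
100-point log-spaced grid over [1e-4, 1e4] followed by bounded refinement
between the best grid point's neighbours. The boundary δ = +∞ (pure noise;
the model collapses to OLS) is always evaluated as a candidate and wins
ties — in particular when K = I, where only the total variance is
identified, the fit deterministically reports δ = +∞ with the OLS Gaussian
log-likelihood.

Per variant, β is estimated by generalized least squares at the fixed δ
with the scale σ² profiled out; the likelihood-ratio statistic
N·log(RSS₀/RSS₁) (weighted residual sums of squares without/with the
variant) is referred to χ²(1). The statistic is invariant to affine
rescaling of y. Monomorphic variants yield missing entries, with a logged
count.

### Step 2 — V-structure discovery

Dependence between genes uses the Pearson correlation test (t with N−2 df);
the first-order partial correlation given gene C uses the closed form
r_AB·C = (r_AB − r_AC r_BC)/√((1−r_AC²)(1−r_BC²)) with N−3 df, which equals
the correlation of the residuals after regressing both genes on gene C.
Independence is declared when the raw p-value exceeds a threshold — a
pragmatic criterion, not a calibrated test, but standard in this setting.
SNP–gene (in)dependence reuses the Step-1 mixed-model p-values.

Anchors are genes whose Bonferroni-adjusted association p-value is strictly
below `p_anchor`; in cis mode the gene's TSS must additionally lie within
`cis_window` (default ±1 Mb, inclusive) of the variant. Candidate focal
genes exclude the anchor itself and genes within the cis window of the
tested variant. Partial correlations are evaluated lazily, only for
candidates that already satisfy the marginal criteria and the SNP guard —
this shortcut provably yields the same V-structure set as exhaustive
evaluation and is covered by a test.

Thresholds (defaults): adjusted p < 0.01 for (conditional) dependence,
raw p ≥ 0.1 for gene–gene independence, adjusted p < 0.05 for the anchor,
raw p ≥ 0.1 for SNP–exogenous-gene independence. "Adjusted" means
Bonferroni within a configurable family: the number of gene pairs examined
per focal gene (T−1) for dependence tests, and the full T×F grid for the
anchor. For few-gene designs a stricter preset is provided
(`ThresholdConfig.basic_preset()`: raw p < 0.001 for dependence calls and
anchors); with a handful of genes the family correction is meaningless and
the preset reads the thresholds as raw, which is also how the original
description words them.

One printed formula conditions the A–B dependence test on the *genotype*
x_C rather than the expression y_C; the surrounding text says
"conditioning on the gene C". We treat the subscripted x as a typo and
condition on y_C; the config switch `partial_condition="both"` additionally
requires dependence given the focal gene's best local variant, for
sensitivity analysis.

### Step 3 — conditioned re-tests

For each (SNP, focal gene) pair with a nonempty conditioning set L the test
becomes

    y_C ~ N(x_A β + C α,  σ²_bg K + σ²_exo Σ_{B∈L} ỹ_B ỹ_Bᵀ + σ²_n I),

where each exogenous expression vector is standardized to unit variance
(ỹ_B), so σ²_exo is on a per-gene variance scale and the test is invariant
to the measurement scale of the exogenous genes. The three variance
components are refit on the null model of each unique (focal gene,
conditioning set) pair — mirroring the Step-1 treatment of δ; whether the
original implementation reuses the Step-1 δ here is not documented, and
refitting is the choice that keeps the null model internally consistent —
then held fixed for the LRT on β across all variants sharing that set.

Computationally the K-eigenbasis rotation makes the covariance
"diagonal + rank-R", and all solves and determinants go through the
Woodbury identity and a rank-R capacitance matrix, so a group of m tests
against one conditioning set costs O(N²R + mNR²) after the one-off
eigendecomposition, never a dense refactorization per test. The two
variance ratios (background and exogenous, relative to noise) are profiled
on a 7×7 coarse grid including both zero boundaries, then polished by
Nelder–Mead in log-space (interior optimum) or bounded 1-D refinement (on a
boundary); the overall scale is profiled analytically throughout. The
low-rank path agrees with a dense-covariance reference implementation to
|Δp| < 1e-6 (tested for N ≤ 100, R ≤ 5).

Conditioning sets are deduplicated per (SNP, focal gene) and ordered by
ascending partial-correlation p-value; `max_rank` (default 10) truncates
the list deterministically, keeping the strongest colliders.

## Comparator methods

All comparators consume the same inputs and emit the same gene×variant
scan. *ideal-LMM* conditions on the true parents of the focal gene that are
not downstream of the tested variant, plus the true confounder factors
loading on it. *coreg-LMM* conditions on genes co-regulated by the tested
variant (its downstream genes) — the deliberately harmful choice.
*PC-LMM* adds the top-n expression PC scores (computed on the
column-standardized matrix, scores restandardized) as a second random
effect; *PCselect-LMM* first maps each PC as a quantitative trait and drops
PCs with any Benjamini–Hochberg q < 0.2. *ICE-LMM* uses the empirical
expression covariance of the *other* genes as the second random effect:
including the focal gene makes the profiled ML unbounded (the low-rank term
reproduces y exactly while the noise variance goes to zero), so exclusion
is the default, switchable for sensitivity analysis.

## Synthetic data

The generator emulates a population eQTL panel: independent variants with
dosage ~ Binomial(2, maf), maf ~ U(0.05, 0.5), on one synthetic chromosome
at 20 Mb spacing (so the ±1 Mb cis, ±5 Mb cis-exclusion and ±2 kb
true-positive windows separate cleanly); an anchored gene's TSS sits 500 bp
from its variant. Default panel: 379 samples; the full-size variant panel
is 4030 quasi-independent common variants, while the shipped motif designs
use 100 variants — enough that no single tested variant contributes
appreciably to its own RRM. (With only a handful of variants the tested
SNP dominates the background covariance and absorbs its own signal —
proximal contamination — which collapses anchor p-values by six orders of
magnitude in our measurements.)

Four-gene motifs around one causal variant:

* **power** — SNP A → gene A; {gene A, gene B} → gene C; gene C → gene D.
  The cis anchor and each regulating edge explain 10–20 % of the target's
  variance (each share drawn uniformly per replicate).
* **direct / trans** — SNP A additionally hits gene C (direct) or gene D
  (trans), with α (default 0.5) splitting the SNP's variance share.
* **confounding** — no SNP → gene C path; two confounders jointly explain
  50–70 % of each affected gene; optionally SNP A → gene B (the
  synthetic-association guard design). These are the null designs used for
  calibration.

Network designs simulate T = 100 genes by default (benchmarks here use 50):
*sparse* draws each edge over a random topological order with
p_edge = 0.02; *star* plants 9 hub genes, each regulating a U(20 %, 50 %)
fraction of the other genes (hubs regulate non-hubs, preserving
acyclicity). Edge weights come from the equal mixture
0.5·N(+1, 0.1²) + 0.5·N(−1, 0.1²), guaranteeing nonzero weights with
balanced signs. Every gene receives a cis variant explaining `var_cis`
(default 0.10); the joint network-plus-confounding share is `var_network`
(default 0.80), apportioned by `conf_fraction` (default 0.20); the network
part of a gene is split among its parents proportionally to squared mixture
weights, the confounding part equally among its confounders (membership
per confounder with probability conf_per_gene/C), and unused shares return
to the noise budget.

A real-genotype loader (`load_vcf_genotypes`) is provided as an optional
entry point: it reads a VCF (via cyvcf2, imported lazily), discards variants
with MAF < 0.05 and greedily prunes local linkage disequilibrium to
r² ≤ 0.9 within sliding windows of 50 variants advanced by 5, producing the
kind of quasi-independent panel the simulations assume. Nothing else in the
package depends on it.

"Variance explained" is operationalized by exact per-draw rescaling: each
component vector is standardized and scaled so its realized sample variance
equals the drawn share, noise fills the remainder, and the realized
fractions are recorded in the truth tables. Component vectors are mutually
independent by construction but sample correlations make the total variance
only approximately 1; the recorded fractions are exact for each component.

What the generator does **not** emulate: linkage disequilibrium (variants
are independent), population structure (so the RRM is near-identity and the
background component mainly guards the method rather than being exercised),
non-linear regulation, and measurement-platform artefacts. Passing tests
therefore demonstrate the statistical machinery under the stated generative
model, not robustness to real-data pathologies.

## Evaluation

An association (variant, gene C) is a true positive when some direct
regulator of gene C has a cis anchor within ±2 kb (inclusive) of the tested
variant; associations within ±5 Mb of the focal gene's own locus (its
anchor variant position in simulations) are excluded as putative cis
signals; everything else is a false positive. Power is the area under the
ROC (p-values ascending, ties processed as a block, trapezoidal
integration) restricted to FPR ∈ [0, 0.05]; both the raw area and the
normalized area (divided by 0.05, so perfect ranking scores 1) are
reported. ROC records are pooled within a replicate and power is averaged
across replicates. Hotspot tables count, per variant and significance
threshold, the genes associated in trans (outside a configurable window,
±5 Mb here, ±20 Mb for the mouse-style setting). Calibration summaries
report the Kolmogorov–Smirnov test against U(0,1) and the tail fraction at
nominal 0.05.

## Problem sizes used by the shipped benchmarks

The original benchmarks use 1000 replicates per design. The package's own
acceptance runs use: 200 replicates of the mediated-trans motif (four
methods), 45 star and 60 sparse 50-gene network replicates (100-variant
panels, N = 379, PC-LMM at n_pcs = 10), ~650 null-design replicates for
calibration and 500 for the guard; the test suite uses the same designs at
30–50 network replicates. These sizes keep each qualitative comparison
statistically decisive (the smallest asserted gap, sparse GNet−LMM, is
positive in ~90 % of paired replicates).

## Numerical choices and degenerate inputs

* LRT statistics are clipped at 0; p-values are χ²(1) survival values and
  satisfy p = sf(LRT) to 1e-12 by construction.
* Eigenvalues of K are clipped at 0 after the PSD check
  (tolerance −1e-8·λ_max); kinships must be symmetric to 1e-10.
* Missing dosages are mean-imputed per variant in the model layer; readers
  preserve them (TSV sentinel −9, PLINK missing code).
* Zero-variance expression or genotype vectors raise errors
  ("monomorphic variant", "degenerate conditioning", "zero-variance").
* Partial correlations with |r_AC| or |r_BC| = 1 (denominator ≤ 1e-12) are
  rejected as degenerate conditioning; during the V-structure search such
  candidates are skipped.
* Quantile normalization maps averaged ranks to Φ⁻¹((rank − 0.5)/n),
  avoiding infinite quantiles; a residualize-then-renormalize helper
  mirrors the usual two-pass covariate treatment.
* Determinism: all generators take explicit seeds; the simulator derives
  independent child streams (genotypes / topology / confounders / noise)
  from one seed, so the confounder path can be switched off without
  perturbing the other streams. Written provenance records the config and
  seed (no timestamps), so repeated runs are byte-identical.

## Known limitations

* The independence calls use raw-p thresholds on correlation tests; they
  are decision rules, not calibrated tests, and inherit the usual power
  limits (a true collider with partial correlation ≈ 0.18 at N = 379 is
  detected in roughly half the replicates at the strict preset — the
  method then simply reverts to the plain LMM for that pair).
* In the regime of one dominant factor correlating all genes, marginal
  independence never holds and no V-structures are found (by design).
* PC-LMM comparisons depend strongly on the share of per-gene variance the
  network explains; under the default budgets PC adjustment costs power in
  every no-confounding topology we simulate, most dramatically for hubs.
* The conditioned model treats exogenous genes as a variance component
  rather than fixed effects; with very small conditioning sets the two
  choices are nearly equivalent, and the variance-component route keeps the
  rank-R scaling.
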