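# Methods

This note documents the statistical model, the numerical choices, and what
the synthetic-data generator does and does not emulate. It is the package's
own account of its science; every number quoted here is computed by the
test suite or the reproduction script, not asserted from elsewhere.

## The two-step scan

### Step 1 — null animal model by profiled REML

The null model is y = Xβ + u + e with u ~ N(0, G σu²) and e ~ N(0, I σe²).
Each animal has exactly one phenotype record (when a bull has several
evaluations the reader keeps the one based on the most breedings, the most
reliable record), so the incidence matrix of the animal effect is the
identity and record weights are not used (R = I).

Writing σ² = σu² + σe² and h² = σu²/σ², the phenotypic covariance is
V = σ²(h²G + (1−h²)I). On the eigenbasis G = U diag(d) Uᵀ this is diagonal,
so after one O(n³) eigendecomposition every likelihood evaluation is O(np).
σ² is profiled out analytically; the restricted likelihood is maximised
over the single parameter h² by a grid scan (step 0.01 over [0, 0.99])
followed by bounded scalar minimisation on the bracketing interval to
|Δh²| < 1e−6 (at most 200 refinement evaluations). The grid-then-refine
scheme is globally robust — the profiled restricted likelihood in h² can be
flat or bimodal near boundaries — and trivially checkable against a dense
oracle, which the test suite does at n = 40 to 1e−6 using explicit matrix
inverses and determinants.

Conventions: the restricted log-likelihood is the Patterson–Thompson form
−½[(n−p)(log 2πσ̂² + 1) + log|V*| + log|XᵀV*⁻¹X|] with V* = h²G + (1−h²)I
(no |XᵀX| constant). Estimates pinned at h² = 0 or at the 0.99 cap are
reported with `converged=False` rather than silently clamped. X defaults to
an intercept only: SCR-style phenotypes arrive pre-adjusted for systematic
effects by the upstream national evaluation; arbitrary covariate columns
are accepted.

### Step 2 — per-SNP score test against the frozen null

Each marker's B-allele dosage is mapped through one of four codings —
additive (0,1,2), dominance (0,1,1), recessive (0,0,1), overdominance
(0,1,0) — and tested with

z = xᵀV₀⁻¹(y − Xβ̂) / √(xᵀV₀⁻¹x),   V₀ = G σ̂u² + I σ̂e²,

with β̂ and V₀ frozen from step 1 (a GRAMMAR-type two-step test; no per-SNP
mixed-model refit). The reported effect is β = xᵀV₀⁻¹r / xᵀV₀⁻¹x with
se = (xᵀV₀⁻¹x)^(−1/2), so z = β/se, and p = 2Φ(−|z|).

**Numerical choice — projection of the coded vector.** Before testing, x is
residualized against the fixed-effect design in the V₀⁻¹ inner product,
x ← x − X(XᵀV₀⁻¹X)⁻¹XᵀV₀⁻¹x. This cannot change the numerator (because
XᵀV₀⁻¹(y − Xβ̂) = 0 at the GLS solution, the statistic is invariant to
adding any column-span of X to x there), but it makes the denominator the
exact conditional variance of the numerator. Consequently z coincides to
machine precision with the Wald statistic of a joint GLS fit of y on
[X, x] at the known V₀ — the property the oracle-equivalence tests assert
at 1e−6 — and the test is exactly calibrated rather than slightly
conservative. With an intercept-only X this projection is GLS centering of
the coded vector.

A marker whose projected coded vector is numerically constant (e.g. the
recessive coding of a marker with no BB genotypes) is reported as
untestable (nan statistics), never as z = 0: a test with no genotype-class
contrast has no evidence to offer in either direction.

The whole-panel scan vectorises step 2 on the eigenbasis (one n×m matrix
product per coding). The additive coding is always computed alongside the
requested non-additive codings so every marker reports both a non-additive
and an additive p — the paired columns that let a purely non-additive mode
of action be recognised.

### Genomic control and multiple testing

λ = median(z²)/median(χ²₁) per coding (each coding's scan has its own null
behaviour); the exact χ²₁ median 0.45494 is used rather than the rounded
0.456. A trimmed regression-through-the-origin estimator on the lower 90%
of order statistics is available as an option; exact numerical agreement
with any particular legacy implementation is not claimed. When λ > 1,
p_gc = 2Φ(−|z|/√λ); deflation (λ < 1) is left uncorrected by the usual
convention. Family-wise control is Bonferroni at α/m with α = 0.01 by
default and m the number of markers tested.

## Marker QC and conventions

Filters, in order: non-autosomal chromosome labels ({X, Y, XY, MT, 30} —
"30" being a legacy bovine-X synonym), monomorphic markers, then
MAF < 0.01. The boundary is inclusive (MAF exactly 0.01 is retained,
matching removal of markers with frequency *less than* 1%). MAF for QC is
computed on observed calls only, so imputation can never rescue a
monomorphic marker. MAF itself is min(f_B, 1−f_B) with
f_B = (2n_BB + n_AB)/2(n_AA + n_AB + n_BB).

Allele orientation is file-defined: dosage counts the second distinct
allele symbol encountered per marker in the .ped, which is stable and
reproducible; `orient_minor` re-orients so B is the minor allele. Under
opposite orientations the dominance and recessive codings are mirror images
of each other, and the overdominance and additive codings are unchanged up
to sign — since all codings are scanned, orientation affects labelling of
hits, not their discovery.

Missing dosages are mean-imputed per marker (before GRM construction and
before coding); the coding map is applied to imputed fractional dosages by
piecewise-linear interpolation, which preserves column means and keeps the
dominance − recessive = overdominance identity exact on complete data.

## GRM

VanRaden method 1: G = WWᵀ / 2Σp(1−p) with W the dosage matrix centered at
2p per marker and p the sample allele frequencies (no base-population
frequencies are assumed available). A ridge of 1e−6 on the diagonal
guarantees positive definiteness, since V₀ must be inverted downstream.
Under Hardy–Weinberg sampling the diagonal has expectation 1 and paternal
half sibs have expected off-diagonal 0.25; both are property-tested.

## The synthetic-data generator

The generator emulates the structure of an AI-bull study population:

- **Relatedness.** Paternal half-sib families: each of `n_sires` sires
  contributes `offspring_per_sire` genotyped sons; a son inherits one
  random gamete of his sire and one dam gamete drawn from the population
  frequency (dams unobserved and mutually unrelated). Setting
  `offspring_per_sire = 1` yields an unrelated panel for calibration work.
- **Markers.** Biallelic SNPs with B-allele frequencies drawn uniformly on
  [maf_low, maf_high] (defaults 0.05–0.5), independent across loci, spread
  over 29 autosome labels.
- **Phenotype.** y = μ + Σ_q b_q·code_q(dosage) + u + e with u = √σu²·Lζ,
  where LLᵀ is the Cholesky factor of the realised GRM (so the simulated
  polygenic covariance is exactly the matrix the analysis estimates) and e
  i.i.d. N(0, σe²). Default σu² = 3, σe² = 7 (h² = 0.3, a realistic value
  for semen/fertility traits), μ = 0 since SCR-type phenotypes are
  expressed as deviations from the population mean.
- **QTLs.** Planted causal markers are members of the scanned panel (the
  marker *is* the causal variant); effects are phenotype units per coded
  unit, recorded in a ground-truth table.

What it does **not** emulate — and hence what passing tests do not show
about real data: linkage disequilibrium between markers (each locus is
drawn independently, so LD-tagging power is out of reach by construction),
multi-generation pedigrees and maternal relatedness, selection,
genotyping error, call-rate structure, and X-chromosome dosage. Real SNP
panels also have frequency spectra skewed by array ascertainment rather
than uniform.

## Validation studies and their problem sizes

The package's own statistical behaviour is established by three replicate
studies (in `sirescan.studies`, run by both the acceptance tests and
`scripts/acceptance.py`):

- **REML recovery.** 200 replicates of n = 500 (50×10 half-sib), m = 2,000,
  true h² = 0.3; the mean ĥ² must land within ±0.05 of truth. Per-replicate
  ĥ² has SD ≈ 0.09 at this design, so the mean over 200 is a sharp check.
- **Null calibration.** 100 QTL-free replicates at the same size; pooled
  type-I error at nominal 0.05 must lie in [0.04, 0.06] per coding, and the
  genomic-control λ of replicate scans must fall in [0.9, 1.1] at least 90%
  of the time. Measured λ distributions are centered at 1.000–1.003 for all
  four codings; the recessive λ is the noisiest (SD ≈ 0.054) because
  rare-homozygote codings carry fewer effective degrees of freedom, so the
  in-band requirement is evaluated over all replicate-scan λ values.
- **Power ordering.** A dominance QTL explaining ~1% of phenotypic variance
  planted at the panel's most common variant (allele frequency nearest
  0.5, where dominance and additive regressors are most distinguishable;
  their correlation ≈ 0.82 there and → 1 as the coded allele becomes
  rare), n = 2,000 (100×20), 60 replicates: the dominance-coding p must
  beat the additive-coding p at the causal marker in ≥ 80% of replicates.
  Observed ≈ 92%.

These sizes were chosen so each study pins its band tightly while the whole
suite stays fast; the reproduction script re-runs the same studies at
100/60/40 replicates.

## Known limitations

- The two-step test freezes β̂ and V₀ from the null fit; for markers with
  very large effects the null-based V₀ slightly overstates the residual
  variance, giving mildly conservative p at the strongest signals (the
  standard trade-off of score-type scans).
- Single genomic variance component only: no dominance-GRM or multiple
  random effects, and no record weights.
- The PLINK dialect is text .ped/.map only (plus a dosage CSV); binary
  .bed/VCF/BGEN are out of scope.
- λ estimation follows the classical median (or trimmed-regression)
  estimator; agreement with specific historical software to the last digit
  is not claimed.
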