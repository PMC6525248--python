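# Methods

## The testing problem

Symptom questionnaires such as the 21-item Beck Depression Inventory (items
scored 0–3, cumulative score 0–63) are usually collapsed to their cumulative
score before genetic association analysis.  That collapse is only lossless
when a single latent trait explains all inter-item correlation, the genetic
effect acts on that latent trait, and it acts equally on every item.  When a
variant influences only a subset of symptoms, the diluted cumulative score
can carry almost no signal.  This package tests the gene–questionnaire
relationship without collapsing: it asks whether subjects' pairwise
similarity across all Q items jointly is independent of their pairwise
genetic similarity across the V variants of a gene.

## The kernel distance-covariance test

For N unrelated subjects, two N×N similarity matrices are built:

* **Phenotypic similarity** from the item matrix Y (N×Q), after OLS
  residualization of each item on an intercept and any covariates.  Two
  forms: the *projection matrix* P = Y_c (Y_cᵀY_c)⁻¹Y_cᵀ (idempotent,
  eigenvalues 0/1, invariant to invertible recombination of the items) and
  the *linear kernel* Y_c Y_cᵀ.
* **Genotypic similarity** as a weighted linear kernel
  K_G = G_c W² G_cᵀ, with G_c the column-centered dosage matrix of the
  gene's array-typed variants and W = diag(w).  Default weights are
  w_v = 1/√(p_v(1−p_v)) with p_v the sample MAF — variance-standardizing for
  common variants — with flat and external (|log OR|) schemes available.
  Because weights multiply centered columns, the kernel is invariant to a
  global rescaling of w, and so is the p-value.

The statistic is T = trace(K_P K_G)/N.  Under independence its asymptotic
null law is the weighted chi-square mixture Σᵢⱼ (λᵢμⱼ/N²)·χ²₁ over nonzero
eigenvalues λ of K_P and μ of K_G (both kernels are double-centered by
construction, since their factors are column-centered).

### Finite-sample calibration

The raw asymptotic mixture drifts from the exact permutation distribution by
O(1/N) — enough to shift mid-range p-values by ~0.02–0.03 at N = 200.  Both
the mean and the variance of trace(K_P Π K_G Πᵀ) over uniform permutations Π
have closed forms for symmetric double-centered matrices (the quadruple
index sum collapses to trace, Frobenius and diagonal terms; the
implementation is verified against full enumeration of all permutations at
n = 6, 7).  The observed statistic is location/scale-standardized to those
exact moments before the mixture tail is evaluated.  The permutation test
(genotype rows permuted, p = (#{T_perm ≥ T_obs}+1)/(n_perm+1)) is kept as an
independent oracle and the analytic p-values are required to agree with it
to within 3 binomial standard errors.

### Implementation note

The N×N kernels are never materialized in the test path: with K_P = FFᵀ
(F an N×Q orthonormal basis or the residualized items) and K_G = G_w G_wᵀ,
the statistic is ‖FᵀG_w‖²_F/N and all eigenvalues come from Q×Q / V×V Gram
matrices, so a gene test costs O(NQV) rather than O(N²).

## Tail probabilities of chi-square mixtures

P(Σ c_k χ²₁ ≥ q) is computed by numerical inversion of the characteristic
function in the Imhof representation.  The integrand sin θ(u)/(u ρ(u))
oscillates at frequency q/2 while its envelope decays only as u^(−k/2−1), so
the half-line is split: adaptive Gauss–Kronrod quadrature on the head
(up to where the arctan phases saturate or the envelope falls below 1e−20),
then Fourier-weighted (QAWF) quadrature on the oscillatory tail using
sin(φ − qu/2) = sin φ cos(qu/2) − cos φ sin(qu/2).  Coefficients below
1e−10 of the maximum are dropped (projection-mode eigenvalue products carry
exact zeros plus float noise; the count is recorded).  Target accuracy is
1e−9 by default; p-values are floored there and never returned as 0.  If the
integrator fails its own error check, the Liu–Tang–Zhang four-moment match
to a noncentral chi-square is used instead and the result is labeled
`moment_fallback`; well-conditioned inputs always take the primary `davies`
path, which unit tests assert.

## Univariate comparators

**Kernel machine regression (KMR)** on the cumulative score: a SKAT-style
variance-component score test.  With null-model OLS residuals r and
residual variance σ̂² (denominator N−C−1), Q_s = rᵀK_G r/σ̂² is referred to
the mixture weighted by the eigenvalues of the kernel projected onto the
null residual space.  With a single unweighted variant this reduces exactly
to the two-sided score test of simple regression.

**Per-SNP linear regression + minP**: each typed variant is tested by OLS of
the cumulative score on [1, C, g] (two-sided t, N−C−2 df).  The gene-level
p-value adjusts the minimum over the V correlated tests: with z = Φ⁻¹(1 −
p_min/2) and R the correlation matrix of covariate-residualized dosages,
p_gene = 1 − P(−z < X < z componentwise), X ~ MVN(0, R).  The rectangle
probability is evaluated by Genz sequential conditioning over a scrambled
Sobol sequence with a fixed scramble seed (deterministic; ~1e−4 accuracy at
8,192 points, checked against a tightly converged reference integrator and
against simulated minP nulls).  Results are clipped to the envelope
[p_min, min(V·p_min, 1)].  Non-PD dosage correlation matrices get an
eigenvalue-clipping repair with a warning.

## Synthetic data generator

The generator reproduces the study conditions the tests are validated
under; its defaults are fixed, not tuning knobs.

* **Haplotype pools.**  Binary haplotypes are thresholded latent Gaussian
  AR(1) draws: lag-one correlation `ld_decay` (default 0.9, giving strong
  adjacent-variant LD typical of a gene-scale region), thresholds at the
  normal quantiles of per-variant target MAFs drawn uniformly on
  (0.05, 0.5) — the common-variant spectrum after a MAF > 5% filter.  Two
  packaged structures mirror the validation genes: 27 SNPs / 14 typed
  (STAT3-like, ~79 kb) and 127 SNPs / 50 typed (LRFN5-like, ~323 kb).
  Realized pool frequencies stay within ±0.02 of targets at pool size 2,000.
  Genotypes pair two uniformly drawn haplotypes per subject, giving
  Hardy–Weinberg dosages with the pool's LD.
* **Questionnaires.**  A Gaussian copula: latent Z ~ MVN(0, R) cut at
  per-item thresholds.  Default margins are right-skewed
  (0.55, 0.25, 0.12, 0.08) for levels 0–3 — BDI-like floor effects — and R
  is exchangeable at 0.2 with three equal item blocks raised to 0.45
  (symptom clusters).  These are synthetic stand-ins: the original
  cohort-estimated margins and 21×21 correlation matrix are restricted
  data.  Thresholds come from `calibrate_margins` (normal quantiles of
  cumulative frequencies; round-trip verified at N = 50,000).
* **Causal effects.**  The causal variant (typed or untyped; untyped causal
  variants are detectable only through LD) shifts the latent means of an
  affected item subset by β per centered dosage unit.  Default β = 0.2 puts
  a typical common causal variant at roughly 0.5–1% of cumulative-score
  variance explained when 12 of 21 items are affected — a modest overall
  effect that the cumulative score dilutes when concentrated in few items.
* **Confounding.**  U ~ N(0,1) enters item latents with slope γ_pheno and
  tilts haplotype sampling through a logistic weight in the haplotype's
  standardized allele count with slope γ_geno.  Defaults 0.2/0.2: strong
  enough that the unadjusted test visibly inflates (empirical size ≈ 0.29
  at α = 0.05, N = 1,000), mild enough that item residualization restores
  nominal size.
* **Seeding.**  One master seed; per-replicate generators come from
  `SeedSequence.spawn`, so experiments are reproducible and order-independent.

What the generator does *not* emulate: real HapMap haplotype structure
(block boundaries, recombination hotspots), item-specific margins,
population stratification beyond a single continuous confounder,
missingness, or genotyping error.  Passing size/power checks therefore
demonstrate calibration and relative efficiency under the copula model, not
performance guarantees on any particular cohort.

## Experiment sizes and numerical choices

Null size experiments in the shipped tests use 2,000 replicates at
N = 1,000 and 1,200 at N = 2,500 (binomial 3-SE bands around nominal α);
power runs use 500 replicates at N = 2,500 and α = 0.001 on a reduced causal
grid; the permutation-agreement check uses 20 datasets × 10,000
permutations.  These sizes keep a full validation run in the tens of
minutes on one CPU while leaving Monte-Carlo error well below the effects
being measured.

Degenerate inputs are policy-handled rather than fatal: zero kernels
(no phenotypic variation after residualization, no typed variants with
positive weight) return p = 1 with a diagnostic flag so genome scans never
abort; monomorphic variants are dropped; missing dosages are mean-imputed
per variant; constant columns raise explicit errors naming the column.
Projection-mode rank uses a relative singular-value cutoff of 1e−8 plus an
absolute floor tied to the pre-residualization scale of the items.

## Scan conventions

Gene windows are 1-based closed intervals with a symmetric flank (default
2,000 bp; a variant at exactly start − flank is included).  Region files are
read with BED semantics (0-based half-open) by default, switchable.  The
MAF > 5% filter uses sample MAF computed after subject intersection.
Study-wise significance is 0.05 divided by the number of gene tests actually
performed (recomputed after external-weight drops); suggestive thresholds
are 1e−4 (gene level) and 1e−6 (SNP level).  Scans are deterministic given
identical inputs, and subject order is taken from the phenotype table with
genotypes inner-joined by id.

## Known limitations

* Only projection and linear phenotype similarities, and linear genotype
  kernels, are provided (no IBS/Gaussian kernels, no rare-variant burden
  weighting).
* The minP adjustment integrates the plain MVN rectangle; the stepwise
  refinements of the original correlated-tests procedure are not reproduced.
* Continuous-score KMR only (no logistic variant); no relatedness or
  mixed-model adjustment — subjects are assumed unrelated.
* Power magnitudes depend on the synthetic effect-size and LD defaults;
  only the qualitative ordering between methods (multivariate vs cumulative
  score when few items carry signal) is asserted.
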