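# gamut

Gene-based association testing for **multivariate ordinal questionnaire
phenotypes** — a kernel distance-covariance test (GAMuT) with analytic
p-values, the standard univariate comparators, and the simulation machinery
to validate all of them.

## Who this is for

Psychiatric-genetics and epidemiology analysts who have per-item
questionnaire data (e.g., the 21 Beck Depression Inventory items, each
scored 0–3) plus genome-wide genotypes, and who want gene-level tests that
do not require collapsing the items into a single cumulative score.
Collapsing is safe only when one latent trait drives all items and the
genetic effect hits every item equally; when a variant affects a subset of
symptoms, the cumulative score dilutes the signal and univariate tests lose
power.

## The test

For N subjects, build two N×N similarity matrices and test their
independence:

* **Phenotypic similarity** from the residualized item matrix Y_c — either
  the projection matrix P = Y_c(Y_cᵀY_c)⁻¹Y_cᵀ or the linear kernel
  Y_cY_cᵀ;
* **Genotypic similarity** K_G = G_cW²G_cᵀ, a weighted linear kernel on the
  gene's centered dosages (default weights 1/√(p(1−p)) from sample MAF;
  flat or external |log OR| weights available).

The statistic T = tr(K_P K_G)/N is referred to its asymptotic null — a
weighted mixture Σ λᵢμⱼ/N² · χ²₁ over the kernels' eigenvalues — with exact
permutation-moment standardization and tail probabilities from numerical
characteristic-function inversion (Davies/Imhof; Liu moment-matching
fallback).  Comparators: SKAT-style kernel machine regression (KMR) on the
cumulative score, and per-SNP linear regression with correlated-minP
(P_ACT-style MVN) gene-level adjustment.  See `docs/methods.md` for the
full model.

## Worked example

Simulate a 2,500-subject study at a STAT3-like gene (27 SNPs, 14 typed)
where a causal SNP affects only 6 of the 21 items, then test the gene:

```python
import numpy as np
from gamut.simulate import (stat3_like_pool, default_bdi_model,
                            draw_genotypes, simulate_questionnaire, EffectModel)
from gamut import gamut_test, kmr_test, cumulative_score, WeightVector

pool, model = stat3_like_pool(), default_bdi_model()
rng = np.random.default_rng(1)
G = draw_genotypes(pool, 2500, rng)
causal = int(np.nonzero(pool.typed_mask)[0][6])
eff = EffectModel(causal, affected_items=np.arange(6), betas=0.2)
Y, _ = simulate_questionnaire(model, G, eff, 2500, rng)

Gt = G.typed()
w = WeightVector.from_maf(Gt.maf)
print("GAMuT (projection):", gamut_test(Y, Gt, w, mode="projection").p_value)
print("GAMuT (linear):    ", gamut_test(Y, Gt, w, mode="linear").p_value)
print("KMR on sum score:  ", kmr_test(cumulative_score(Y), Gt, w).p_value)
```

Output:

```
GAMuT (projection): 0.005406929870343136
GAMuT (linear):     0.0005179280096735961
KMR on sum score:   0.02468995666920054
```

On this draw both multivariate tests see the gene one to two orders of
magnitude more clearly than the cumulative-score test, which is diluted by
the 15 unaffected items; across 500 such replicates the projection-matrix
test rejects at α = 0.001 an order of magnitude more often than KMR.  Under
the null generator all three p-values are uniform (the test suite verifies
empirical size at α ∈ {0.05, 0.01} for N = 1,000 and 2,500).

The same machinery is scriptable from the shell:

```bash
gamut simulate-size  --gene-model stat3 --n-subjects 1000 --n-reps 10000 --out-prefix size
gamut simulate-power --gene-model stat3 --n-affected 6 --causal typed --out-prefix power
gamut scan --genotypes study.vcf --phenotypes pheno.tsv --genes genes.bed \
           --methods gamut-linear,kmr --weights maf --snp-pass --out-prefix scan
gamut plotdata --genes-tsv scan.genes.tsv --snps-tsv scan.snps.tsv --out-prefix plots
```

`scan` writes per-gene records (gene, chrom, n_variants, method, statistic,
p_value, flags) with Bonferroni (0.05 / genes tested) and suggestive
(1e−4 gene, 1e−6 SNP) thresholds; `plotdata` emits QQ/Manhattan tables with
the genomic-inflation factor.

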