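# phenopred

Genomic and phenomic prediction for structured plant-breeding panels —
a complete, tested analysis pipeline for comparing marker-based (genomic)
selection with NIRS-based (phenomic) selection in maize-style breeding
material: elite heterotic pools plus diverse landraces, evaluated in
multi-environment field trials.

## Who this is for

Quantitative geneticists and breeding informaticians who want to

* estimate genotype means (BLUEs) and broad-sense heritabilities from
  plot-level multi-environment data with a proper REML mixed model,
* run a defensible stepwise SNP quality-control pipeline,
* preprocess plot-level NIR reflectance spectra into a predictor matrix
  (edge trim, Savitzky–Golay first derivative, per-wavelength BLUEs,
  standardization),
* fit ridge-regression BLUP (RR-BLUP) with either markers or wavelengths as
  predictors, and
* evaluate predictions the way breeders actually deploy them: repeated
  stratified cross-validation within groups, predictions among unrelated
  groups, and composite training sets — with an explicit diagnostic for
  predictive ability that is an artifact of population structure.

A synthetic-data generator reproduces the statistical structure of such a
panel (structured subpopulations with nested families, additive traits,
plot-model noise, smooth spectra carrying trait signal independent of
group), so the entire pipeline is testable without any field data.

## The models

**Plot model.** A trait value from genotype *i* in environment (location–
year) *j*, replicate *k*, incomplete block *l* is

```
y_ijkl = mu + g_i + e_j + (ge)_ij + r_jk + b_jkl + eps_ijkl
```

with independent normal random effects and homogeneous error variance.
All-random fits give variance components and the entry-mean broad-sense
heritability

```
H2 = sigma2_g / (sigma2_g + sigma2_gxe / n_e + sigma2_eps / (n_e * n_r))
```

while genotype-fixed fits give the BLUEs used as phenotypes downstream.
REML is computed through the mixed-model equations with the largest random
factor absorbed by its Schur complement, profiled residual variance, and
analytic gradients (L-BFGS-B plus a Newton polish).

**Prediction model.** With per-genotype BLUEs `y`, predictor matrix `Z`
(marker dosages or standardized spectral derivatives),

```
y = 1*mu + Z u + eps,   u ~ N(0, V_u I),   eps ~ N(0, V_e I)
```

the single variance ratio `lambda = V_e / V_u` is estimated by spectral
REML (one eigendecomposition, Brent search on the profile likelihood), and
predictions are `y_hat = mu + Z_new u`. The algebraically equivalent
kernel (GBLUP) route with `K = Z Z'` is implemented independently and used
as a correctness oracle. Predictive ability is the Pearson correlation
between predictions and BLUEs in the prediction set.

## Worked example

```python
import numpy as np
from phenopred import evaluate, scenarios

sc = scenarios.confounded_landraces(seed=1)   # six landraces, trait driven
ids = list(sc.y.index)                        # purely by subgroup means

for name, Z in (("genomic", sc.genomic), ("phenomic", sc.phenomic)):
    dec = evaluate.cv_structure_decomposition(
        sc.y, Z, ids, sc.subgroups, n_runs=10, seed=7)
    print(f"{name}: overall r = {dec['overall_r']:.3f}, "
          f"r-bar = {dec['r_bar']:.3f}")
```

prints (seed 1):

```
genomic: overall r = 0.861, r-bar = -0.054
phenomic: overall r = 0.087, r-bar = 0.107
```

Read: pooled over all 200 landrace lines, marker-based cross-validation
reports a *high* predictive ability (0.86) — yet the mean correlation
within the six individual landraces (`r-bar`) is zero. The pooled number
is an artifact: markers separate the subpopulations, subpopulations differ
in their means, and the model predicts group membership, not breeding
value within a group. Spectra-based prediction, whose predictors carry no
group signal, reports a low overall ability that honestly matches its
within-group level. This is the central caution for anyone running
genomic prediction on structured panels.

The numbered scripts under `analysis/` walk through the full study:
`01` builds the synthetic panels, `02` fits BLUEs and heritabilities,
`03` runs marker QC, `04` the NIRS preprocessing, `05`–`07` the three
evaluation designs, `08` the DAPC group-discrimination contrast. Each
prints its findings and writes a table under `results/`.

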