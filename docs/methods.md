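# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limits of what the packaged tests
demonstrate.

## Plot model and REML

The multi-environment plot model is

y_ijkl = mu + g_i + e_j + (ge)_ij + r_jk + b_jkl + eps_ijkl,

genotype, environment (location–year), genotype-by-environment,
replicate-within-environment, incomplete-block-within-replicate, and an
iid error with homogeneous variance. Two fit modes are used:

* **all-random** — every factor random; yields variance components, BLUPs
  of genotype effects and the entry-mean heritability
  H² = σ²g / (σ²g + σ²gxe/nₑ + σ²ε/(nₑ·n_r));
* **genotype-fixed** — genotype as a fixed cell-means factor; the fixed
  estimates are the BLUEs used as phenotypes for prediction. In balanced
  orthogonal designs they reduce exactly to genotype means; in unbalanced
  data they are the GLS solution at the REML variance ratios.

REML works on the mixed-model equations with residual variance profiled
out: with γ_f = σ²_f/σ²_ε the criterion is
F(γ) = (n−p)·log(y'Py) + log|C| + Σ_f q_f·log γ_f, minimised over log γ.
Every single factor's block in C is diagonal, so the factor with the most
levels (usually genotype-by-environment) is absorbed via its Schur
complement; the reduced system is dense, its Cholesky factor gives the
objective and its inverse gives analytic gradients. Optimisation is
L-BFGS-B (bounds γ ∈ [1e-8, 1e8]) followed by a short Newton polish with a
finite-difference Hessian of the analytic gradient — needed because the
REML surface is nearly flat along components with few levels (environment,
replicate) and quasi-Newton stops ~1e-6 short in those directions, while
the balanced-design REML = ANOVA equivalence is asserted at 1e-6.
Components reaching the lower boundary are fixed at zero and the rest
re-optimised. Degenerate designs are handled explicitly: factors whose
levels would be confounded with the residual (one observation per
genotype-by-environment cell, one block per replicate, a single
environment) are dropped from the model, and exactly-fit responses
(zero residual) return the exact solution with zero variance components.
Per-wavelength fits reuse one factorised design across all responses
(`fit_plot_model_multi`), warm-starting each wavelength at the previous
one's ratios with relaxed tolerances — BLUEs are insensitive to the exact
variance ratios.

ne is taken from the observed data per trait (a trait recorded in only
two environments gets nₑ = 2), n_r as the mean number of replicates per
environment.

**Outlier screen.** Standardized residuals of the all-random fit are
converted to two-sided normal p-values and subjected to the Holm step-down
procedure at family-wise α = 0.05 (the method's convention; the level is
configurable). Flagged plots are set to missing and the screen re-run
once. Under a clean null the family-wise error rate is verified by Monte
Carlo to stay at or below α.

## Marker quality control

Thresholds are strict inequalities: markers are removed in order
(all-missing; missing fraction > 50%; heterozygous fraction > 5% of
non-missing calls; monomorphic), and the report records both the count
*detected* by each criterion and the count *newly removed*, so overlap
between criteria is visible and the step table is additive. Monomorphism
means one allele among non-missing calls; het-only markers count as
polymorphic. After the marker pass, genotypes exceeding 20% missing or 5%
het are flagged, never silently dropped. Per group (elite Dent, elite
Flint, landraces): all-missing and monomorphic markers and markers with
MAF < 3% are removed (MAF over non-missing calls, het contributing one
copy of each allele, computed before the het conversion), then surviving
het calls are set to missing rather than excluded. Imputation is
deliberately simple: numeric coding REF=0/HET=1/ALT=2 and within-group
marker-mean replacement (non-integer dosages allowed); it uses no linkage
or haplotype information, and a paired simulation shows ≤ 0.05 loss in
predictive ability at 10% missingness. After a final per-group MAF < 5%
filter the groups are merged on the **intersection** of surviving marker
sets — the only choice that gives every genotype every predictor column.

## NIRS processing

Pipeline order is fixed: average the cup repetitions (default 24) to one
spectrum per plot → trim 18 nm per edge (border effects) → Savitzky-Golay
smoothing and first derivative → per-wavelength plot-model BLUEs →
column standardization (mean 0, sample variance 1) into the phenomic
predictor matrix. The SG kernel is built from first principles as the
central row of the local least-squares polynomial projection, so it
reproduces the m-th derivative of any polynomial of degree ≤ p exactly;
this is property-tested and checked against a dense normal-equations
oracle. Window/polyorder are not dictated by the processing convention we
follow, so the defaults are common chemometrics practice (w = 11, p = 2,
m = 1), recorded in the output metadata. Edge points whose window leaves
the grid are dropped, not padded — consistent with the deliberate edge
trim. Standardization happens **after** the per-wavelength BLUEs;
permuting the two changes results.

## RR-BLUP

y = 1·mu + Zu + ε with iid effect variance over predictor columns —
identical machinery for dosages and spectral derivatives (predictor
provenance is carried as metadata only). λ = V_e/V_u is estimated by REML
on the profile likelihood after one eigendecomposition of the kernel
projected onto the intercept's complement; Brent search on log λ in
[1e-5, 1e5] with 1e-10 tolerance. The kernel (GBLUP) formulation is coded
as an independent route and must agree with the marker-effect route to
1e-8 relative on random instances — the module's central oracle. Dosage
columns are not centred (with an intercept, per-column affine coding is
immaterial; verified by the allele-flip invariance test); spectral
predictors arrive standardized.

## Evaluation designs

* **Within-group:** repeated random 5-fold partitions (default 1,000
  runs; the packaged analyses use 10–20 and state so). Heterogeneous
  groups are stratified proportionally per subgroup with a
  largest-remainder rule: each subgroup contributes floor(n_s/k) members
  to every fold and the remainders go one each to the currently smallest
  folds (subgroups in name order, residual ties randomised). Predictive
  ability is computed per prediction set (per fold) and pooled across
  runs; pooling a run's predictions before correlating is available
  behind a flag but non-default.
* **Among-group:** one whole group trains, another is predicted, no
  cross-validation; negative abilities are reported as-is.
* **Composite:** a random 80% of the target group plus one or more whole
  donor groups trains; the held-out 20% is predicted; 100 runs by
  default. With no donors this reduces exactly to an 80/20 within-group
  evaluation (tested).
* Groups below 30 genotypes never form a standalone training or
  prediction set.
* **Structure decomposition:** predictions of several CV runs are pooled
  into one scatter; the overall correlation is contrasted with r̄, the
  unweighted mean of within-subgroup correlations (subgroups with < 3
  members or zero variance are excluded and reported). Neither ordering
  of overall r and r̄ is assumed.
* **DAPC:** PCA (retaining the smallest PC count explaining ≥ 90%
  variance, capped at n/3 and n − n_groups − 1) followed by linear
  discriminant axes; the reassignment rate is leave-one-out over the
  discriminant step with the PCA basis held fixed — slightly optimistic
  versus a full LOO-PCA, but cheap and unbiased for the contrasts used
  here.

## Synthetic-data generator

The generator emulates a 400-line maize panel: elite Dent and Flint pools
(100 each) and six landraces (11/33/14/53/30/59), three location–year
environments, two replicates, incomplete blocks; NIR reflectance on a
1,250–2,400 nm unit grid with 24 cup repetitions per plot. One seed fixes
the full stream; stage generators derive from it by fixed offsets.

* **Population:** Balding–Nichols divergence — ancestral frequencies
  Uniform(0.1, 0.9), group frequencies Beta-distributed around them with
  one FST parameter (default 0.15; the Hudson estimator recovers it).
  Within groups, lines come in **families** (default size 8) whose
  frequencies diverge from the group's by `family_fst` (default 0.3):
  doubled-haploid lines derived from the same source plants are highly
  related, and this within-group relatedness variation is precisely what
  kinship-based prediction exploits. Lines are homozygous up to an
  error-like heterozygosity. Assay quality is heterogeneous: a fraction
  of probes fails outright (default 14% all-missing) and per-marker
  missing/het rates are Beta-dispersed, so the QC steps have realistic
  work.
* **Trait:** additive over n_qtl loci acting on the true (complete)
  dosages, scaled to unit pooled within-group SD; optional evenly spaced
  group-mean offsets (`group_mean_shift`, in within-group SD units)
  confound structure with performance; `group_effect_corr` < 1 makes QTL
  effects partially group-specific — the regime where marker-based
  prediction transfers poorly between unrelated groups while remaining
  useful within a group. No linkage disequilibrium, dominance or
  epistasis is simulated.
* **Plots:** generated exactly under the plot model with independent
  normal effects; error-side components are scaled so the entry-mean H²
  hits a target given the realized genetic variance (GxE at half the
  error variance by convention; environment/replicate/block variances at
  1/0.1/0.1 of the genetic variance).
* **Spectra:** smooth deterministic baseline plus Gaussian absorption
  bands whose heights are linear in latent "chemistry" components; the
  latent components correlate (default 0.85) with each genotype's
  **within-group genetic deviation** and, by construction, carry no group
  signal — this is what makes phenomic prediction structure-robust in the
  simulation. Smooth per-environment deviations and iid measurement noise
  complete the model; repetitions are averaged by default (noise variance
  divided by 24) or emitted as rows on request. The study's source
  reports no quantitative spectral noise model, so the noise defaults are
  conventions stated in `SpectraConfig`; at those defaults the simulated
  per-wavelength heritabilities are near 1 — cleaner than real NIRS,
  which shows variable, sometimes much lower wavelength heritability.

### Packaged scenarios and problem sizes

Two seeded scenarios run the full pipeline at desk scale (a ~100 nm
spectral window, hundreds of markers; chosen so a scenario builds in about
a minute — the per-wavelength mixed-model fits dominate):

* `confounded_landraces` — the six landraces; the trait has **zero**
  within-group genetic signal (all QTL effects zero) and subgroup-mean
  offsets only. Pooled genomic CV then reports overall r ≈ 0.85 with
  r̄ ≈ 0, the structure artifact; phenomic overall r ≈ r̄ ≈ 0.1.
* `elite_landrace_panel` — all 400 lines; polygenic trait (150 QTL among
  1,000 markers, no group shift) with cross-group effect correlation 0.1,
  family_fst 0.4, H² target 0.9. Within-group genomic CV and composite
  training sets then sit around r ≈ 0.4–0.55, among-group genomic
  prediction near 0, and phenomic prediction ≈ 0.8 within, among, and
  composite alike. Those scenario parameters were set so the generator
  reproduces the qualitative pattern the analysis is about (within ≈
  composite ≫ among ≈ 0 for markers; flat for spectra) stably across
  seeds; without family structure the composite rescue does not occur,
  because equal-weighted foreign rows merely dilute the marker effects.

What passing these scenario tests shows: the pipeline's *mechanics*
(model fitting, QC, preprocessing, CV designs, decomposition) behave
correctly under data that has the assumed statistical structure. What it
does not show: performance on real spectra (scatter effects, vendor
preprocessing, wavelength-correlated noise), real linkage disequilibrium,
or real family pedigrees — none of which are simulated.

## Numerical conventions

* REML convergence: L-BFGS-B ftol 1e-15 / gtol 1e-9 plus Newton polish
  (gradient norm 1e-10) for single fits; relaxed (gtol 1e-6) for
  multi-response spectral fits.
* Boundary variance components: γ < 1e-7 is treated as zero and refitted.
* RR-BLUP λ search bounds [1e-5, 1e5]; an indefinite kernel gets a
  logged jitter.
* Fold allocation ties: subgroup name order, then RNG.
* Missing-call symbols accepted on ingest: `NA`, `NN`, `./.`, `.`, empty
  — all normalised to one internal code. Marker positions are 1-based
  and never used in computation.
* Matrix-text orientation is sniffed (markers usually outnumber
  genotypes) and logged; an explicit `orientation` argument overrides.

## Known limitations

* Mean imputation is a placeholder for haplotype-based imputation; it is
  adequate at the simulated missingness but discards linkage information
  real pipelines use.
* Group-specific heritabilities come from separate per-group REML fits —
  equivalent to dummy-variable heterogeneous-variance fits for disjoint
  groups, but error variances are not pooled across groups.
* The plot model assumes homogeneous error variance across environments;
  no spatial row-column modelling.
* The outlier screen runs on the joint multi-environment fit, once per
  trait; running it per environment would flag different plots.
* DAPC reassignment holds the PCA basis fixed in the leave-one-out loop.
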