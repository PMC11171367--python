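# Methods

## Statistical model

### SMR ratio test

For a probe with top cis-QTL variant *z*, let `b_zx ± se_zx` be the
per-allele effect on the molecular trait and `b_zy ± se_zy` the per-allele
log-odds effect on disease, both oriented to the same effect allele. The
effect of the trait on disease implied by the instrument is the Wald ratio
`b_xy = b_zy / b_zx`. Its significance is assessed with

    T_smr = z_zy² z_zx² / (z_zy² + z_zx²),  z = b / se,

which is bounded by the weaker of the two chi-square signals (so a probe can
never borrow significance it does not have on both sides) and is referred to
a 1-df chi-square. The delta-method standard error is
`se_smr = |b_smr| / sqrt(T_smr)`. Records with `b_zx = 0` or non-finite
standard errors are flagged non-computable rather than propagating NaNs.

### HEIDI heterogeneity test

Under pleiotropy (one shared causal variant) every cis-SNP in LD with the top
SNP estimates the *same* `b_xy`; under linkage (distinct causal variants)
estimates differ systematically. For instruments i = 1..k the test uses
deviations `d_i = b_xy(i) − b_xy(top)`, with delta-method covariance

    cov(b_xy_i, b_xy_j) ≈ r_ij se_zy_i se_zy_j / (b_zx_i b_zx_j)
                        + r_ij b_zy_i b_zy_j se_zx_i se_zx_j / (b_zx_i² b_zx_j²)

where `r_ij` is the signed dosage correlation from the reference panel (GWAS
and QTL samples are independent; within each study the covariance of marginal
estimates at two SNPs is approximated by `r · se_i · se_j`). The statistic
`T_heidi = Σ z_d(i)²` has null distribution `Σ λ_m χ²₁`, with λ the
eigenvalues of the deviation correlation matrix (eigenvalues below 1e-8 of
the largest are treated as null space).

Instrument selection (defaults, all configurable): QTL p < 1.57e-3
(z² > 10), LD r² with the top SNP in [0.05, 0.9], ranked by QTL
significance, at most 20 and at least 3 instruments; with fewer than 3 the
HEIDI p is reported missing and the probe cannot pass the filter. These
mirror the settings commonly used with the reference SMR tooling.

Pass rule: `p_smr < 5e-8` and `p_heidi > 0.05`, fixed thresholds with no
additional multiple-testing layer.

### Weighted chi-square tails

`weighted_chisq_tail` evaluates `P(Σ w_i χ²₁ > q)` by Ruben's series: for
positive weights, `Q/β` is an infinite mixture of central chi-squares with
df = n, n+2, …, whose mixing weights sum to one, giving a computable
truncation bound (series stopped when the remaining mixing mass is below
1e-12). `β = 0.90625·min(w)` per Ruben's convergence recommendation. A
Liu–Tang–Zhang moment-matching approximation (`method="ltz"`) is provided
for speed; it agrees with the exact series to ~1e-2 in the worst case and
much better near conventional significance levels. An Imhof-type inversion
integral was prototyped and rejected: the oscillatory integrand decays too
slowly for general-purpose quadrature when the smallest eigenvalue is small,
whereas the series is unconditionally stable for the positive-weight case
needed here. Tests validate the series against large Monte-Carlo samples.

### PRS construction and scoring

The functional model takes the unique passing top SNPs (union over scans,
e.g. eQTL + mQTL) weighted by their GWAS betas. `combine_models` is a set
union that *refuses* conflicting weights for shared variants — a combined
score is only meaningful under one weighting. `ld_prune` scans variants in
genomic order and drops any with r² above threshold (default 0.9) against an
already-retained variant; keeping the earlier variant makes pruning
deterministic and idempotent. Scoring follows plink `scoresum`: score =
Σ βₖxₖ over model variants present in the cohort, dosages flipped (x → 2−x)
when the model's effect allele is the cohort's other allele, missing dosages
imputed at twice the effect-allele frequency observed in the scoring cohort,
absent variants skipped with a logged count (never an error), and
`n_variants_used` always reported.

### Evaluation

AUC is the Mann–Whitney probability (ties counted half), its CI from
DeLong's structural-component variance. OR per SD is `exp(β)` from a
univariable logistic fit on the score standardised by the *pooled* sample SD
(control-only SD available as an option). The Youden point maximises
sensitivity + specificity − 1 over midpoints between adjacent distinct
scores, with the classification rule `score > threshold`; ties take the
smallest threshold (maximal sensitivity). The high-risk rule thresholds at
the 80th centile of *control* scores (type-7 / linear-interpolation
quantile) with strict inequality, so with continuous control scores and
n_controls divisible by 5 specificity is exactly 0.8; heavily tied
(few-variant, integer-dosage) scores can push specificity above 0.8 because
tied individuals fall below the strict threshold. For any binary classifier
the reported `auc_binary` is (sensitivity + specificity)/2 exactly. The
two-score joint model is a logistic fit on both standardised scores with the
AUC of the fitted linear predictor; a (near-)collinear second score is
dropped before fitting so the joint AUC degrades exactly to the single-score
AUC. Prospective cohorts (incident case = 1) are evaluated identically to
case-control samples; no time-to-event modelling is attempted.

### Variant-count subsampling

Each iteration draws `i` distinct variants uniformly (not
weight-proportional) without replacement, rescans the cohort, and records
the AUC; a master seed spawns one substream per iteration. Columns are
processed in canonical (model) order so that exact score ties — common with
integer dosages — do not depend on the draw order, and the full-set draw
takes the uncopied code path, making `i = |model|` collapse exactly to the
full-model AUC.

## Synthetic data: what it emulates, and what it does not

The generators emulate the *shape* of a molecular-QTL × disease-GWAS × PRS
study at desk scale: block-structured LD (equicorrelated latent-Gaussian
haplotypes per block, Hardy–Weinberg genotypes, the latent correlation
calibrated numerically so the realised *dosage* correlation matches the
requested target at the block's mean MAF); cis-QTL summary statistics from
per-variant OLS of a simulated trait in an independent sample; GWAS summary
statistics from per-variant logistic regressions (statsmodels) in a sampled
case-control set; and cohorts whose outcome follows a logistic model on a
known true score. Case-control sampling at base rate 0.5 only shifts the
intercept, leaving per-variant log-odds effects interpretable.

Architectures: under **pleiotropy** the causal variant's marginal disease
effect equals `b_zx·b_xy` by mediation (the trait, including its noise,
enters the liability — so the marginal logistic coefficient is attenuated by
~1% at the default noise level, well inside Monte-Carlo tolerances); under
**linkage** a distinct variant in the same block carries a direct effect;
under **null** everything is noise, and QTL/GWAS p-values are uniform.

Not emulated: realistic allele-frequency spectra and LD decay with distance
(blocks are equicorrelated), population stratification and relatedness,
genotyping/imputation error, covariates, age structure in prospective
follow-up, and trans effects. Passing tests therefore certify the
statistical machinery — calibration, invariants, recovery of planted effects
— not robustness to those real-data complications.

## Default study conditions

The bundled demonstration (`SimulateConfig`) scales the target study design
to a laptop: 300 variants in 30 blocks (within-block r = 0.55, MAF
0.1–0.5), a 2,000-haplotype-model panel, QTL studies of n = 5,000, a GWAS of
10,000 cases / 10,000 controls, and a case-control cohort of 1,500/1,500
(the real counterparts are ~10⁵ GWAS subjects and 3,560/3,383 cohort
members). Effects `b_zx = 0.5`, `b_xy = 0.35` make pleiotropic top SNPs
clear genome-wide significance at this reduced GWAS size, mirroring how
established risk loci sit far past threshold at full scale;
`b_zy_direct = 0.18` gives linkage probes comparable GWAS signal so that
HEIDI, not SMR, must reject them. Half the remaining variants carry N(0,
0.08) background effects so a many-variant "GWAS PRS" exists to benchmark
against. Calibration experiments (HEIDI type-I error) instead use a single
clean pleiotropy block with no background effects, since background hits in
LD with the probe are genuine heterogeneity. Simulation sizes in tests and
the acceptance script (e.g. 500 scan replicates for calibration, 200
subsampling iterations) were chosen to keep Monte-Carlo error comfortably
inside the asserted tolerances at desk-scale runtimes.

## Numerical and design choices

- Variant identity is the ID string within one run (all files derive from
  one panel); allele harmonization is strand-aware for summary statistics
  (complement matching; palindromic A/T and C/G variants resolved by allele
  frequency only when both sides are at least 0.08 away from 0.5, else
  dropped and counted) and label-trusting for genotype scoring, where weight
  files and cohort share a strand convention.
- "LD" means squared dosage correlation r² estimated from the panel; signed
  r is retained internally for HEIDI covariances.
- Monomorphic variants in a realized GWAS sample keep their record with
  `se = inf`, `p = 1` sentinels; logistic non-convergence / separation is
  treated the same way.
- Determinism: every generator is a pure function of (inputs, seed); the
  pipeline writes a provenance JSON with a config hash and SHA-256 of every
  artifact, and a rerun with the same config is bit-identical.
- Degenerate inputs: all-identical scores give a Youden point with J = 0 and
  a warning; empty instrument sets give a missing HEIDI p; an empty scan or
  a model with no variants present in the cohort raises.

## Known limitations

- HEIDI's type-I error is nominal only with strong instruments; with very
  weak QTL signals the ratio estimates are non-normal and the test can drift
  (the instrument p-threshold guards against the worst of this). Measured
  type-I error at the default calibration settings is ~0.05–0.07.
- The LD calibration targets the block's mean MAF; with wide MAF ranges the
  realised pairwise r² varies around the target.
- The established "GWAS PRS" in the pipeline is built from
  genome-wide-significant variants of the simulated GWAS, LD-pruned and
  beta-weighted — a stand-in for an externally trained score; externally
  supplied weight files are supported everywhere but none are bundled.
- VCF-derived panels support LD estimation but not resampling (the
  generative block metadata only exists for simulated panels).
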