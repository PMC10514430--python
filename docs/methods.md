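# Methods

## Model and estimands

The package estimates the effect of genetically proxied HbA1c lowering via
metformin's targets on cardiometabolic outcomes. The structural model is the
standard instrumental-variable one: for variant j with per-allele exposure
effect β_Xj (HbA1c, SD units; 1 SD is treated as a 0.62 percentage-point
absolute change throughout) and outcome effect β_Yj, a valid instrument
satisfies β_Yj = θ β_Xj, and θ is identified from summary statistics by the
Wald ratio β_Yj/β_Xj. Binary outcomes use log odds ratios, so θ is a log OR
per SD and exp(θ) the reported OR.

Sign convention: tables are first harmonized to a common effect allele, then
re-signed so the effect allele is the HbA1c-*lowering* allele; `beta_exposure`
becomes the (positive) number of SD lowered per allele and all causal
estimates read as outcome change per 1 SD lowering. Negative β / OR < 1 is
the protective, drug-mimicking direction.

### Estimators

- **Wald ratio** — delta-method SE `sqrt(se_Y²/β_X² + β_Y² se_X²/β_X⁴)` by
  default; the one-term `se_Y/|β_X|` is available behind a flag.
- **IVW** — weighted mean of ratios, weights 1/se². "Fixed effects" uses
  `1/√Σw`; the default random-effects version inflates that SE
  multiplicatively by `max(1, √(Q/(k−1)))`, matching the convention of the
  common two-sample MR toolchain; an additive DerSimonian–Laird variant is
  available behind a flag. A single-variant table routes to the Wald ratio
  and is labelled so.
- **Cochran's Q** — `Σ w_j (β̂_j − β̂_IVW,fixed)²` against χ²(k−1).
- **Weighted median** — interpolated weighted median of the ratios at
  cumulative weight 0.5 (midpoint convention, weights normalized); SE by
  seeded parametric bootstrap resampling per-variant betas from their
  sampling normals.
- **Simple/weighted mode** — argmax of a normal-kernel density of the
  ratios over a 2048-point grid, bandwidth `φ·0.9·min(sd, iqr/1.34)·k^(−1/5)`
  (φ = 1 by default); degenerate spread returns the common ratio. SE by the
  same bootstrap.
- **Multivariable IVW** — weighted regression (weights 1/se_out²) of outcome
  betas on m exposure-beta columns without intercept; SEs carry a
  multiplicative overdispersion factor floored at 1. An all-zero exposure
  column is reported with zero direct effect and excluded from the design,
  so a single remaining exposure reduces exactly to univariable IVW.
- **Two-stage least squares** — stage 1 regresses observed HbA1c on the
  weighted allele score plus covariates (age, sex, array, PC1–PC10); stage 2
  regresses the outcome on the stage-1 fitted values plus covariates. The
  variance uses the conventional IV estimator with residuals formed from the
  *observed* exposure; a heteroskedasticity-robust sandwich is optional.
  Estimates are negated to the per-SD-lowering scale.
- **Within-cohort two-sample workflow** — exposure effects come from the
  external instrument set (winner's-curse protection), outcome effects from
  covariate-adjusted per-variant regressions inside the cohort; the summary
  pairs then run through the two-sample battery.

P-values are two-sided normal for all estimators (large-sample GWAS
convention, not t).

### Instrument selection

Four filters, applied per target region: cis window (±500 kb around the
lead — smallest-P — cis-eQTL variant, the reading adopted for a single
500 kb window anchored at a "central" variant), eQTL P < 0.01, HbA1c
P < 0.05, MAF ≥ 1%; the region as a whole must colocalize (PP.H4 > 0.7,
computed once per region; a failing region drops all its variants).
Clumping is greedy at r² < 0.001, ranked by HbA1c P — the therapeutic axis —
with p-value ties (which occur when P underflows at extreme z) broken by
|z| descending, then position, then allele order; retained instruments carry
the HbA1c association as their exposure effect. Clumping is within-target;
the registry of reference counts records both the seven-target configuration
(sum 34) and the five-target subset (sum 32). Benchmark instruments for
circulating HbA1c require P < 5×10⁻⁸ for both HbA1c and type 2 diabetes and
clump at r² < 0.01.

Instrument strength: per-variant F = (β/se)² (squared-z approximation —
the specific "approximate approach" is not otherwise pinned down, so this
standard form is adopted and documented); per-variant R² = 2p(1−p)β²/Var;
aggregate R² sums per-variant values (independence after clumping);
aggregate F = R²(n−k−1)/((1−R²)k). Aggregate F < 10 flags a weak set, and
the one-sample grid drops targets whose score F falls below 10 from
target-specific runs (the GCG-style exclusion).

### Colocalization

Classic single-causal-variant-per-trait ABF colocalization: per-variant
Wakefield log-ABF `0.5·log(1−r) + 0.5 z² r`, `r = W/(se²+W)`, with prior
effect SD W^0.5 = 0.15 for continuous and 0.2 for binary traits; priors
p1 = p2 = 1e-4, p12 = 1e-5. Configuration sums are done in log space
(log-sum-exp; H3 via a stable log-difference), so |z| up to ~100 cannot
overflow. "Colocalization probability" is operationalized as PP.H4;
PP.H3+PP.H4 is also exposed.

### Harmonization

Allele alignment tries direct match, swap, then strand complement; swap
negates the outcome beta and complements its EAF. Palindromic (A/T, C/G)
variants with MAF > 0.4 on either side are dropped (minor-allele frequency
computed as min(f, 1−f) on each side — the conservative reading); below
that, orientation is inferred from allele-frequency agreement (toggleable).
Instruments absent from the outcome dataset are replaced by the highest-r²
proxy with r² > 0.8 within ±500 kb (ties broken by distance then id),
alleles mapped through the LD panel's signed r; the proxy substitutes on the
outcome side only. Irreconcilable alleles drop the row with a warning, never
a hard error; every row leaves with exactly one action/reason code.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the pipeline assumes:

- Seven target regions, one per chromosome, with block-exchangeable LD
  (within-block correlation 0.9, blocks of 5, zero across blocks). The
  number of causal eQTL variants per target follows the instrument registry
  (26/3/1/1/1/1/1), one per block, so clumping at r² < 0.001 retains
  exactly the causal set. Each region has one dominant lead eQTL
  (standardized effect ≈ 0.5 vs 0.15–0.3 for secondaries); without a
  dominant shared signal, single-causal-variant colocalization on a
  multi-signal region legitimately drifts to H3 when noise reorders the two
  traits' top variants — the lead structure mirrors the single strong
  shared signal per gene that criterion assumes.
- The causal chain: expression → HbA1c (default 0.15 SD/SD) → outcomes.
  Default outcome effects per SD HbA1c *increase* are +0.22 kg/m² BMI,
  +0.19 mmHg SBP, +0.29 mmHg DBP, log(1/0.62) log-odds CAD, log(1/0.57)
  log-odds T2D — so the pipeline's per-SD-lowering estimates land on the
  familiar protective values. The reference one-sample DBP value (−0.90)
  cannot coexist with the two-sample −0.29 under one truth; the 2SLS
  recovery experiment sets the DBP truth to 0.90 explicitly.
- Summary statistics come from the closed-form marginal expectation
  (R·β on the standardized scale) plus correlated sampling noise
  (covariance R/n), at sample sizes 31,684 (eQTL), 344,182 (HbA1c) and
  466,947 (outcomes; binary traits use an effective variance of
  case-fraction × (1 − case-fraction), case fraction 0.10). This is
  distributionally equivalent to per-variant regression on a simulated GWAS
  sample at a fraction of the cost. P-values floor at the smallest positive
  float.
- A 23-variant independent "glycemic biomarker" panel with strong direct
  HbA1c and T2D effects (log-odds ≈ 1.2 × HbA1c effect — glycemic loci are
  strong diabetes loci) feeds the benchmark selection.
- Harmonization stressors: a configurable fraction of palindromic alleles
  (EAFs split between 0.41–0.49 and 0.10–0.35 to exercise both branches of
  the MAF-0.4 rule), allele-swapped emission of outcome rows, optional
  missingness to force proxy substitution.
- The cohort (default n = 338,425) draws dosages for every region variant
  block-by-block by latent-Gaussian thresholding of two haplotypes; the
  realized dosage LD is mildly attenuated relative to the latent correlation
  (a property of thresholding, documented rather than corrected — it costs
  one-sample efficiency, not consistency). HbA1c has unit variance by
  construction; outcomes are causal-effect × (full) HbA1c plus optional
  direct (pleiotropic) variant effects, small fixed covariate effects, a
  shared unobserved confounder, and noise scaled to realistic phenotypic SDs
  (BMI 4.7 kg/m², SBP 19 mmHg, DBP 10 mmHg). Using the full exposure plus a
  confounder (rather than only its genetic component) keeps 2SLS consistent
  while making naive OLS biased — the situation MR exists for.

Not emulated: realistic genome-wide LD maps, imputation quality, sex
chromosomes, selection into the cohort (a non-diabetic selection rule on a
latent liability is sketched as an extension point but off by default),
sample overlap between exposure and outcome GWAS, and winner's curse from
aggressive significance thresholds (the generator's instruments are strong,
z ≈ 13–44, so the P < 0.05 exposure filter barely truncates). Passing tests
therefore demonstrate correctness of the estimators and plumbing under the
assumed model, not robustness to the full messiness of real cohort data.

## Experiment designs and problem sizes

Coverage and error rates are sample-size-free properties, so the experiment
suites run at sizes chosen for seconds-scale runtimes while keeping the
asymptotic regime the estimators assume (strong instruments, F ≫ 10):

- IVW recovery: 100 replicate full summary-level studies (generation →
  selection → harmonization → IVW) at study-scale GWAS sizes; the 95% CI
  must cover the BMI truth −0.22 in ≥ 93/100.
- 2SLS recovery: one summary-level truth, 100 replicate cohorts of
  n = 20,000 (score F ≈ 10³); CI coverage of the DBP truth −0.90 in
  ≥ 93/100. At much smaller n the ratio estimator's finite-sample tails
  distort coverage — a property of 2SLS, not of the implementation.
- Cochran's Q calibration: 1000 homogeneous 34-instrument tables; rejection
  rate at α = 0.05 must lie in [0.03, 0.07]. Q inherits slight conservatism
  from exposure-side noise in the delta-method weights (NOME violation),
  sitting near 0.03 at the chosen instrument strengths.
- 2SLS null calibration: 1000 cohorts of n = 1500 with a strong first stage
  and a null causal effect; rejection rate in [0.03, 0.07].
- Weighted-median robustness: 200 seeds of 50 valid (truth −0.3) + 20
  pleiotropic (ratio shifted +0.5) instruments with >50% of weight valid;
  mean estimate within 0.05 of the truth.
- Oracle equivalences: IVW-fixed vs statsmodels WLS (1e-10); coloc vs
  brute-force configuration enumeration (1e-10, up to 20 variants); Wald
  delta SE vs 10⁶-draw Monte-Carlo propagation (relative error < 2%);
  Wakefield ABF vs direct quadrature of the marginal-likelihood ratio.

`scripts/acceptance.py` re-runs all of the above from a single seed and
additionally averages the headline IVW grid over 20 replicate studies so the
reported betas/ORs reflect the generating conditions rather than one
realization's noise.

## Numerical and design choices

- Log-space throughout colocalization; H3's log-difference clamps at −inf if
  cancellation would go negative.
- Clumping is deterministic under row permutation (stable mergesort, total
  ordering).
- Bootstrap SEs are seeded and reproducible for a fixed row order; point
  estimates are order-invariant.
- Multiplicative (not additive) random effects as the IVW default, floored
  at no deflation, reproducing the IVW / IVW-fixed duality of the reference
  result tables.
- Bonferroni flagging uses strict inequality at α/n (0.05/8 → 0.00625,
  printed as 0.006).
- Trial triangulation rescales MR effects linearly in HbA1c dose
  (trial %-reduction / 0.62), point and CI bounds identically; concordance
  = overlapping 95% CIs with same-signed point estimates. The linearity is
  an assumption, stated, not a derived fact.
- Orientation state (`oriented`) travels with serialized harmonized tables
  so a round-trip through TSV cannot silently re-orient.
- Genetic scores weight the lowering-allele dosage by |β_X|; unweighted
  allele counts are available behind a flag (the weighted form is assumed).
- MR-Egger is deliberately absent from the default battery (not part of the
  reference analysis); the regression machinery in `mvmr` permits adding it.

## Known limitations

- Single-causal-variant colocalization understates H4 in regions with many
  comparable shared signals; a SuSiE-style multi-signal extension is out of
  scope.
- Aggregate R²/F assume exact independence after clumping; residual r² up
  to the clump threshold is ignored.
- The 2SLS variance is homoskedastic by default; the sandwich option exists
  but robust small-sample refinements (e.g. Anderson–Rubin intervals) are
  not implemented.
- Proxy substitution transfers the outcome association only; no attempt is
  made to impute the proxy's exposure association from LD.
- The cohort generator draws covariates independently of genotype, so
  covariate adjustment in 2SLS is observable but not strictly necessary —
  population stratification is not emulated.
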