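# Methods

## Score model

The genetic risk score is a weighted allele count over a fixed SNP panel:
GRS_j = Σ_i w_i g_ij, where g_ij is the dosage of the *modeled* allele
(0/1/2 copies) and w_i its log-odds-scale weight. The modeled allele is the
allele whose copies are counted; protective alleles keep their counting
orientation and carry negative weights (4 of the 12 panel weights are
negative), so the sign pattern of the published weight table is preserved
rather than re-orienting to minor or risk alleles. The canonical 12-SNP
panel ships with the package (`load_panel("af12")`); a 9-SNP one-per-gene
reduction (`"af9"`) keeps only rs2200733 among the four PITX2 SNPs, with
weights carried over unchanged — the source analysis gives no indication the
reduced model was re-fit, and re-estimating weights would require the
original discovery data.

Missing genotypes are replaced by the *observed sample mean* dosage at that
marker (additive coding), not by the Hardy–Weinberg expectation 2f; 2f is
only a logged fallback for a column with no observed calls at all. Mean
imputation guarantees every participant a finite score and exactly preserves
observed column means.

Quintile/tertile stratification uses type-7 (linear-interpolation) sample
quantiles as cut points and closed-upper membership: a score exactly equal
to a cut point falls in the lower group. With ties this can make group
sizes unequal; that is the intended behavior, not an error. Labels are
invariant to strictly monotone transforms of the score.

## Synthetic cohorts

The simulator emulates the structure the analysis assumes, not any real
dataset:

* **Genotypes.** Independent SNPs are Binomial(2, f_i) (Hardy–Weinberg at
  the panel frequencies). One designated pair — by default the two key
  PITX2 SNPs rs2200733/rs10033464 — is drawn from a two-locus haplotype
  distribution parameterized by signed disequilibrium D, with haplotype
  frequencies f_a f_b + D, f_a(1−f_b) − D, (1−f_a)f_b − D,
  (1−f_a)(1−f_b) + D, so single-SNP marginals are exact and the dosage
  covariance is 2D. D is bounded by the admissible range for the two
  frequencies; requesting more is an error that reports the bound. The
  default is half the most-negative admissible value (D ≈ −0.0065): the
  direction (negative) is established for this pair but the magnitude in
  the study population is not published, so the default is deliberately
  mid-range and the parameter is exposed.
* **Covariates.** Independent margins matched to the study cohort: age is
  truncated normal at the 40-year inclusion bound (rejection sampled), with
  the latent location calibrated by root finding so the *post-truncation*
  mean equals the 66.2 y target — a latent mean of 66.2 would drift ~0.4 y
  upward after truncation; SD 11.8 y. Male 341/904, current smoker 84/904,
  BMI ~N(29.6, 6.8²) kg/m², diabetes 201/904, hypertension 693/904, prior
  MI 80/904, heart failure 49/904. No covariate–covariate or
  covariate–genotype correlation is modeled (only margins are published);
  passing tests therefore say nothing about confounding structure in real
  cohorts, where age and comorbidities co-vary.
* **Outcome.** Bernoulli per participant. Either fixed per-quintile
  absolute rates (default 4/6/8/10/12%: a 2-percentage-point rise per
  quintile around an 8% mean, i.e. half the average in the lowest quintile
  and 1.5× in the highest), with quintiles taken from the simulated score
  distribution; or a logistic model expit(β₀ + β_g·GRS + β_cᵀx), where β₀
  may be auto-calibrated by bisection to hit a target marginal rate (the
  study's 85/904 ≈ 9.4% is the conventional target). All draws flow from a
  single seeded `numpy` Generator; identical configs are bit-reproducible.

## Association statistics

* Baseline two-group comparisons use the Welch (unequal-variance) t-test
  for quantitative traits — computable from (mean, SD, n) summaries as well
  as raw data — and the Yates continuity-corrected χ² for 2×2 tables.
  These specific choices reproduce the published baseline p-values from the
  published summaries; the pooled t and uncorrected χ² do not.
* Logistic models are maximum likelihood (statsmodels), odds ratios
  exp(β) with Wald 95% CIs on the log scale. Per-SD coding standardizes the
  score by its sample SD; quintile/tertile codings dummy-code against the
  lowest group; ordinal coding enters the quintile index 1–5 as a single
  quantitative term. Non-convergence and separation raise an explicit
  error (including a |β| > 15 guard against silent quasi-separation) rather
  than returning unstable estimates.
* Discrimination is the C-statistic (ROC AUC) of fitted probabilities;
  nested models (covariates vs covariates + GRS) are compared with the
  paired DeLong test. The source analysis reports a p-value for the
  C-statistic increase without naming a method; DeLong is the field
  standard for paired AUCs and is the package's choice. The implementation
  uses the midrank structural-components formulation and matches
  `pROC::roc.test` to ≥6 significant digits on a frozen fixture.
* The per-SNP scan fits one additive-dosage logistic model per SNP,
  unadjusted and adjusted; monomorphic SNPs are flagged and skipped, and
  the dosage correlation of the PITX2 pair is reported alongside.

## Power experiment

The prospective design assigns n participants evenly to 5 quintiles
(quintiles are equal-sized by construction) with the absolute-rate gradient
above, draws events, and tests the quintile–event association; power is the
rejection fraction at two-sided α. The default test is the Wald test on the
ordinal quintile term of a logistic fit (on the 5 aggregated binomial rows,
which is likelihood-identical to the participant-level fit and much
faster); a Cochran–Armitage trend test is selectable since the original
claim does not name the test — both comfortably exceed 90% power at
n = 1,000. Replicates with zero events count as non-rejections and are
logged. Expected events are n·mean_rate analytically (80 at n = 1,000).
Default 2,000 replicates, reported with the binomial Monte-Carlo SE
(~0.6% at the observed power); the original replicate count is unreported.

## Problem sizes and tolerances

Stochastic checks are sized to keep Monte-Carlo error well below the
assertion bands: 2,000 replicates for power (SE ≈ 0.6%), 500 cohorts of 904
for per-SD odds-ratio recovery (the replicate mean is compared within 3 MC
SEs of the truth on the log scale, and 95% CI coverage within 93–97%),
50,000 participants for the closed-form population-mean check (3 MC SEs),
150 null cohorts × 12 SNPs for scan calibration. Closed-form identities are
asserted to 1e-10…1e-12; the saturated 2×2 logistic reproduces ad/bc to
1e-6 relative.

## Known limitations

* Quintile cut points and cohort-specific estimates (observed score range,
  per-quintile ORs, C-statistics) are data-dependent; on synthetic cohorts
  they are recovered only in distribution, which is what the
  parameter-recovery tests check.
* The simulator draws covariates independently and models LD for a single
  SNP pair only; no population structure, ancestry admixture, or
  genotype-calling error is represented.
* VCF support matches records by rsid and requires the modeled allele to
  equal REF or an ALT — no strand flipping or position-based matching.
  Writing VCF requires integer dosages (imputed values are CSV-only).
* No time-to-event modeling, genotype QC, or multiple-testing correction
  for the per-SNP scan (none is part of the reproduced analysis).
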