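# afgrs — a 12-SNP genetic risk score for atrial fibrillation

Atrial fibrillation (AF) is the most common pathological arrhythmia and a
major cause of embolic stroke, yet it is frequently silent: patients present
with palpitations or syncope, wear an ambulatory rhythm monitor for ~2 weeks,
and may or may not manifest an AF episode in that window. Common variants
near PITX2, ZFHX3, KCNN3 and other loci are robustly associated with AF, and
a weighted genetic risk score (GRS) over such variants can stratify the
short-term probability of a positive monitoring result beyond clinical risk
factors alone.

`afgrs` implements that analysis as a tested, reusable pipeline for
epidemiologists and methodologists working with small SNP panels:

* **Scoring** — the weighted allele-counting GRS over a 12-SNP panel
  (built-in, with a one-per-gene 9-SNP reduction that keeps only rs2200733
  for PITX2), with mean imputation of missing genotypes and
  quintile/tertile stratification.
* **Simulation** — synthetic cohorts with Hardy–Weinberg genotypes at the
  panel frequencies, configurable negative linkage disequilibrium between
  the two key PITX2 SNPs, study-matched covariate margins (mean age 66.2 y
  truncated at the 40-year inclusion bound, 38% male, 77% hypertensive, …)
  and Bernoulli AF outcomes from either per-quintile absolute rates or a
  logistic model with a calibrated intercept.
* **Association statistics** — baseline two-group tables (Welch t /
  Yates-corrected χ²), logistic odds ratios under per-SD, quintile-dummy,
  ordinal-trend and tertile codings with Wald 95% CIs, C-statistic
  comparison of nested models by the paired DeLong test, and a per-SNP scan.
* **Power** — the prospective Monte-Carlo power experiment for a
  quintile-gradient design (absolute AF rate rising 2 percentage points per
  GRS quintile around an 8% mean in 1,000 participants).

## The score

For participant *j* with dosage *g<sub>ij</sub>* ∈ {0, 1, 2} copies of the
modeled allele at SNP *i* (real-valued after imputation),

&nbsp;&nbsp;&nbsp;&nbsp;GRS<sub>j</sub> = Σ<sub>i</sub> w<sub>i</sub> · g<sub>ij</sub>

with published log-odds-scale weights *w<sub>i</sub>* (four of the twelve are
negative — protective alleles are counted, not flipped). The theoretical
range is [−1.42, 3.46] and the population mean under Hardy–Weinberg
equilibrium is 2 Σ f<sub>i</sub> w<sub>i</sub> ≈ 0.454. Association is
summarized as the odds ratio per sample-SD increase in GRS and as odds
ratios of the upper quintiles/tertiles against the lowest.

## Worked example

Simulate a study-sized cohort, score it, and fit the adjusted quintile model:

```bash
afgrs simulate --n 904 --seed 7 --out demo
afgrs score --dosage demo/dosages.csv --out demo/scores.csv
afgrs associate --dosage demo/dosages.csv --covariates demo/covariates.csv \
                --coding quintile --adjusted --out demo/assoc
```

which logs

```
afgrs: simulated 904 participants, 95 AF events
afgrs: scored 904 participants (quintile bounds [0.11 0.3  0.51 0.77])
```

and writes `demo/assoc/association_0_quintile_adj.tsv`:

```
term        or      ci_low  ci_high p_value   or_ci
quintile_1  1.0                               Reference
quintile_2  0.893   0.335   2.379   0.82      0.89 (0.34-2.38)
quintile_3  2.131   0.939   4.837   0.070     2.13 (0.94-4.84)
quintile_4  2.727   1.210   6.147   0.016     2.73 (1.21-6.15)
quintile_5  5.062   2.341   10.948  3.8e-05   5.06 (2.34-10.95)
```

Each row is the odds of an AF event in that GRS quintile relative to the
lowest quintile, adjusted for age, sex, smoking, BMI, diabetes,
hypertension, prior myocardial infarction and heart failure: under the
default generating design (absolute AF rate 4%→12% across quintiles) the
odds ratios rise monotonically in expectation, and in this realization the
top quintile carries about five times the odds of the bottom one. The JSON
report alongside echoes the seed, configuration and package version.

The power experiment:

```bash
afgrs power --reps 2000 --seed 1
```

```json
{
  "power": 0.9155,
  "mc_se": 0.0062,
  "mean_events": 80.1,
  "expected_events": 80.0
}
```

i.e. a cohort of 1,000 with AF rates 4/6/8/10/12% per quintile yields ~80
events and rejects the null of no quintile–AF association (Wald test on the
ordinal quintile term, two-sided α = 0.05) in ≈92% of replicates.

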