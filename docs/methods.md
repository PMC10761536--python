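# Methods

This note documents the statistical procedures pocagree implements, the
assumptions behind them, the synthetic-study generator used to exercise them,
and the numerical choices made where the design was genuinely open.

## Data model and below-LLOQ handling

Measurements live in a long-format table keyed by (animal, analyte, matrix,
device, replicate). Glucose is carried in mg/dL, β-hydroxybutyrate (β-HB) in
mmol/L; no unit conversion is ever attempted. The reference laboratory
measures plasma only, so every POC block — whole blood or plasma — is compared
against the plasma reference value of the same animal.

Readings below an instrument's lower limit of quantification arrive as a
censoring token `<X` (X = the LLOQ). They are parsed into an explicit
`censored` flag, kept as NaN, and only replaced when `impute_lloq` is applied:
every censored value becomes LLOQ/2 (20 mg/dL → 10 mg/dL; 0.1 mmol/L →
0.05 mmol/L). Half-LLOQ substitution is the single-imputation convention that
introduces the least bias into downstream means; it still biases any quantity
that depends on the censored tail, which is why the flag is retained and every
report counts imputed values, and why the slope/intercept calibration of the
regression procedures is assessed on uncensored data (below). Values above a
device ULOQ are flagged in the log but never altered. Pairs are ordered by
animal id; the rank procedures downstream are order-invariant, so this fixes
reproducibility without affecting results.

Missing covariates (weight, PCV, buffy coat) drop an animal from the mixed
model only — with a logged warning — never from the agreement statistics.

## Error metrics

* `CV% = sd(replicates)/mean × 100`, sample (n−1) standard deviation. The
  denominator choice is not prescribed by any of the formula sources; n−1 is
  used everywhere in the package.
* `Bias% = (mean_ref − mean_POC)/mean_ref × 100`. Note the sign convention: a
  meter that reads high yields a negative Bias%.
* `TE_obs% = 2·CV% + Bias%`. TE_obs is a magnitude-style quality metric, so
  the bias magnitude enters by default; a signed variant is exposed
  (`signed=True`). Veterinary QC guidance (ASVCP) regards TE_obs above
  10–20% as undesirable; the package reports the value and leaves verdicts to
  the reader.
* Relative error per pair: `RE% = (POC − ref)/ref × 100`. Zone proportions
  count pairs with |RE| strictly below 12, 15 and 20% — the absolute value is
  the only reading under which the proportions are meaningful, and the strict
  inequality follows the regulatory phrasing. Pairs containing an imputed
  member are included but counted and flagged in the output.
* Replicate precision in reports is the mean of per-animal CVs across the
  replicate subset (the pooling rule is unspecified in the source design;
  averaging per-animal CVs keeps each animal's mean as its own denominator).

## Bland–Altman

Differences are d = POC − reference. Limits of agreement are
`d̄ ± 1.96·sd(d)` — the 1.96 is the definition of the LoA, deliberately a
normal quantile. Confidence intervals use Student-t quantiles with df = n−1:
`d̄ ± t·sd/√n` for the bias and `LoA ± t·sd·√(3/n)` for each limit, the
large-sample variance approximation Var(LoA) ≈ 3σ²/n from the classical
method description. Whether t or z quantiles were used in any given published
table is rarely stated; `use_t=False` switches to z for comparison. Bias is
flagged significant when its CI excludes 0. Zero-variance differences are
legal: the LoAs and their CIs collapse onto the mean bias. No automatic
outlier handling exists; the CLI's `--exclude-ids` removes animals from plot
data only, mirroring the practice of excluding a visual outlier from plots
while keeping it in the statistics, and logs the exclusion.

## Passing–Bablok

All pairwise slopes S_ij = (y_j − y_i)/(x_j − x_i), i<j, with the original
procedure's degenerate-pair rules pinned explicitly: pairs identical in both
coordinates contribute nothing; vertical pairs contribute signed infinity;
slopes exactly −1 are removed; K counts remaining slopes < −1. The slope is
the K-shifted median (1-indexed: S_{(N+1)/2+K} for odd N, the average of
S_{N/2+K} and S_{N/2+1+K} for even N); the shift makes the estimator
invariant under exchange of the two methods. The CI takes the order
statistics at distance C = z_{1−α/2}·√(n(n−1)(2n+5)/18) around the median,
again offset by K; M1 = round((N−C)/2) uses round-half-away-from-zero (the
method papers say only "rounded to the nearest integer"). The intercept is
median(y − b·x), with CI bounds obtained by plugging the slope CI bounds into
the same median. Constant bias ⇔ intercept CI excludes 0; proportional bias ⇔
slope CI excludes 1. No cusum linearity test is performed.

Two properties worth stating precisely:

* **Scale equivariance is local, not global.** Multiplying y by k > 0 scales
  all pairwise slopes by k, but the −1-slope exclusion and the K offset are
  defined at fixed thresholds, so exact equivariance holds only while no
  pairwise slope crosses −1 — in practice, on positively associated data. The
  tests assert it there. Shift equivariance (y + c) is exact always.
* **Calibration holds under the method's own error model.** The procedure
  assumes comparable measurement error on both variables. Simulated that way
  at n = 28 (error-sd ratio matched to the slope), the slope estimator's
  median bias is below 1% and slope-CI coverage is ≈95%. With noise on y
  only, the K offset induces a small upward median bias (~2% at moderate
  noise) — a property of the method, not of this implementation, which is
  verified against an independent brute-force enumeration oracle
  (`pb_oracle`, pure-Python loops and `statistics.median`) for exact equality
  on a thousand random instances.

Fewer than 10 points triggers a warning; the rank CI can become undefined at
very small n (the order-statistic index leaves [1, N]), which raises.

## Mixed model

For each (device, analyte), the response is the per-(animal, matrix)
difference d = POC − reference, modeled as

    d = Xβ + b_species + b_animal + e,
    b_g ~ N(0, σ_g²),  e ~ N(0, σ_e²)

with fixed effects: intercept, sex (F=0/M=1), centred weight, centred PCV,
centred buffy coat, and matrix (plasma=0/whole blood=1). Centring the
continuous covariates affects only the intercept and improves conditioning.
Individuals are nested in species by id construction; coding the two factors
as crossed is equivalent under nesting.

Fitting is REML with β and σ_e² profiled out: σ_g² = θ_g·σ_e², covariance
σ_e²·W(θ) with W = I + Σ_g θ_g Z_g Z_gᵀ, and the criterion
(n−p)·log σ̂² + log|W| + log|XᵀW⁻¹X| minimized over log θ (two parameters)
by L-BFGS-B from the deterministic start θ = 1, followed by a tight
Nelder–Mead polish (so estimates are invariant to row ordering) and a
boundary refinement: the profiled criterion is extremely flat as θ → 0 on
the log scale, so each subset of small components is pinned to the boundary
and the rest re-optimized, keeping the candidate with the smallest criterion.
Variance components may therefore land exactly on the θ ≈ 0 boundary, which
is reported and flagged, never an error; in that degenerate limit the fixed
effects coincide with ordinary least squares, and in the balanced one-way
layout the interior REML solution equals the closed-form ANOVA estimators —
both are asserted in tests, along with agreement with an independent REML
implementation (statsmodels MixedLM).

Wald t-tests use df = n_obs − p. This residual approximation is
anti-conservative for effects estimated between small groups (a Satterthwaite
correction is deliberately out of scope); for the within-animal matrix
contrast at the default design size the measured type-I error is ≈5%
(400-replicate simulation, tolerance ±2.5%). The covariate screen tabulates
which fixed effects have p < α per device/analyte.

## Synthetic studies

The generator emulates the motivating study design:

* **Cohort** — 28 animals: 6 cownose rays (3.85–6.8 kg), 10 Atlantic
  stingrays (0.8–1.8 kg), 4 southern stingrays (5.4–9.2 kg), 8 yellow
  stingrays (0.6–1.65 kg). Sex ~ Bernoulli(½); PCV ~ U(11, 32)%,
  buffy coat ~ U(0, 4)%, total solids ~ U(4.4, 8.1) g/dL.
* **Reference distributions** — species-specific lognormals (only ranges and
  medians are published; lognormals are chosen for positivity and right skew)
  with medians ≈26–48 mg/dL glucose and ≈0.22–0.31 mmol/L β-HB. Yellow
  stingrays carry a 10% per-animal chance of a ×20 β-HB spike, emulating the
  single ~5.4 mmol/L outlier such cohorts produce.
* **Measurement model** — measured = α + β·truth + matrix_effect·1[WB] + ε
  with ε ~ N(0, (σ₀ + σ₁·truth)²): constant plus proportional bias (exactly
  what Passing–Bablok detects) and heteroscedastic noise. Default device
  parameters give one meter a large positive offset (α=37 mg/dL, β=1.4), one
  mild proportional bias (α=−6, β=1.3), and one severe insensitivity (β=0.4)
  for glucose, with analogous β-HB settings; the reference method is identity
  with 2% proportional noise. Glucose LLOQ is 20 mg/dL on every instrument;
  β-HB LLOQ is 0.1 mmol/L on two meters and 0 (uncensorable) on one. Negative
  simulated readings are truncated at 0 and counted in the table metadata.
* **Replicates** — 5 extra readings per device/analyte/matrix on 2 animals of
  the last species, sharing the animal's truth (pure measurement noise).
* **Randomness** — one seed per study; every draw comes from a SeedSequence
  sub-stream keyed by (purpose, species/animal/device/analyte/matrix/
  replicate), so adding a device or replicate never perturbs other draws, and
  equal seeds give byte-identical CSVs.

What the generator does **not** emulate: assay chemistry, anesthesia or
venipuncture-site effects, sample-handling decay, inter-device correlation of
errors on the same drop of blood, or non-Gaussian meter noise. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under a plausible data-generating process, not that any physical meter meets
a performance claim.

## Problem sizes used in the checks

The simulation-based checks run at the study's design size (28 animals, two
matrices): Passing–Bablok CI calibration over 500 generated studies with
censoring disabled (half-LLOQ imputation deliberately biases censored values,
so slope/intercept coverage is only a meaningful expectation on uncensored
data; censoring behaviour is verified separately against its binomial
prediction), Bland–Altman bias-CI coverage over 2000 draws, oracle parity on
1000 random instances with n ∈ [10, 60], and the mixed-model type-I rate over
400 fits. Larger sizes change none of the conclusions; these were chosen as
comfortable desk-scale runs.

## Known limitations

* Half-LLOQ imputation is a single-imputation stopgap; heavy censoring (the
  low-reading glucose meter censors a third of animals) biases means, zone
  proportions and regression fits toward the imputed constant. Maximum
  likelihood or multiple imputation would be principled alternatives and are
  out of scope.
* TE_obs combines a replicate-subset CV with a cohort bias; with only two
  replicate animals the CV itself is an unstable estimate.
* The mixed model's df = n − p makes small-group fixed-effect tests (sex,
  weight, species-confounded covariates) anti-conservative; within-animal
  contrasts such as matrix are essentially unaffected.
* The LoA CIs use the classical 3σ²/n approximation, which is slightly narrow
  at very small n.
* No Deming regression, error-grid analysis, repeated-measures LoA, or
  allowable-total-error verdicts are implemented.
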