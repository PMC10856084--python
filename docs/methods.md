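# Methods

## Screening design

The screening engine builds two-level Plackett-Burman (PB) designs from
the standard cyclic generator rows for N ∈ {4, 8, 12, 20, 24} runs: row i
of the factorial block is the generator shifted cyclically by i, closed by
an all-minus row. Any subset of k ≤ N − 1 columns of such a block is
balanced (N/2 runs at each level) and mutually orthogonal
(XᵀX = N·I), which is what makes the one-contrast-per-factor analysis
exact. N = 16 has no cyclic generator (it comes from a Hadamard doubling
construction) and is not offered; requests for 12 < k ≤ 15 factors get the
20-run design. Dummy columns — design columns assigned to no physical
variable — are always placed last. Center points are all-zero coded rows
appended after the factorial block; run order is randomized by a seeded
Fisher-Yates shuffle and stored separately from the plan-order matrix, so
the same design object serves both analysis and execution.

Real factor levels map to the coded scale by
`coded = (x − center)/((high − low)/2)` with `center = (low + high)/2`;
the transform is exactly invertible, and the worklist assembler uses the
inverse to turn coded rows into per-run instrument settings (mL volumes
scaled to µL).

**Plan loading.** A plan CSV is reconstructed by coding each cell against
the supplied (or column-inferred, min/max) factor definitions. Rows coding
to ±1 everywhere are factorial; all-zero rows are center points. The
bundled example plan has a third case: its three replicated validation
rows sit at the column midpoint for most factors but at the *high* level
for the two fastest dispense speeds (discrete pump settings). The loader
therefore accepts replicated non-factorial rows as validation points and
stores them as all-zero coded, which matches how they are used: they are
held out of the fit, and the model's prediction at a validation point is
taken as b₀. Rows that are neither ±1-codable, all-mid, nor replicated are
a consistency error — silent coercion of a corrupted plan would bias every
contrast.

## Screening analysis

Each response is fitted by ordinary least squares of the factorial-block
responses on the coded columns plus intercept. On an orthogonal block this
equals the classical contrasts b₀ = mean(y), bᵢ = (1/N) Σ xᵢⱼ yⱼ; the
implementation nevertheless solves the generic least-squares problem so a
corrupted plan fails the rank check instead of silently mis-estimating
(the contrast shortcut is kept as an independent oracle in the tests).
Center replicates are excluded from the fit: their all-zero coding makes
them uninformative for main effects, and they are reserved for validation.

**Error from dummies.** With zero true effect, a dummy coefficient is pure
noise with sd σ/√N. Two estimates are exposed: `dummy_band`, the largest
absolute dummy coefficient (the screening rule: a factor is significant
iff |bᵢ| strictly exceeds the band), and `effect_se`, the RMS of the dummy
coefficients, which feeds an optional t-test with df = number of dummies.
With only two dummies both rules are weak — by symmetry a null factor
beats the band of two null dummies with probability 9/11 somewhere among
nine null factors — so the package reports flags together with the rule
and band used rather than pretending more resolution than the design has.

**Center-point validation.** The experimental mean of the n center
replicates carries the half-width t(1 − α/2, n − 1)·sd/√n. The same
half-width is applied to the predicted response b₀, and the model is
validated iff the two intervals overlap. How the prediction's dispersion
should be derived is genuinely open at this design size; applying the
replicate half-width to both intervals is the primary rule, and a
dummy-based alternative t(1 − α/2, df_dummy)·effect_se is reported
alongside as `predicted_halfwidth_dummy` so users can apply either.
The replicate RSD is reported with the verdict.

**Recommendation.** For each real factor the highest-priority objective
response in which it is significant decides the level: +1 when the
coefficient sign agrees with the objective (positive & maximize, negative
& minimize), −1 otherwise. Factors significant nowhere stay at 0 and are
annotated "free"; the full decision trace (deciding response, coefficient,
objective) is returned, since in practice these choices get argued over.

## Calibration and detection limits

Calibration is an unweighted least-squares line of PAR on nominal
concentration (pg/mL), including the zero level; 1/x-weighted WLS is
available behind a flag for strongly heteroscedastic data (the zero level
inherits the smallest nonzero level's weight). Detection limits follow
the ICH intercept-dispersion approach, LOD = 3.3 σ/S and LOQ = 10 σ/S,
with σ the standard error of the intercept by default (the residual sd is
selectable). Because both limits derive from one σ and S, LOQ/LOD is
exactly 10/3.3; a printed table that rounds the two limits independently
will not satisfy that ratio to the printed digits, and this package always
reports the internally consistent pair at full precision, rounding only
for display (limits to 2 decimals, percentages to integers, precision to
1 decimal).

Performance figures: precision is the sample RSD% of replicate CQI
(quality-control) determinations; accuracy is 100·mean(determined)/nominal.
Matrix effect and extraction recovery compare the three spiking-set means,
ME% = 100·Set2/Set3 and RE% = 100·Set1/Set2 — accuracy and recovery are
deliberately distinct operations despite both being ratio percentages,
because they answer different questions (bias against the nominal vs loss
across the extraction). Cartridge-reuse QC returns the largest prefix of
an extraction-intensity series whose RSD stays below a threshold (default
5%); a single extraction trivially qualifies. The solvent budget sums the
non-sample reagent volumes of one run's worklist (mL) and reports the
loaded urine volume separately; at the selected extraction conditions this
gives 1.4 mL of solvent per 1.0 mL of urine.

## Quantification and censoring

Concentrations are back-calculated as (PAR − intercept)/slope and censored
against the curve's limits: c ≥ LOQ quantified (these are the "positives"
counted in batch summaries), LOD ≤ c < LOQ retained but flagged below-LOQ,
c < LOD suppressed entirely (not clamped to zero) so the censoring remains
auditable. The LOQ boundary is inclusive. Batch reports are ordered by
(sample_id, analyte) and take the calibration curves as explicit inputs.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the instrument physics:

- **Screening responses**: y = b₀ + Σ bᵢxᵢ + N(0, sd) per run, additive
  noise; center rows scatter around b₀. Defaults plant the reported effect
  directions (wash composition +, equilibration volume −, loading speed +
  for peak areas; loading/wash speeds dominant and negative for duration)
  at roughly 10–15% of the intercept, with noise sd 2,000 counts
  (≈ 4% CV) for areas and 9 s for duration (matching the reported 1.3%
  replicate RSD); true replicate variability of the original experiments
  is unpublished, so these are assumptions. Negative draws for
  non-negative responses are resampled. Planting a coefficient on a dummy
  factor is rejected — it would contradict the error-estimation premise.
- **Calibration**: PAR = (a + b·c)(1 + N(0, CV/100)) at the six levels
  0–50 pg/mL; the zero level gets additive noise with sd = CV/100·a.
  Default lines and CVs per analyte: slope 0.019/0.020 PAR per pg/mL,
  intercepts 0.055/0.094, CV 18.7%/21.6%.
- **Spiking sets**: Set3 centered at a base response, Set2 at
  base·ME/100, Set1 at base·ME/100·RE/100, proportional noise; defaults
  ME 93%/88% and RE 77%/79%, four replicates, CV 5%.
- **Batches**: 23 samples by default with planted positives (27 and
  182 pg/mL for one analyte, 95 pg/mL for the other) mapped through the
  calibration line; all other sample×analyte pairs draw a PAR uniformly
  below the PAR-equivalent of the LOD, so they censor below detection.
  When curves are not passed in, they are derived deterministically by
  simulating and fitting one calibration per analyte from the same config.

Every generator is a pure function of (config, seed); the `seed` key is
mandatory in configs. Proportional (CV-based) Gaussian noise is an
idealization: real MRM peak areas show drift, carryover, integration
artifacts and occasional gross outliers, none of which are emulated, so
passing recovery tests demonstrate correctness of the estimators under the
assumed error model, not robustness to real-instrument pathologies.

## Problem sizes and numerics

Monte-Carlo checks use 200 simulated calibration curves (slope recovery),
10,000 replicates per spiking set (ME/RE recovery), 10,000 CQI replicates
(precision), and 500–1,000 refits for the screening sampling-law and
coverage checks — sizes at which the Monte-Carlo error is several times
smaller than the tolerances being asserted, while the whole suite runs in
seconds. Level coding uses exact arithmetic on integers ±1/0 for design
matrices; comparisons against coded levels tolerate 1e−6 of the level
span. Strict inequality is used at the dummy-band boundary (a coefficient
exactly equal to the band is not significant) and inclusive inequality at
the LOQ (a concentration exactly at the LOQ is quantified).

## Known limitations

- Main effects only: no interactions, foldover or response-surface
  follow-up designs.
- The dummy-band significance rule with two dummies has low specificity
  (see above); it is kept as the default because it is the field's
  screening convention, with the t-test as the conservative alternative.
- Censored reporting does not propagate calibration uncertainty into the
  concentration estimates.
- The generator's noise models are stationary and independent across runs
  and levels.
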