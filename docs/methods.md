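# Methods

## Measurement model

A grazer in a closed, mixed tube of volume *V* (mL) removes algal biomass
in proportion to its clearance rate *f* (mL hr⁻¹ ind⁻¹). With in vivo
chlorophyll-*a* fluorescence *F* linear in biomass density (*F = lW*),

    dF/dt = −(f/V) F,    F(t) = F(0) e^(−f t / V),
    f = (V/t) ln(F(0)/F(t)).

Assumptions: first-order (non-saturating) clearance over the assay, no
algal growth or settling during incubation (dark, inverted tubes), and
fluorescence proportional to edible biomass with a stable
chlorophyll-to-carbon ratio. The model reads a single endpoint per tube;
functional-response saturation and time-series designs are out of scope.

**F(0) operationalization.** F(0) is taken from consumer-free control
tubes *read on the same plate as the samples*. Reading the controls
alongside the samples (rather than at assay start) makes common-mode
drift — detector gain, temperature, plate position of the read — cancel
in the ratio. The well table supports either convention; what matters is
that control and sample wells share a plate, never that controls are
pooled across plates.

**Technical replicates** are averaged on the fluorescence scale before
the log-ratio (the sample's mean fluorescence is the modelled quantity),
not estimated per well and averaged afterwards. The replicate CV is
reported, and flagged above a threshold (default 0.15) without excluding.

**QC.** Exclusions are: negative rate (sample brighter than its plate
controls — a technical error, excluded rather than truncated to zero),
death during the assay, and males (their feeding differs systematically
from females). Each exclusion is logged with sample id and reason; an
explicit override can retain everything while keeping the log. A high
replicate CV warns only.

## Key parameters

| parameter | default | units | why |
|---|---|---|---|
| `default_volume_mL` | 10 | mL | standard 15 mL-tube protocol volume |
| `default_hours` | 7 | h | standard assay duration; per-animal override in metadata |
| `output_units` | mL_per_hr | — | internal canon is mL hr⁻¹ ind⁻¹; L day⁻¹ (×24/1000) on request |
| `tech_rep_cv_warn` | 0.15 | fraction | replicate disagreement worth a look, not an exclusion |
| `bootstrap_B` | 2000 | resamples | percentile CI stability to ~±1 quantile position |
| `gain_range` | 112–120 | — | fluorometer gain window validated with a warning, not an error (ratios are gain-invariant) |
| `min_r2` (calibration) | 0.95 | — | linearity gate for the standard curve; configurable |

Blank (algae-free media) subtraction is supported but off by default; the
base protocol does not blank-correct, and the option exists for turbid or
stressor-bearing media.

## Bootstrap confidence intervals

Per-animal uncertainty comes from a **plate-pooled parametric bootstrap**.
The well-level noise is multiplicative, so a pooled CV is estimated from
every replicate group on the plate (the control wells plus each sample's
technical replicates, pooling within-group squared deviations scaled by
group means). Each of B resamples perturbs the control mean and the
sample mean with independent Gaussian multiplicative noise at that CV
scaled by 1/√n of each mean, recomputes the log-ratio, and the 2.5/97.5
percentiles form the interval.

The naive alternative — resampling the two technical-replicate wells with
replacement — is retained as `bootstrap_method="wells"` but is not the
default: with n = 2 the resampled mean takes only three values, the
percentile interval collapses to roughly the observed well range, and the
interval undercovers badly (~75% in simulation where the pooled scheme
achieves ~93–95%). Pooling borrows the noise scale, not the values, from
the rest of the plate; it assumes a common well CV across the plate,
which matches the simulator's generative model and is the natural
single-fluorometer assumption. Degenerate inputs (zero variance
everywhere) collapse the interval to the point estimate.

## Inference layer

Retained rates are modelled by OLS as `f ~ genotype * block` with
**sum-to-zero contrasts enforced** — Type III marginal tests are only
meaningful under such contrasts, and results are then invariant to factor
level order. Each term is reported as an F statistic with numerator and
residual df, and alongside it a Wald chi-square (F × df_num) with its own
p-value, since both styles circulate in the literature for this design;
the F test is the primary one. Residuals feed a Shapiro–Wilk check.

Averaging genotype effects over blocks is only honest when the
genotype×block interaction is negligible, so `drop_interaction()` refuses
when the interaction p-value is below 0.05 unless forced; single-block
data fall back to a genotype-only fit with a note.

Post hoc comparisons are **Tukey–Kramer on estimated marginal means**:
genotype means are predicted on a reference grid averaged over blocks,
their covariance propagated from the fit, and all G(G−1)/2 differences
get simultaneous intervals `diff ± q(0.95, G, df_resid)/√2 · SE(diff)`
from the studentized range, which remains valid under the unequal group
sizes QC leaves. The single-step multivariate-t generalization would
differ negligibly for designs of this size and is not implemented. A
compact letter display (insert-and-absorb on adjusted p-values)
summarizes the pattern.

## Exposure extension

With a fluorescent stressor in the medium, animal-free controls that
*contain the stressor* replace pure-algae controls, so background
fluorescence enters numerator and denominator alike. The background is
assumed additive and common to sample and control tubes; with blank
subtraction enabled the additive offset cancels exactly, without it a
known ratio distortion of order (offset/F0) remains. Clearance then
converts to exposure: rate *E = f·Z*, and cumulative dose either
`f·Z0·t` (constant concentration, e.g. replenished or non-depletable
particles) or `Z0·V·(1 − e^(−f t/V))` (particles cleared like the algae;
bounded by the `Z0·V` present). The depleting model is the default as it
shares the assay's own depletion assumption.

## Simulator

The generator mirrors the assay: per-genotype true rates, a common
starting fluorescence `F0_true` (default 10,000 RFU), exponential
depletion per sample, a lognormal multiplicative plate factor (sd 0.1 on
the log scale by default), and multiplicative Gaussian well noise
(CV 0.05 by default) — fluorometer noise scales with signal, and plate
effects are scale effects, which is precisely why the matched-pairs
design cancels them. Artifacts are injected per sample: death and male
flags at given rates, and spurious spikes (one replicate well multiplied
by 4) that guarantee a negative estimated rate, matching the attribution
of negative rates to technical error. Plates are packed per temporal
block, six control wells plus 45 samples × 2 replicates filling a 96-well
plate exactly; every plate carries its own controls.

Defaults mirror the motivating study design: 7 genotypes × 30 animals,
two temporal blocks, two technical replicates, 10 mL, 7 h. True rates
default to 0.55–1.30 mL hr⁻¹ ind⁻¹, the range typical of juvenile-adult
*Daphnia* grazing on chlorophytes. The well CV default is a plausible
placeholder — real plate readers should be calibrated by the user —
so passing recovery tests demonstrates correctness of the pipeline under
this noise model, not the noise level of any particular instrument. The
simulator does not emulate algal growth during the assay, edge effects on
plates, temperature/light covariates, or saturating functional responses;
conclusions about those require real data.

Monte-Carlo experiments (type-I error of the genotype test; family-wise
coverage of the Tukey intervals) run 1000 simulated assays at a reduced
per-assay size of 7 genotypes × 6 animals: the nominal error rates under
study do not depend on the per-assay n, and this keeps a thousand full
pipeline runs fast.

A caution on recovery diagnostics: per-genotype bias estimated from one
simulated assay is itself a Monte-Carlo quantity. With a 5% well CV, two
replicates and n = 30, a genotype-mean bias carries a sampling sd of
roughly `(V/t)·cv·(1/√2)/√30 ≈ 0.009` mL hr⁻¹ from replicate noise alone
(plus a control component shared across genotypes on the same plates) —
about 1.7% relative for a slow feeder at 0.55 mL hr⁻¹. Single-realization
recovery numbers at the few-percent level therefore measure simulation
noise, not estimator bias; the estimator is exactly unbiased, as the
noiseless-inversion test shows at 1e-10 relative error, and plate effects
cancel to machine precision.

## Numerical choices

- Closed-form rates are validated against an independent oracle that
  integrates the depletion ODE with classical RK4 (1500 steps) and
  inverts it for *f* by 70 bisection iterations; agreement is at the
  1e-12 level over wide parameter ranges.
- Through-origin standard curves report the uncentred R²; the inverse map
  `(F − intercept)/l` requires a positive slope.
- Unit conversion (mL hr⁻¹ ↔ L day⁻¹, factor 24/1000) is exact and
  applied once, at output.
- Studentized-range critical values are cached per (level, G, df);
  adjusted p-values can be skipped (`adjusted_p=False`) in interval-only
  Monte-Carlo loops where they dominate runtime.
- Bootstrap resamples with non-positive means (possible only at extreme
  CVs) are dropped from the percentile computation.
- All randomness (bootstrap, simulation, experiments) flows from explicit
  integer seeds through `numpy.random.default_rng`; identical seeds give
  byte-identical simulator output files.

## Known limitations

- Single-endpoint design: no within-assay time series, no saturation.
- The bootstrap's pooled-CV assumption shares noise information across a
  plate; a plate with genuinely heteroscedastic wells would need the
  (undercovering) `wells` method or more replicates.
- Fixed-effect blocks only; random-block or mixed models are not fitted.
- The additive-stressor-background assumption is a modelling choice; a
  stressor that quenches or amplifies the algal signal multiplicatively
  would bias rates and requires its own calibration.
- Calibration curves are diagnostic; rates never depend on them unless
  biomass units are requested, so calibration error does not propagate
  into *f*.
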