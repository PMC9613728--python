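# Methods

## Pipeline overview

A testing session is a 3-min seated baseline, a 6-min warm-up, seven 4-min
submaximal stages at fixed power, a 6-min passive rest, and a 180-s all-out
time trial (TT). Inputs are second-by-second ergometer power and native
10-s mixing-chamber ergospirometry (VO2, VCO2, VE, optionally HR). Time is
seconds from session start with half-open windows `[start, end)`; all
internal power/metabolic quantities are absolute watts, converted to W·kg⁻¹
or J·kg⁻¹ only at the reporting layer to avoid double normalization.

## Respiratory processing

Submaximal stage values are averages of the raw 10-s samples over the final
minute of each stage (6 samples); no smoothing is applied there, because
steady-state averages gain nothing from it. The TT segment is expanded to a
1-s grid by piecewise-constant interpolation of each 10-s value and
smoothed with a 9-s counterbalanced moving average (± 4 s) applied twice,
to obtain a dynamic per-second aerobic response. At the TT segment edges
the half-width shrinks symmetrically to the distance from the edge
(window 1, 3, 5, 7, 9 samples over the first five seconds, mirrored at the
end), so the first and last seconds are unsmoothed; the second pass
re-applies the identical operator. The TT segment is smoothed independently
of the preceding rest — a single edge rule covers both the start and the
end of the trial. A config flag (`smooth_submaximal`) extends smoothing to
the stages for sensitivity checks.

Peaks during the TT: VO2peak is the highest 20-s moving average of the
smoothed series, with peak RER taken over the same window (computed as the
window mean of the smoothed VCO2/VO2 ratio series; the ratio-of-window-means
alternative is a config flag — the difference is second order); peak power
and cadence are highest 5-s moving averages of the 1-s data; peak heart
rate is the highest native 10-s value. Moving-window ties break to the
earliest window for determinism.

## Energetics

The Weir conversion uses the energy constant 4184 J·kcal⁻¹ exactly.
Submaximal MR uses the measured final-minute RER capped at 1.00 (raw RER
is retained for reporting); the baseline MR uses the uncapped resting RER
(resting RER > 1 does not occur in practice, so no cap policy is needed).
TT aerobic MR fixes RER at 1.00 (pure carbohydrate utilization during
supramaximal work). Measured RER inputs outside [0.6, 1.3] are rejected as
sensor errors.

## Models and integration

The PO–MR regressions are ordinary least squares; the standard error of the
estimate uses an n−2 denominator; delta efficiency is the reciprocal slope.
Extrapolation of the regression far above the fitted range is the intended
supramaximal use, so no warning is emitted. The GE_LAST model is the
equivalent zero-intercept line with slope 1/GE_LAST.

Integration is the rectangular rule on the 1-s grid — the data are defined
second-by-second, so sub-second interpolation would add nothing. Negative
instantaneous MR_AN/PO_AN values are retained by default (late in an
all-out TT the anaerobic contribution hovers near zero and small signed
fluctuations are real features of the decomposition); `clamp_negative_mr_an`
turns on clamping. W′ is the signed integral of PO − CP over the full
180 s, which makes W′ = (mean PO − CP)·180 exact; because CP is the mean of
the final 30 s of the same series, the signed and clamped variants
(`clamp_below_cp`) coincide whenever PO ≥ CP throughout the decay. The
average TT gross efficiency is the unweighted time mean of the
instantaneous GE (a ratio-of-integrals alternative sits behind
`ge_tt_avg_ratio_of_integrals`).

A session that recorded only the TT still yields the CP model; the
regression and GE models are reported as per-model errors rather than
aborting the run.

## Synthetic athletes

The generator produces data with exactly the structure the models assume,
plus controlled measurement noise, so every estimator can be validated
against known truth:

* **Submaximal truth.** A linear PO–MR law (default slope 4.15 W/W,
  intercept 1.9 W·kg⁻¹) with seven stages at 1.62–3.47 W·kg⁻¹ and stage RER
  0.86–0.91, matching a highly trained ~78.5-kg cyclist with VO2peak
  64 ml·kg⁻¹·min⁻¹. Stage VO2 is the exact Weir inverse of the true line at
  the stage RER, generated at steady state (no onset kinetics within
  stages): the regression estimators are exactly identifiable at zero
  noise, which is what the recovery tests exploit. The default baseline VO2
  is chosen so the resting point lies exactly on the true line (when the
  true intercept is non-positive, a typical seated-rest VO2 of 0.30 L·min⁻¹
  is used instead, since an on-line baseline is then impossible).
* **TT truth.** Power decays exponentially from 9.3 to 4.5 W·kg⁻¹ with a
  35-s time constant (mean PO ≈ 5.4 W·kg⁻¹, the observed all-out profile).
  Aerobic MR follows first-order kinetics (τ = 25 s, the typical fast
  component of VO2 kinetics in trained cyclists) toward the required MR
  capped at the peak aerobic MR, stepped exactly per second for the
  piecewise-constant target. The truth record defines AnWC/AnC through the
  regression-model equations with the true GE(t) = PO/(slope·PO+intercept);
  ground truth is model-relative by construction and labelled as such.
* **Noise.** 10-s VO2 samples carry multiplicative log-normal noise with
  unit mean (default CV 2%, a typical gas-analyzer error); VCO2 scales with
  the same factor, so RER is noiseless. Breath outputs are 10-s box
  averages of the true 1-s series, so block-averaging and re-expansion are
  mutually inverse.
* **Cohorts.** Athlete parameters are drawn from truncated normal
  distributions whose means and SDs follow the cohort spread of highly
  trained male cyclists (slope 4.15 ± 0.28, intercept 1.9 ± 0.5 W·kg⁻¹,
  VO2peak 64 ± 6 ml·kg⁻¹·min⁻¹, TT peak 9.3 ± 1.2, end power 4.5 ± 0.23
  W·kg⁻¹), with the peak forced at least 1 W·kg⁻¹ above the end power.

What the generator deliberately omits: the VO2 slow component (a flagless
mono-exponential is the default; real supramaximal GE likely declines with
fatigue, which none of the four models capture either), breath-by-breath
variability and ectopic-breath artifacts, cadence–efficiency interactions,
and any lactate kinetics. Passing recovery tests therefore demonstrates
estimator correctness under the models' own assumptions, not validity of
those assumptions in real athletes. Because the aerobic kinetics here are a
clean fast mono-exponential, the simulated fractional utilization of
VO2peak (~87%) runs above typical field values (~80%); the between-model
AnWC ordering and agreement structure are unaffected.

## Agreement statistics

Typical error is SD(differences)/√2; its percentage form divides by the
grand mean of all values from both models in the pair. Hedges' g_av is
Cohen's d_av (mean difference over the average of the two SDs) multiplied
by the small-sample factor 1 − 3/(4·df − 1) with df = n − 1; the exact
gamma-function correction is available via `exact=True`. The RM-ANOVA
reports Greenhouse–Geisser ε from the double-centred covariance matrix and
corrects the degrees of freedom only when ε ≤ 0.75 (with ε > 0.75 sphericity
is treated as tolerable and uncorrected df are used; Huynh–Feldt is not
implemented), Mauchly's W with the chi-square approximation, η² =
SS_condition/SS_total, SEM = √MS_error, and Bonferroni-multiplied pairwise
paired t-tests. These implementations are cross-checked in the test suite
against pingouin to 1e-8.

## Problem sizes and tolerances

Tests run on 15-athlete cohorts (the standard cohort size for this
protocol) and check: exact identities at 1e-9 relative; numerical-oracle
equivalence (smoother, moving peaks, agreement formulas, RM-ANOVA) at
1e-8; noise-free regression recovery at 1e-9 relative and noise-free AnWC
within 1% of truth (the residual comes from the 10-s sampling, expansion
and smoothing of the aerobic signal, not from integration); median AnWC
error under 2% VO2 noise below 5% across 100 seeds; and the cohort-mean
AnWC ordering GE_LAST > 7±Y_LIN > W′ in ≥ 95% of 200 seeded cohorts. The
acceptance script uses 50 cohorts for the ordering fraction to stay fast;
the test suite uses 200.
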