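# anwc

Estimation of **anaerobic work capacity (AnWC)** and **anaerobic capacity
(AnC)** from cycle-ergometry exercise, for exercise physiologists and sport
scientists who test athletes with a submaximal stage protocol followed by a
3-min all-out time trial (TT).

There is no gold-standard measure of the anaerobic energy contribution to
whole-body exercise, and the common computational models disagree. This
package implements four of them on a shared data pipeline so that their
estimates — and their disagreement — can be computed, compared, and studied
on synthetic data with known ground truth.

## The models

Metabolic rate comes from indirect calorimetry via the Weir equation,

```
MR [W] = 4184 · V̇O2 [L·min⁻¹] · (1.1·RER + 3.9) / 60
```

with gross efficiency GE = PO/MR (PO = external power output). For the TT,
aerobic MR (MR_AE) uses a fixed RER of 1.00 (pure carbohydrate oxidation).

1. **7+Y_LIN** — OLS regression of MR on PO over seven 4-min submaximal
   stages *plus* the seated resting baseline as the Y-intercept point
   (PO = 0). The regression is extrapolated to predict the required MR at
   each TT second.
2. **7-Y_LIN** — the same regression without the baseline point.
3. **GE_LAST** — the gross efficiency of the last (highest) submaximal
   stage assumed constant during the TT: MR_req(t) = PO(t)/GE_LAST.
4. **CP_3'AO** — critical power as the mean PO of the final 30 s of the
   3-min all-out TT; W′ = ∫(PO − CP) dt stands in for AnWC.

For models 1–3 the per-second anaerobic MR is `MR_AN = MR_req − MR_AE`, and
the anaerobically attributable power is `PO_AN = PO − MR_AE·GE_inst`, where
GE_inst is the model's instantaneous gross efficiency. Integrating over the
180-s TT gives AnC (kJ·kg⁻¹) and AnWC (J·kg⁻¹). With a constant GE the
identity `AnWC = GE_LAST · AnC` is exact.

Agreement between models is quantified with Bland–Altman limits of
agreement, typical error (SD of paired differences / √2, absolute and as %
of the grand mean), Hedges' g_av, and a one-way repeated-measures ANOVA
with Greenhouse–Geisser correction (ε ≤ 0.75), η², Bonferroni-adjusted
pairwise tests, and SEM = √MS_error.

## Worked example

```python
import anwc
from anwc import synthetic_athlete as sa

session, truth = sa.simulate_full_session(sa.SyntheticAthleteParams(), seed=42)
res = anwc.run_pipeline(session)
mass = session.protocol.body_mass

reg = res.regressions["7+Y_LIN"]
print(f"7+Y_LIN: MR = {reg.slope:.2f}*PO + {reg.intercept/mass:.2f} W/kg  (r2={reg.r2:.4f})")
for m, d in res.decompositions.items():
    extra = f"  CP={d.cp/mass:.2f} W/kg" if d.cp else f"  AnC={d.anc/mass/1000:.2f} kJ/kg"
    print(f"{m:8s} AnWC = {d.anwc/mass:6.1f} J/kg{extra}")
print(f"truth   AnWC = {truth.anwc_true/mass:6.1f} J/kg")
```

prints

```
7+Y_LIN: MR = 4.15*PO + 1.89 W/kg  (r2=0.9998)
7+Y_LIN  AnWC =  213.8 J/kg  AnC=0.94 kJ/kg
7-Y_LIN  AnWC =  214.4 J/kg  AnC=0.95 kJ/kg
GE_LAST  AnWC =  245.0 J/kg  AnC=1.15 kJ/kg
CP_3AO   AnWC =  161.3 J/kg  CP=4.55 W/kg
truth   AnWC =  218.1 J/kg
```

The 2% VO2 measurement noise moves the regression-model estimates a few
J·kg⁻¹ off the generator truth (218.1 J·kg⁻¹). The characteristic pattern
is visible: the constant-GE model (GE_LAST) gives the highest AnWC because
the positive regression intercept implies GE rises with PO, while W′ from
the 3-min all-out CP model is far lower, because the end-test CP sits near
96% of the peak aerobic MR — well above the TT's ~80% fractional
utilization of VO2peak.

## Command line

```bash
anwc simulate --seed 1 --n 15 --out data/          # synthetic cohort CSVs
anwc fit --power data/ath01/power.csv --breath data/ath01/breath.csv \
         --protocol data/ath01/protocol.yaml --out results/ath01/
anwc compare results/ath*/ --quantity anwc --out stats/
```

`fit` writes a tidy long table (`athlete, model, quantity, value, units`)
plus `summary.json` per athlete; `compare` writes the pairwise agreement
table and the RM-ANOVA summary.

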