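# plaquefatigue

Coronary plaques live under pulsatile load: every cardiac cycle the luminal
pressure swings between diastole and systole and the vessel wall works
through a stress/strain cycle.  The amplitude of that cycle — *plaque
fatigue* — is a candidate driver of stenosis progression (the gradual loss
of lumen area between a baseline and a follow-up imaging study).
`plaquefatigue` is a tested, end-to-end pipeline for studying that link on
IVUS-style vessel cross-sections:

1. **Thin-slice mechanics.**  Each cross-section (lumen and
   external-elastic-membrane contours, with optional lipid/calcification
   inclusions) is meshed and inflated by a finite-strain FE solver under
   generalized plane strain (prescribed axial stretch λ_z = 1/0.95,
   i.e. 5% axial shrinkage).  Tissue follows a modified Mooney–Rivlin law

       W = c1 (I1 − 3) + c2 (I2 − 3) + D1 [exp(D2 (I1 − 3)) − 1]
         (+ (K1/K2) [exp(K2 (I4 − 1)²) − 1]  for the anisotropic wall)

   with literature parameters per tissue class and a near-incompressibility
   penalty.  Because VH-IVUS frames are R-wave gated, the imaged shape is
   matched at *minimum* pressure via a circumferential-shrinkage fixed
   point (inflate-after-shrink recovers the imaged lumen area).

2. **Fatigue and morphology factors.**  From the solutions at diastolic and
   systolic pressure, 19 baseline factors per slice: max/average luminal
   principal stress and strain at both pressures, their four cardiac-cycle
   amplitudes, plaque burden PB = (wall area / EEM area)·100%, lumen/wall
   areas at both pressures and their amplitudes.  The outcome is
   DLA = lumen area(baseline) − lumen area(follow-up); label 1 ⇔ DLA > 0.

3. **Statistics.**  Slices cluster within patients, so each factor is
   screened against DLA with a random-intercept mixed model
   y_ij = β0 + β1 x_ij + b_j + ε_ij and the dependence-adjusted
   correlation r = β̂1·√(var x / var y).

4. **Prediction.**  A random forest classifies narrowing vs non-narrowing,
   with Mtry/Ntree tuned purely on out-of-bag (OOB) error,
   mean-decrease-Gini importances, and varSelRF-style backward elimination
   (`ProgressionForestClassifier`, a scikit-learn estimator).

Because patient IVUS pullbacks of this kind are not publicly deposited, the
package ships a first-class **synthetic cohort generator** that reproduces
the study's structure (7 patients, 305 paired slices, eccentric walls,
patient random effects, and a generative link in which DLA rises with
stress amplitude and falls with plaque burden), so every stage is testable.

## Worked example

```python
from plaquefatigue import CohortConfig, generate_cohort, cohort_feature_table
from plaquefatigue import correlation_screen, ProgressionForestClassifier
from plaquefatigue.features import FACTOR_COLUMNS

cohort = generate_cohort(CohortConfig(seed=1))          # 305 slice pairs
table = cohort_feature_table(cohort.pairs, mode="surrogate")
screen = correlation_screen(table).set_index("factor")
print(f"avg stress amplitude: r = {screen.loc['avg_stress_amplitude','r']:+.3f}")
print(f"plaque burden:        r = {screen.loc['pb_at_pmin','r']:+.3f}")

clf = ProgressionForestClassifier(mtry=4, ntree=500, seed=1)
clf.fit(table[FACTOR_COLUMNS], table["label"].to_numpy())
print(f"OOB accuracy: {100 - clf.oob_error_:.1f}%")
```

prints

```
avg stress amplitude: r = +1.000
plaque burden:        r = -0.869
OOB accuracy: 90.8%
```

i.e. on the synthetic cohort the screen recovers the generative directions
(fatigue correlates positively with narrowing, plaque burden negatively;
the clipped r = 1.000 marks a within-patient slope larger than the total
variance ratio) and the forest predicts the narrowing label well above
chance.  `mode="fe"` runs the same table through the finite-element path
(minutes instead of seconds); the closed-form Laplace surrogate is the
default for fast exploration and CI.

A command-line interface mirrors the stages:

```bash
plaquefatigue generate --out run/contours --seed 1
plaquefatigue features --contours run/contours --out run/features.csv --surrogate
plaquefatigue correlate --table run/features.csv --out run/correlations.csv
plaquefatigue train --table run/features.csv --out run/model_report.json
plaquefatigue metrics --confusion 138,22,28,117
plaquefatigue run-all --out run/ --seed 1 --surrogate
```

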