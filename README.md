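# dexin — finger individuation from multi-channel fingertip forces

`dexin` quantifies how well individual fingers can be moved in isolation.
When a person presses one finger isometrically, force leaks into the
uninstructed fingers of the same hand (**enslaving**) and, more subtly,
into the opposite hand (**mirroring**).  Both are sensitive probes of fine
motor control: they shrink with training and grow with damage to the motor
system, and they are of particular interest in focal hand dystonias such as
musician's dystonia, where they behave as candidate severity biomarkers.

The package is aimed at motor-control and movement-disorder researchers
working with multi-channel isometric force data: 10 fingertip channels
sampled at 200 Hz while a cued finger matches force targets at 25/50/75% of
its maximum voluntary contraction (MVC).

## The model

For each ordered pair (instructed finger *i*, uninstructed finger *j*) the
per-trial peak forces are related by a regression line through the origin,

&nbsp;&nbsp;&nbsp;&nbsp;*y* = *β*<sub>ij</sub> *x*,&nbsp;&nbsp;&nbsp;
*x* = peak force on *i*, *y* = peak force on *j*,

with *β*<sub>ij</sub> (N per N) estimated by iteratively reweighted least
squares with Tukey bisquare weights (c = 4.685, MAD scale), so single
aberrant trials are downweighted.  Log-slopes log *β*<sub>ij</sub> form a
5 × 5 **enslaving pattern** per hand (20 off-diagonal cells) and a 5 × 5
**mirroring pattern** per direction (25 cells).  On top of the patterns the
package computes:

* overall coupling per subject: mean log-slope, back-transformed to a
  geometric-mean slope in N/N;
* split-half reliability (odd vs even blocks, Fisher-Z pooled with 95% CI);
* cross-validated pattern similarity between groups (leave-one-out control
  averages; pooled-variance t on Fisher-Z similarities) — separates pattern
  *shape* from coupling *magnitude*;
* clinical contrasts: group t-tests on mean log-slopes, a one-way ANOVA
  over symptomatic/asymptomatic finger-pair categories (eta², Tukey–Kramer
  post-hoc), and paired tests for symptom-dependent mirroring including a
  mirror-dystonia probe.

Because no public cohort exists for this design, `dexin` ships a calibrated
generative simulator (`dexin.simulate`) with known ground-truth coupling
matrices, so the entire pipeline is testable by parameter recovery; see
`docs/methods.md` for the generative model and its calibration.

## Worked example

```python
from dexin import CohortConfig, FingerIndividuation

model = FingerIndividuation.from_simulation(
    CohortConfig(n_patients=4, n_controls=4, blocks=4, seed=2025))
results = model.fit()
print(results.summary())
```

prints (excerpt):

```
enslaving (instructed hand R)
----------------------------------------------------------------
  geometric-mean slope   patient: 0.0539 N/N, control: 0.0346 N/N
  patients vs controls   t(6) = 1.44, p = 0.199
  pattern similarity     patient r = 0.898, t(6) = -0.02, p = 0.986
  split-half r (patient)  0.924 [0.908, 0.938]
  split-half r (control)  0.938 [0.895, 0.963]
```

Reading this: during right-hand presses each newton of instructed force
produced about 0.054 N (patients) vs 0.035 N (controls) of involuntary
force in the other fingers of that hand (geometric means across the 20
finger pairs); the group difference at these small sample sizes has
t(6) = 1.44.  Patterns are highly reliable within subjects (split-half
r ≈ 0.93) and patients' pattern *shape* is as close to the control-average
pattern as the controls' own (similarity p = 0.99): the simulated disorder
scales coupling up without reorganising it, which is exactly the
dissociation the similarity analysis is designed to detect.

The same pipeline runs from the shell:

```bash
dexin simulate --config config.yaml --seed 9 --out cohort/
dexin analyze --manifest cohort/subjects.json --out results/
dexin report --results results/
```

`analyze` accepts any cohort in the documented on-disk format (a
`subjects.json` manifest plus one tidy trace CSV per subject), so recorded
data can be analysed identically to simulated data.

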