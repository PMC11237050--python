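# Methods

## The quantities being estimated

During an isometric single-finger press, force leaks into fingers that were
not instructed to move: *enslaving* within the instructed hand and
*mirroring* on the contralateral, passive hand.  Both grow approximately
linearly with the force of the instructed finger, so each
(instructed, uninstructed) finger pair is summarised by the slope of a
regression line through the origin between the two fingers' per-trial peak
forces — newtons of involuntary force per newton of instructed force.  The
origin constraint encodes the physical boundary condition that a press of
zero force produces zero overflow.

Slopes are estimated by iteratively reweighted least squares with Tukey
bisquare weights (tuning constant c = 4.685, scale = median absolute
residual / 0.6745, re-estimated each iteration), starting from the
ordinary-least-squares origin slope.  When the residual MAD is zero (an
exact fit, e.g. noise-free simulation) the OLS slope is returned directly.
The iteration runs to a step tolerance of 1e-11 with a generous iteration
cap: the bisquare fixed point can contract slowly when an outlier sits near
the weight cutoff, and a looser step tolerance (e.g. 1e-8) can leave the
slope several orders of magnitude further from the fixed point than the
final step size, which would spoil agreement with an independent solver.

Slopes are natural-log transformed before any averaging or parametric
testing, with non-positive slopes floored at 1e-4 N/N (far below any
physiological coupling; keeps cells finite when an uninstructed finger only
ever relaxed).  A hand's 20 off-diagonal pairs form the *enslaving
pattern*; the 25 active-to-passive pairs form the *mirroring pattern*.  The
overall coupling strength of a pattern is the arithmetic mean of its valid
log-slope cells; the back-transform of that mean (a geometric mean, in
N/N) is reported for readability.  The three target levels (25/50/75% MVC)
are pooled into a single regression per pair.

## Preprocessing

The resting baseline per channel — the mean over the final 200 ms before
the go-cue — is subtracted from the whole trace.  The per-channel peak is
the maximum *signed* force over the response window (go-cue to trial end);
extension dips below baseline are treated as near-zero coupling and handled
by the log floor.  Trials whose instructed peak missed the ±25% target zone
are flagged but never excluded.

## Reliability, similarity, clinical contrasts

*Split-half reliability*: patterns are estimated separately from
odd-numbered and even-numbered blocks (1-based block index) and their valid
cells correlated (Pearson).  Group summaries average per-subject
correlations on the Fisher-Z scale; the 95% CI is the Z-mean ± 1.96
standard errors of Z across subjects, back-transformed.  Correlations are
clamped to ±(1 − 1e-6) before atanh.

*Cross-validated pattern similarity*: each patient's pattern is correlated
with the control-average pattern; each control is correlated with the
average of the *other* controls, so no pattern enters its own reference
(leave-one-out removes the otherwise guaranteed positive bias).  Fisher-Z
similarities are compared between groups with a pooled-variance two-sample
t-test.  Because Pearson correlation is invariant to additive offsets of
log-slopes, a group that differs only in overall coupling *magnitude* is
indistinguishable in this test — the similarity analysis isolates pattern
*shape* from gain.

*Clinical contrasts*: group differences in mean log-slope use the
pooled-variance two-sample t (df = n1 + n2 − 2).  Within patients,
enslaving cells are classified by the symptom status of the
(instructed, uninstructed) pair — sym-sym / sym-asy / asy-sym / asy-asy —
and per-patient category means enter a one-way ANOVA with eta-squared
(SS_between / SS_total) as effect size and Tukey–Kramer post-hoc tests
(which accommodate unequal category sizes; a Levene homogeneity p is logged
for transparency).  The category mean, not the raw cell, is the unit of
analysis: with 11 patients of whom 6 have two or more affected right-hand
digits this yields 11+11+11+6 = 39 observations and error df 35, matching
the reference design.  Mirroring contrasts split per-patient mean
mirroring by the symptom status of the instructed finger (symptomatic hand
active) or of the passive finger (asymptomatic hand active — a behavioural
probe for mirror dystonia), tested with paired t-tests; patients whose
relevant hand is all- or none-symptomatic are excluded with a warning.

Degenerate inputs are resolved deterministically: identical groups give
t = 0, p = 1 (rather than 0/0); constant patterns are excluded from
correlation analyses with a warning; empty ANOVA categories are dropped
with the dfs adjusted.

## The synthetic cohort

No public dataset exists for this design, so a calibrated simulator stands
in for it, and every estimator is validated by parameter recovery against
the simulator's ground truth.

Study design (defaults): 11 patients and 7 analysable controls; 10 blocks
of 30 trials, each block containing every (hand × finger × level)
combination exactly once in pseudo-random order; 200 Hz sampling; trials
consist of a 2–3 s preparation (uniformly drawn — the protocol states only
a range), a 0.3 s half-cosine ramp, a 2–3 s hold and a 0.5 s release; MVC
per finger ~ N(20, 2) N truncated to [14, 24] N so 75% targets stay inside
the 0–25 N transducer range.  Patient symptom maps are drawn from the
reference clinical table (`dexin.datasets`), which always affects at least
one right-hand digit and includes a left-hand digit in 2 of 11 rows.

Ground-truth coupling: off-diagonal enslaving cells are log-normal around
the group geometric mean (controls 0.028 N/N; patients ×1.643 ≈ 0.046 N/N)
multiplied by a distance-decay structure (ratio 0.6 per unit of anatomical
finger distance, normalised so the pattern's geometric mean is unchanged);
mirroring cells likewise around 0.006 / 0.009 N/N with homologous fingers
(distance 0) coupling most.  A per-subject log-normal factor
(sd 0.3 in log units) sets the between-subject spread — sized so that the
patient-control contrast lands at the t ≈ 3 scale observed for cohorts of
this size — and cell-level log-normal jitter (sd 0.2) individuates
patterns.  Finger pairs in which both digits are clinically symptomatic
receive an extra gain of 1.5, a modest exaggeration consistent with the
reported sym-sym effect.

Trial generation: the instructed channel follows the ramp-hold-release
profile scaled to `level × MVC × (1 + ε)` with matching error
ε ~ N(0, 0.12) (≈ ±2 σ spans the ±25% target zone).  Uninstructed channels
follow `gain × f_instructed(t)` where the gain is the ground-truth cell
jittered per trial by a multiplicative 1 + N(0, 0.3) term — trial-to-trial
variability of motor overflow, the dominant noise source for slope
estimation.  Each channel adds slow drift (independent Gaussian knots 1 s
apart, linearly interpolated) with marginal sd `0.02·|f| + 0.005` N, plus a
constant per-trial baseline offset ~ N(0, 0.1) N; samples are clipped to
[−1, 25] N.

Two modelling choices deserve comment.  First, coupling acts on the
instantaneous instructed trace (including its own fluctuations), not just
on the peak, so peak-based estimation is consistent: instructed-side
variability cancels in the slope.  Second, within-trace noise is *slow*
rather than white: peak extraction takes a maximum over ~900 response
samples, and white noise of any useful amplitude would systematically
inflate small enslaved/mirrored peaks (the expected maximum of hundreds of
independent draws), biasing slopes upward.  With ~1 s drift the response
window contains only a handful of effective draws and the residual
inflation is small (≈ +1% on enslaving geometric means, ≈ +8% on the much
smaller mirroring slopes).  The trial-level coupling jitter carries the
calibrated share of slope noise and is unbiased by construction.

Calibration: with these defaults a control subject's expected split-half
enslaving reliability is ≈ 0.97 (inside the 0.85–0.99 band that brackets
the reference value 0.945) and cell-wise slope recovery has median
|relative error| ≈ 5% (enslaving) and ≈ 8% (mirroring) over a 10-block
session.

What the simulator does **not** emulate — and hence what passing recovery
tests do not establish about real recordings: nonlinear coupling at high
forces, fatigue or learning across blocks, heteroscedastic matching error
across levels, serially correlated behaviour between trials, hand-dominance
asymmetries, and any biomechanical (tendon) coupling structure beyond the
distance decay.  Recovery results certify the estimators under the stated
generative model, not the model itself.

## Problem sizes and determinism

The test-suite and the acceptance script use a full-design cohort
(18 subjects × 300 trials) for recovery/reliability checks, a 2-block
cohort for noiseless identifiability, 500 random problems for
robust-regression oracle agreement, and 200 pattern-level replicate
cohorts for the similarity-dissociation property.  All randomness flows
through `numpy.random.Generator` streams spawned per subject from a master
`SeedSequence`, so any subject's data is reproducible independently of
cohort composition.

## Known limitations

* The robust-regression scale estimator (MAD about zero) and tuning
  constant follow the common default; other conventions (MAD about the
  residual median, Huber weights) would shift slopes slightly.
* Whether reported group coupling levels are arithmetic or geometric means
  is convention-dependent; this package reports geometric means (the
  back-transform of averaged log-slopes) and exposes cell-level tables for
  any alternative summary.
* Reliability CIs are computed across subjects (Fisher-Z); a bootstrap
  over blocks would be an alternative.
* With fewer than 3 usable trials for a pair the cell is invalid rather
  than imputed; downstream correlations use pairwise-complete cells.
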