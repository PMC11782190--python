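# Methods

This note documents the models, estimators and numerical choices behind
`orthomorph`, what the synthetic-cohort generator does and does not emulate,
and the limitations a user should know before applying the pipeline to real
recordings.

## Signal model and windows

A recording is a per-heartbeat series of systolic/diastolic pressure and
inter-beat (RR) intervals with the stand onset anchored at *t* = 0 (negative
times supine). All analysis windows are half-open `[a, b)` and the uniform
grid sits on integer seconds, so window membership is unambiguous. Beat
values are linearly interpolated onto the grid; no smoothing is applied at
this stage and no extrapolation beyond the first/last beat is permitted.
Linear interpolation is exact on piecewise-linear signals and idempotent on
already-uniform series — both are asserted by property tests.

The supine baseline is the mean grid SBP over [−60, −30) s before standing,
a window chosen to avoid both motion noise at the transition and
anticipatory pressure rises. Resting indices come from the same window:
PP = SBP − DBP, MAP = (SBP + 2·DBP)/3, HR = 60/mean(RR). The RR 30:15 ratio
is operationalized as the RR interval of the beat nearest 30 s divided by
that of the beat nearest 15 s; the metric's name is standard but its
estimator is not, so the nearest-beat choice is an explicit convention here.

### Quality screen (stand-in rules)

Production devices ship proprietary signal-quality frameworks whose criteria
are not public. The screen implemented here is therefore a deliberately
simple, documented stand-in with three signal rules and two coverage rules,
all thresholds configurable (`QualityConfig`):

* **flatline** — SBP standard deviation below 0.1 mmHg over any ≥ 10-s span
  (a physiological signal always varies beat to beat);
* **spike** — a single beat jumping > 40 mmHg relative to *both* neighbours
  and reverting on the next beat (photoplethysmography artefact);
* **calibration_step** — a > 40 mmHg jump that *persists* (cuff
  recalibration);
* **gap** — > 3 s without a beat;
* **short_phase** — under 60 s of supine or 120 s of standing data.

A recording passes iff no rule fires. These rules are not a validated
replacement for device-specific screening; on real data they should be
tuned against manual review.

## Feature definitions

Three Δ% features summarize the standing response, each relative to
baseline, drops negative:

* **early phase** — the nadir of trailing 2-s means (grid pairs ending at
  each integer second in (0, 15]); captures the transient dip of initial
  orthostatic hypotension. Ties resolve to the earliest window.
* **stabilization point** — the 5-s mean over [38, 43), centred on 40 s;
  a marker of delayed early stabilization. Window widths are stated by the
  field's convention; their *alignment* (trailing vs centred) is not, so
  both are configurable with these defaults.
* **late phase** — the minimum 10-s rolling mean over windows [s, s+10)
  with s = 60…110, fully inside [60, 120]; aligns with sustained-deficit
  (classic orthostatic hypotension) criteria. Earliest window wins ties.

The ΔmmHg twins are `baseline · Δ%/100` by construction. Features are
deterministic functions of the recording; Δ% features are invariant to
rescaling the whole pressure signal, ΔmmHg features scale linearly (both
property-tested).

## Clustering

k-means++ is implemented in full: D² seeding (first centre uniform, each
subsequent centre sampled with probability proportional to squared distance
to the nearest chosen centre), Lloyd iterations to a centroid-shift
tolerance, best of `n_init` restarts by inertia. Defaults: `n_init=10`,
`max_iter=300`, `tol=1e-6`, seed 0 — none of these are dictated by the
problem; they are ordinary safe choices. Empty clusters are reseeded to the
point farthest from its centroid. Inertia monotonicity across Lloyd
iterations is asserted on every fit. Exhaustive-partition oracles (n ≤ 8,
k ≤ 3) confirm the restarted fit attains the global inertia optimum on
small instances.

The three features are clustered **unstandardized**: all axes are
commensurate Δ%-of-baseline units, so z-scoring would distort the geometry
(it is available behind a flag for sensitivity analyses). Morphology names
attach by ranking centroids on the stabilization-point axis — highest →
OHYPER, lowest → OHYPO, middle → iOHYPO; exact ties raise rather than guess.

Quality metrics: per-cluster mean (d_c) and maximum (diameter) Euclidean
distance to the centroid, per-axis mean absolute deviation, pairwise
centroid distances, mean silhouette ((b−a)/max(a,b); singleton or fully
degenerate points contribute 0), and bootstrap Jaccard stability: refit on
each resample, match every reference cluster to its best-overlapping
bootstrap cluster on the shared unique points (greedy per reference
cluster), average over clusters and resamples. Degenerate resamples with
fewer distinct points than k are redrawn. B = 100 by default.

## NOR reassignment

The normal-orthostatic-response rule: |early| ≤ 20 and |stab| ≤ 10 and
|late| ≤ 10, all in Δ% units with inclusive bounds — geometrically the
axis-aligned box [−20, 20] × [−10, 10] × [−10, 10]. "Within X %" is read
against the Δ%-from-baseline features, which are already percent-of-
baseline. The wider early bound accommodates the higher variability of the
first 15 s of standing. The rule is applied to members of *all* clusters;
reassignment is idempotent and reduction percentages are reported to 1 dp.

## Frailty analysis

Dichotomization thresholds (all configurable in `AnalysisConfig`): weight
loss ≥ 4.5 kg/year, TUG > 13.5 s, MoCA < 26, gait speed ≤ 0.6 m/s,
functional reach < 15 cm, ADL ≤ 5, hsCRP > 3 mg/L, supine SBP > 140 mmHg,
polypharmacy ≥ 5. Weekly MET expenditure is 3.3·walking + 4.0·moderate +
8.0·vigorous (min/day × days/week each). Grip strength, MET and sitting
time are cut at the sex-stratified lowest/highest *fifth* (the Fried
convention; where sources disagree between quartile and quintile, the
quintile is the default and the fraction is configurable). With all values
equal in a stratum the cut degenerates to flagging everyone — documented
rather than special-cased. Low physical activity enters the Fried count as
(lowest MET quintile OR highest sitting quintile); the count is
weight loss + activity + slowness + weakness + exhaustion ∈ [0, 5], with
≥ 2 marking the pre-frail/frail phenotype. Missing raw values propagate to
missing indicators, and analyses are complete-case per indicator.

Associations are odds ratios for cluster membership versus the NOR
reference group. The unadjusted estimate has a closed form (cross-product
ratio; Wald CI `exp(ln OR ± 1.959964·√(1/a+1/b+1/c+1/d))`; a zero cell is
an error unless the Haldane 0.5 correction is requested). Logistic models
(maximum likelihood via statsmodels' IRLS) give the same estimand with
covariate adjustment: age–sex, and a fully adjusted set (age, sex, BMI,
resting SBP, cardiovascular disease, diabetes, antihypertensive use,
polypharmacy, elevated hsCRP — the elevated-CRP term is included even
though some summary tables omit it from their footnotes; it is
config-switchable). A logistic model containing only the group indicator
reproduces the 2×2 closed form to ≥ 6 significant digits — this analytic
equivalence is a standing test. Separation and non-convergence raise errors
naming the term; the pipeline skips such cells rather than reporting
unstable estimates. Group-level descriptive comparisons use χ² for
categorical and Kruskal–Wallis (or ANOVA where normality is asserted) for
continuous variables, with pairwise t/χ² tests flagged at the Bonferroni
threshold 0.017.

## Synthetic cohort generator

The generator defines the study conditions for every test and experiment.
Four archetypes parameterize the Δ% feature Gaussians, supine baseline,
pulse pressure and heart rate:

| archetype | early, stab, late Δ% (mean) | SDs | baseline (mmHg) | HR |
|---|---|---|---|---|
| iOHYPO | −15.2, 0.7, 0.3 | 9.3, 6.6, 7.3 | 119.1 ± 18.7 | 70.3 |
| OHYPO | −35.6, −15.5, −13.4 | 12.2, 9.5, 10.8 | 115.6 ± 18.9 | 69.2 |
| OHYPER | 2.2, 17.3, 15.6 | 11.3, 9.6, 10.4 | 111.2 ± 20.1 | 70.6 |
| NOR | −8.2, 1.6, 1.3 | 7.4, 5.1, 5.3 | 121.4 ± 19.6 | 70.7 |

Beat times are cumulative RR ~ Normal(60/HR, 0.05 s) truncated above 0.3 s.
Supine SBP is baseline plus AR(1) beat noise (innovation SD 2 mmHg,
coefficient 0.8 — chosen to give a realistic ~3 mmHg stationary beat-to-beat
variability; configurable). Standing SBP follows a monotone-cubic (PCHIP)
Δ% curve threaded through per-participant feature targets drawn from the
archetype's Gaussians. DBP is SBP minus the archetype's pulse pressure — no
independent DBP morphology is modelled.

The curve places flat plateaus over each feature's read-out window (the
nadir at 9–15 s, the stabilization window 37–43 s, the late phase
60–120 s), so each extracted feature equals its target exactly on the 1-s
grid; segments between plateaus are monotone and cannot overshoot. Because
the early feature is a *minimum* of trailing means over grid points 0–15,
a profile whose early target is positive (a rise from the first beat) is
generated with its onset step placed just before *t* = 0; pinning the curve
to zero at onset would make such targets unrecoverable by construction.
Noise-free archetypes round-trip through feature extraction to < 0.001 Δ%.

Cohort-level draws: multinomial group assignment (default proportions
0.245/0.208/0.250/0.297 for iOHYPO/OHYPO/OHYPER/NOR), per-group Bernoulli
frailty indicators at configurable prevalences (defaults encode, e.g., slow
gait at 23.0 % in OHYPER vs 13.0 % in NOR, a generating odds ratio of
~2.0), age ~ Normal(68.1, 7.2) clipped to [55, 105], and sex by per-group
female proportions.

**What the generator does not emulate** — and hence what passing tests do
*not* establish about real data: finger-cuff calibration drift and
measurement artefact beyond the simple AR(1) noise; within-person
(diurnal/seasonal) variability; correlation between indicators within a
participant (indicators are conditionally independent given the group);
continuous raw assessment values tied to the drawn indicators; DBP dynamics;
and any mechanistic baroreflex physiology. The generator validates the
*pipeline's statistics*, not device physics or physiology.

## Known limitations and open choices

* The quality screen is a stand-in, as discussed above.
* Fitted k-means centroids on overlapping Gaussian mixtures are pushed
  apart relative to the generating centres (assignment truncates each
  component), so recovered centroid distances systematically exceed the
  generating ones by ~5 % at these overlaps; recovery experiments should
  compare assignment agreement (adjusted Rand index) in preference to raw
  centroid geometry.
* Whether published silhouette/Jaccard values for comparable analyses used
  standardized features is generally unstated; this package computes both
  on the unstandardized Δ% space by default.
* Problem sizes in tests and the acceptance script (cohorts of 300–4000,
  20-seed recovery experiments at n = 900) were chosen as the smallest
  sizes at which the distributional checks are stable.
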