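# Methods

## Model

Inclination analysis treats a univariate biomarker series as a realisation
of a path-dependent stochastic process whose long-run behaviour is one of
two stable regimes: *survival* (the biomarker trends toward clinical
improvement) or *collapse* (toward worsening).  The observable is not the
regime itself but a sequence of binary local states, one per sliding window
of `m` consecutive samples, and the prediction compares the empirical
distribution of short state sequences against a neutral prior after both
are propagated to their absorbing limits.

Assumptions worth stating explicitly:

* **Univariate per decision.**  Each biomarker is analysed independently;
  multivariate structure enters only downstream, when the nine binary
  decisions become classifier features.
* **One-step window shift.**  Both the local-state extraction and the
  sequence-transition model advance one sample at a time, so the empirical
  sequence distribution `q_c` is estimated from the `L − m + 1` overlapping
  subsequences of the `L` local states.
* **Neutral dynamics between the critical levels.**  Unless a window
  already contains `m⁻` collapse or `m⁺` survival states, the next state is
  a fair coin (`r⁻ = 0.5`).  With `m⁻ = m⁺ = m` (the default) exactly two
  of the `2^m` sequences — all-collapse and all-survival — are absorbing,
  and the `2^m − 2` remaining sequences are transient.
* **Ties are collapse.**  A window score of exactly zero (e.g. a constant
  series) maps to the collapse state, the clinically cautious reading of
  "survival only when strictly improving".  A constant series therefore
  *collapses*; users should be aware of this convention for flat,
  well-controlled trajectories.

## Local-state scoring

The score of the window ending at sample `k` is `Xs = Σ Δᵢ wᵢ` over the
`m − 1` consecutive pairs in the window.  Four trend measures `Δᵢ` are
available — difference, signed time-integral ratio, slope per day, and bare
sign — and four weight rules `wᵢ` — constant 1, a binary 1-or-2 step at the
normality threshold, and linear 1-to-2 ramps between either the min/max
values or the low/high thresholds.  The weight is evaluated at the later
sample of the pair.  The guiding rule: a worsening move at a clinically bad
value, or an improving move at a good value, is *informative* and weighs up
to 2; moves in the benign configuration weigh 1.

Two numerical details:

* **Integral ratio.**  The area ratio of a pair segment to the whole
  series is intrinsically positive; we attach the sign of the local
  difference so every `Δ` scheme preserves "negative = improving".  Areas
  are time-weighted trapezoids on the true (fractional-day) timestamps.
* **Improvement direction.**  For increase-good biomarkers (HDL in the
  default panel), trend contributions are sign-flipped.  The weight rules
  are mirror-symmetric — reflecting both the trend sign and the value axis
  leaves `w` unchanged for every scheme — so the weight formulas need no
  direction branch; only the `Δ` flip matters.  Values outside the
  weighting interval are clamped to its endpoints (weights stay in
  `[1, 2]`).

## Decision

`Z_inf` is computed as `Z^10000` by binary exponentiation; for every
`m ≤ 5` this matches the fundamental-matrix absorption solution
`(I − Q)⁻¹R` to better than 1e−9 (asserted in the test suite, where the
linear solve serves as an independent oracle).  With the uniform prior the
baseline collapse probability is exactly 0.5, so the inclination index
`I = Pc⁻/P⁻` lives in `[0, 2]`.  The decision band `δ = 0.1` absorbs the
inherent uncertainty of clinical data; inside the band the series is split
into its first and last `⌊L/2⌋` states (middle state dropped when `L` is
odd, keeping the halves balanced) and collapse is declared only when the
collapse share strictly rises; equal shares default to survival.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `m` | 3 (4 in variant 6) | sliding-window length, samples |
| `r⁻` | 0.5 | collapse probability below the critical levels |
| `m⁻, m⁺` | `m` | critical state counts forcing the next state |
| `l` | 10,000 | exponent approximating the limiting matrix |
| `δ` | 0.1 | half-width of the no-inclination band |
| min readings | 5 | eligibility threshold per biomarker (→ ≥ 9 samples) |
| lead window | 365 days | case readings this close to onset are excluded |

The nine-biomarker panel (BMI, dBP, sBP, fasting glucose, HbA1c, HDL, LDL,
total cholesterol, triglycerides) ships as a CSV resource with the five
clinical landmarks per biomarker and is user-replaceable for other diseases
or guidelines; units are informational and never converted.

## Synthetic data: what it emulates, and what it does not

The generator exists because the source EMR cohort is access-restricted.
It emulates the *structure* of such data: per patient, all nine biomarkers,
5–8 readings at irregular (exponential-like, mean 180 days) intervals,
values inside each biomarker's observable scale.  Trajectories are linear
drifts in units of the clinically acceptable range plus two noise
components: white Gaussian measurement noise (`noise_sd`, as a fraction of
the low–high range) and sporadic large artifacts (probability 0.15 per
reading, magnitude 0.4–1.0 of the range) representing transient illness,
posture/cuff effects and lab error — the heavy-tailed component
characteristic of routinely collected values.  Ground truth derives from
the *noiseless* trend alone, so truth labels are invariant to the noise
realisation and parameter-recovery tests have an objective target.

Two placement regimes are deliberate design choices:

* **Labeled validation series** are anchored to the normality threshold:
  deteriorating series start just beyond it on the bad side and traverse
  0.65 of the acceptable range further into abnormality; well-controlled
  series start on the good side and improve by a milder 0.35.  This mirrors
  how labeled collapse/survival series present clinically (collapse series
  sit at abnormal values) and is the regime in which the clinically
  weighted variants genuinely out-resolve the unweighted original.
* **Cohort trajectories** are mean-reverting: series drifting up start low,
  series drifting down start high.  This emulates a managed population —
  patients observed at high values tend to be treated and drift down — and
  makes the time-averaged level a deliberately weak readout of the trend,
  so the planted group signal lives in the trajectories, not the means.
  The drift is pinned to each series' realised time span so the noiseless
  trend never hits the observable-scale clamp.

What the generator does **not** emulate: comorbidity and medication
confounding, regime switches within a series, informative sampling
(sicker patients measured more often), missing biomarkers, and label noise.
Passing recovery tests therefore shows that the implementation decodes the
structure it defines — not that comparable accuracy would be reached on
real EMR data.

## Problem sizes

The bundled experiments run at the scale the method is designed for: the
variant benchmark uses 40 patients × 9 biomarkers = 360 labeled series;
the cohort experiments use 349 cases and 349 controls with a planted
pattern-match gap of `effect = 0.5` and noise 0.1; the decision-tree
comparison uses depth-3 CART trees over 40 stratified 75/25 hold-out
shuffles, both feature modes re-using identical per-iteration splits
(seeded `seed_base + iteration`) so the comparison is paired.  AUC uses the
tree's leaf class fractions as scores.  The whole suite runs in seconds.

## Known limitations

* The collapse-on-tie convention makes flat series collapse; for
  biomarkers parked exactly at the normality threshold this may surprise.
* `I` is compared against a uniform-prior baseline; with `r⁻ ≠ 0.5` the
  index is no longer bounded by 2 and the band interpretation changes.
* The eight variants share one `δ`; no per-biomarker calibration is
  attempted.
* Group-difference tests (chi-square, t) are reporting conveniences on top
  of standard scipy routines, not new statistics.
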