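# Methods

This note documents the models and procedures implemented in `copdwatch`,
the parameters that matter, the numerical choices, and what the synthetic
data do and do not establish.

## State machine for exacerbation identification

Each diary session is reduced to a 3-bit input.  The first bit is the
*medication-event* bit: it is set when oral antibiotics or steroids are
**started** (a rising edge of the flag relative to the previous session;
a flagged session arriving ≥ 7 days after the last flagged one counts as a
new course), when increased reliever-inhaler use has been sustained for at
least 48 hours (a contiguous run of flagged sessions spanning ≥ 2.0 days;
consecutive run members may be up to 2 days apart, and a non-flagged session
breaks the run), or when the patient reports a health-care-professional
contact.  The remaining two bits code the symptom change: `00` no change,
`10` worse, `11` improved (`01` is illegal and rejected).

Symptom answers are categorical and self-relative ("compared with what is
usual for me").  *Worsening* requires at least two "worse" answers with at
least one major symptom.  *Improvement* mirrors this against the previous
session: an answer counts toward improvement if it is "improved", or if
that symptom was "worse" last session and is "no change" now; again two
answers including a major symptom are required.  When a session satisfies
both definitions simultaneously, worsening wins — the conservative choice
for a deterioration detector.  Each session is classified on its own
answers (plus the one-session look-back); repeated "worse" answers on
consecutive days are re-evaluated independently.

The machine has three states with start state NORMAL:

| from \ input    | (·,00)  | (0,10)       | (1,10)       | (·,11) | (1,00)       |
|-----------------|---------|--------------|--------------|--------|--------------|
| NORMAL          | NORMAL  | TRANSITIONAL | EXACERBATION | NORMAL | NORMAL       |
| TRANSITIONAL    | (0) stay| TRANSITIONAL | EXACERBATION | NORMAL | EXACERBATION |
| EXACERBATION    | stay    | stay         | stay         | NORMAL | stay         |

Patients in NORMAL stay there unless symptoms worsen, whatever their
medication; EXACERBATION is left only through symptom improvement, so no
EXACERBATION → TRANSITIONAL path exists.  One *exacerbation event* is a
maximal run of sessions in EXACERBATION; its length is the day span from
the entering session to the session that exits to NORMAL, rounded up, with
a minimum of one day (events still open at the end of monitoring are
flagged).  Bookkeeping invariant, checked on every cohort: per patient,
exits(NORMAL) − entries(NORMAL) equals 1 exactly when the patient finishes
outside NORMAL, so the cohort-level imbalance equals the number of
non-NORMAL finishers.

## Period selection

States change only at session times, so between sessions a day inherits the
state of the most recent session; before the first session patients are
assumed NORMAL.

*Prodromal* periods are the 7 days immediately before an event's entering
session, kept only if the whole window was spent in NORMAL or TRANSITIONAL
(an event following a previous event by less than 7 days is dropped) and at
least two sessions fall inside (a line fit needs two points; the two-session
minimum is applied to both labels).

*Stable* periods tile the maximal NORMAL stretches: each stretch is trimmed
by a 7-day guard band after a return to NORMAL and before the next departure
(no guard is applied against enrollment or the end of monitoring, since
guards are defined relative to non-NORMAL states), and the remainder is
filled left-to-right with disjoint 7-day windows; leftover days shorter than
a window are discarded.  A NORMAL stretch of d days bounded by non-NORMAL
states on both sides therefore yields ⌊(d − 14)/7⌋ windows.

## Respiratory rate from the PPG

Breathing amplitude-modulates the PPG; respiratory sinus arrhythmia
(frequency modulation) also exists but is attenuated in older adults, so
the amplitude route is used.  The pipeline per 30-s segment:

1. **Mean removal** and a **heart-rate-adaptive low-pass filter**: linear-
   phase FIR (Kaiser design) with passband edge 0.5×HR and stopband edge
   1.2×HR (Hz equivalents), ≥ 40 dB stopband attenuation and < 1 dB
   passband ripple; applied with its group delay compensated (zero phase).
   The heart rate comes from the device, with a beat-detection fallback
   (band-pass 0.5–3 Hz, peak picking, 60 / median inter-beat interval,
   failing below 10 detected beats).
2. **Decimation to 4 Hz** (polyphase resampling), concentrating the
   autoregressive poles in the respiratory band for short segments.
3. **Median AR spectrum**: Burg fits at orders 4–12 (configurable), each
   power spectrum evaluated on a fixed 0–1 Hz grid with 0.004 Hz spacing,
   then the pointwise median across orders — robust to any single order
   placing a spurious pole.
4. The respiratory rate is 60× the in-band peak frequency (default band
   4–40 breaths/min).  The estimate is rated `ok` only if the peak rises
   ≥ 3 dB above the band's median power **and** is interior to the band;
   an edge maximum is typically the skirt of residual cardiac power, which
   is how unmodulated pulse trains are rejected.  Upstream failures
   (degenerate signal, too few beats) propagate as `failed`.

On clean amplitude-modulated waveforms (depth 0.2) the estimator recovers
rates across an 8–30 brpm × 60–100 bpm grid with a mean absolute error of
about 0.3 brpm and a small positive bias (spectral-grid quantisation plus
AR peak smearing at 30 s); accuracy degrades monotonically with additive
noise.  The estimate is invariant to positive rescaling of the waveform.

## Trend features

For each vital sign in each period, session times are shifted so the first
session sits at x = 0 and a straight line is fitted by ordinary least
squares; the feature pair is the **gradient** (units/day) and the
**unweighted session mean** (not the fitted midpoint — the mean is what the
period summary statistics report).  Sessions missing one vital are excluded
for that vital only; a period in which any vital has fewer than two values
is dropped with a logged reason.  Multiple sessions on one day are kept as
distinct points, and missing days are simply absent — the line fit is the
answer to irregular sampling, not imputation.  The per-period standard
deviation and intercept are computed behind a flag but excluded from the
default feature set (they added no discriminative value).

## Classifier and validation

Plain logistic regression (no regularisation by default; optional ridge) on
the six features.  Features are z-scored with training-fold statistics —
predictions are invariant to this at the optimum, but conditioning
improves; the optimum of the convex cross-entropy cost is found with
L-BFGS from a zero start and then polished with guarded Newton steps to a
gradient norm near machine precision, making the fit deterministic and
permutation-invariant.  Probabilities are clipped at 1e-12 inside the cost
so saturated predictions stay finite.

Validation repeats unstratified 10-fold cross-validation (partitions are
resampled, with a log message, in the rare case a training split lacks a
class).  Out-of-fold probabilities are pooled over the ten folds into one
ROC per repeat — scoring the whole dataset per repeat — rather than
averaging fold-level curves.  The mean ROC averages true-positive rates
vertically on a fixed 101-point false-positive-rate grid; the 95% band is
the 2.5/97.5 percentile envelope across repeats.  The headline AUC is the
mean of per-repeat trapezoidal AUCs (the AUC of the mean curve is also
reported).  Specificity at a requested sensitivity is read off the mean
curve at the smallest grid FPR whose mean TPR reaches the level.  Feature
subsets (each vital alone and every combination) are compared under a
shared partition stream so AUC differences are not fold luck.  Folds are
drawn over periods, as in the source protocol, so periods from one patient
can appear in both training and test; a `groups` option provides the
stricter per-patient folding for sensitivity analyses.

## Synthetic cohort generator

The generator is the package's test bed and defines its study conditions:
100 patients × 365 days by default, sessions on ~5.3/7 of days at a uniform
daytime hour (08:00–20:00, whole-second resolution), exacerbation onsets
from a Poisson process (3.6/patient-year) with the episode itself as dead
time, and episode lengths from a shifted log-normal with a 1-day minimum,
mean 8.8 days and median ≈ 4 days (observed events span at least a day by
construction, so a sub-day latent episode would be unobservable by design
rather than by compliance).  Diary answers are generated so the state
machine recovers the latent onsets: symptoms worsen and a drug course
starts at the first session of each episode, a persisting complaint
prevents spurious mid-episode "improvement", symptoms improve at the first
post-episode session, and benign transitional blips (worsening without
medication, resolving within ~2.5 days) occur at a low rate in stable
stretches and at an elevated rate during the 7-day prodrome, reproducing
both the direct NORMAL→EXACERBATION route and the route through
TRANSITIONAL.

Vitals are class-conditional gaussians.  Outside episodes and prodromes
they sit at the stable means (SpO₂ 94%, PR 80 bpm, RR 22 brpm); during the
7-day prodrome they drift linearly with the configured per-day trend
(default: the gradient connecting stable to prodromal means across 7 days),
centred so the prodrome-average equals the prodromal means (93, 83, 24).
Within-class standard deviations are not published for the source
population; the defaults (2%, 8 bpm, 3 brpm) give heavily overlapping
session-level class distributions and are exposed as parameters, as are
cross-class means and trends.  SpO₂ is clipped at 100%.

PPG segments are gaussian-bump pulse trains with sinusoidal amplitude
modulation at the respiratory frequency, optional sinusoidal period
modulation (emulating sinus arrhythmia) and additive white noise.  Only the
modulation structure matters to the estimator; pulse morphology (dicrotic
notch etc.) is deliberately not modelled.

**What the synthetic data do not show.**  The generator has no
between-patient baseline heterogeneity, no cross-vital correlation, no
missing-not-at-random compliance, and its prodromal drift is exactly
linear.  Cross-sectional classification is therefore substantially easier
than on real patients — synthetic AUCs (~0.6–0.9 across subsets) sit well
above what heterogeneous clinical populations yield — so passing tests
establish the correctness and calibration of the machinery, not clinical
performance.  Qualitative structure (prodromal directions of change; SpO₂
more predictive than pulse rate; combinations at least as good as single
vitals) is preserved and asserted; absolute AUC values are not comparable.

## Problem sizes and determinism

Default problem sizes were chosen to keep a full run interactive on one
CPU: the bundled end-to-end example uses 20 patients × 180 days with 100
cross-validation repeats (~15 s), and `scripts/acceptance.py` uses 60
patients × 365 days with 100 repeats (~40 s); the full validation protocol
(1000 repeats) is a configuration change (`cv_reps=1000`).  All randomness
descends from a single root seed through spawned seed sequences (per
patient, per waveform), so identical configurations reproduce every
artifact byte-for-byte; per-session waveform seeds are derived from the
patient id (CRC32) and session time, independent of iteration order.

## Known limitations

- Exacerbations beginning while a patient is TRANSITIONAL and reported only
  through an HCP contact are invisible when the contact channel is absent
  (the synthetic cohort generates none by default).
- The improvement look-back spans exactly one session; a worsening resolved
  across a multi-session gap with changed answers may be classified
  conservatively as no change.
- The respiratory-band upper edge (40 brpm) and the decimation target
  (4 Hz) assume adult rates; both are parameters.
- `attach_vitals` drops sessions missing any vital from a period, while
  feature extraction tolerates per-vital gaps; the pipeline uses the
  stricter path.
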