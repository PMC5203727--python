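# Methods

This note documents the models, parameter choices and numerical
decisions behind `tremorkit`, and what the synthetic-data experiments
do and do not demonstrate.

## Signal model of the synthetic generator

No public recordings exist for the glove protocol, so the generator
simulates sessions with the statistical structure the analysis chain
assumes. Per inertial channel the signal is additive:

* **static offset** — uniform on ±3 sensor units per axis, emulating
  gravity on accelerometers and the geomagnetic field on magnetometers.
  The scale is deliberately large relative to typical tremor
  excursions: when the static vector dominates, the 3-axis resultant
  responds linearly to the oscillation, as in real limb recordings.
  With a near-zero offset the resultant rectifies the oscillation and
  doubles its apparent frequency, which is physically wrong for this
  sensor configuration.
* **drift** — a random cubic polynomial over the session, scaled by the
  subject's `drift_scale` (default 0.5). This is the component the
  degree-20 detrend exists to remove.
* **voluntary movement** — a task-gated oscillation at 0.5–3 Hz
  (2.5 Hz finger taps, 0.8 Hz finger-to-nose, 1.5 Hz
  supination/pronation, none at rest), with the finger-to-nose task
  given the largest amplitude. Zero during rest, so the rest task
  isolates tremor.
* **tremor** — a sinusoid at the subject's tremor frequency (drawn
  uniformly from 4–6 Hz, the classic parkinsonian rest-tremor band)
  with a slow stochastic amplitude modulation (smoothed Gaussian noise,
  2 s window, clipped to ≥ 0.2 of the carrier) so the instantaneous
  amplitude is informative rather than constant.
* **white Gaussian noise** — `noise_sd` (default 0.1).

EMG envelopes are smoothed (0.2 s moving average) rectified copies of
the voluntary + tremor drive plus folded noise, hence nonnegative.

Cohort structure: subject tremor amplitudes are lognormal within group
(log-SD 0.4) so subjects are heterogeneous and subject-wise splitting
is meaningful. The default group medians place the levodopa group
highest, the DBS group intermediate and healthy controls near the
noise floor; a single `effect_size` dial scales this contrast, with 0
giving a null cohort in which the three groups are statistically
identical. Default sizes are 10/16/12 (S_H/S_PD/S_DBS) subjects, 4
tasks × 10 s × 5 trials at 50 Hz with rest gaps between trials
(default 30 s; rest samples are never analysed, so tests and the
acceptance script shorten the gap to 2 s purely to reduce simulated
data volume).

The generator emulates the *statistical* targets of each processing
stage, not biomechanics: no limb kinematics, no magnetometer physics,
no levodopa pharmacokinetics, no bradykinesia/rigidity phenomena
beyond amplitude scaling. Passing end-to-end tests therefore shows the
pipeline recovers group structure of this additive-oscillation form;
it does not validate clinical performance on real patients.

## Preprocessing

* **Band-pass 0.5–25 Hz, Butterworth order 4, zero-phase** (forward-
  backward `sosfiltfilt`; the magnitude response is squared, phase is
  exactly zero). At 50 Hz sampling the 25 Hz upper edge equals Nyquist,
  where a digital band edge is undefined; since no content exists above
  Nyquist the filter degenerates to the order-4 high-pass at 0.5 Hz.
  The alternative — clamping the edge just below Nyquist — puts poles
  nearly on the unit circle whose transients ring for thousands of
  samples.
* **Detrending**: subtraction of the mean and a degree-20 least-squares
  polynomial fitted on a time axis rescaled to [−1, 1] (fitting on raw
  sample indices at degree 20 is numerically singular). Detrending is
  applied to the full record before windowing, so one smooth trend
  model serves all task segments.
* **Analytic signal**: `scipy.signal.hilbert`; IA = |x + iH(x)|; IF =
  central finite differences of the unwrapped phase ÷ 2π (one-sided at
  the edges), reported in Hz. Where IA < 1e-12 × max(IA) the phase is
  numerically meaningless and IF is set to 0.
* **Segmentation**: five pulses per trial (start of each task plus end
  of the last) cut four half-open windows labelled T1–T4 in execution
  order; an explicit window table can replace pulse-derived windows for
  real data annotated by hand.

Edge effects: the analytic signal and the 0.5 Hz high-pass both have
transients of roughly 1–2 s at record boundaries; closed-form checks
therefore evaluate the central 80% of their windows.

## Features

"Normalized" first/second-difference features use the z-scored signal
(population SD); min-max normalization is available via configuration.
A zero-variance window defines all normalized variants and ApEn as 0.
PEAK is the signed global maximum. STD/VAR are sample (n−1) statistics.
ApEn follows Pincus: m = 2, r = 0.2 × SD (population), Chebyshev
distance, self-matches included — the field-standard parameterisation,
both configurable. The implementation accumulates Chebyshev distances
as running maxima of shifted scalar-distance matrices (O(n²) instead
of O(n²m) memory traffic); it is bit-equivalent to the naive double
loop and tested against one.

Feature matrices are z-scored column-wise before projection: the
battery mixes scales (VAR vs ApEn) and an unstandardized Euclidean
distance would be dominated by the widest column. Constant columns
standardize to zero.

## Sammon mapping

Initialisation is the first two principal components (deterministic,
via SVD with a sign convention); seeded random initialisation is
available. Optimisation is Sammon's diagonal pseudo-Newton iteration
with magic factor 0.35 and step halving on any stress increase, so the
stress trace is monotone by construction; stopping at 500 iterations
or relative improvement < 1e-9. Duplicate rows are jittered by
1e-9 × column SD and zero-distance pairs dropped from the stress sum.

The pipeline projects each task × combination cell **jointly** (all
subjects) and then splits subject-wise for classification, mirroring
the protocol in which the low-dimensional data set is computed once
and then resampled. This leaks test-subject geometry into the
projection; held-out rates are therefore optimistic relative to a
strictly prospective setting. A strict mode (`embed_new_points`)
projects training data only and places test points by inverse-distance
interpolation among their 3 nearest training neighbours.

## PERMANOVA

One-way Anderson pseudo-F on Euclidean distances;
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), ties counting as
exceedances (conservative, p > 0 guaranteed). Pairwise tests multiply
raw p by the number of pairs, capped at 1. Default 10,000 permutations.

Permutation level matters: the five windows of one subject cluster, so
under a subject-level null they are not exchangeable, and
observation-level permutation is strongly anticonservative (typical
null-cohort p ≈ 0.004 empirically). The pipeline therefore permutes
group labels across whole subjects; observation-level permutation
remains the default for plain coordinate inputs with no subject
structure and is exact against exhaustive enumeration on small
fixtures.

## EDDA classification

One Gaussian per class. In 2-D the eigenvalue-decomposition covariance
family collapses to six constraints (spherical/diagonal/full ×
shared/per-class); richer parameterisations are redundant in the
plane. `auto` selects by stratified 10-fold cross-validated error on
the training data, ties toward fewer parameters. Covariance
eigenvalues are floored at 1e-8 × trace to keep degenerate classes
positive-definite. Priors are empirical; prediction is the Bayes rule
with ties broken by the fixed class order (S_H, S_PD, S_DBS).

Evaluation: 1000 subject-wise splits by default, each drawing 5
training and 5 distinct test subjects per group (with 10 healthy
subjects, 5 + 5 exhausts that group, which forces the count). The
"classification set" rates are 10-fold CV within the training
observations; the test rates are held-out predictions. Reported tables
carry the nine mean actual(predicted) rates, MeanTP/StdTP (mean and SD
of the three diagonal rates) and per-combination Mean/Std rows.

## Problem sizes in tests and the acceptance script

Chosen as the package's own trade-off between statistical resolution
and desk-scale runtime: type-I calibration uses 500 null coordinate
cohorts at 199 permutations (the discrete null then puts exactly 5%
of its mass at p ≤ 0.05); end-to-end cohort experiments use full-size
38-subject cohorts, the rest task, 100–200 splits and 999–2000
permutations; chance level is measured as the mean held-out rate over
several independent null cohorts, because a single cohort's rate has
sampling spread of ~0.06 around 1/3 (spurious chance structure
survives the joint projection), while the mean over cohorts estimates
the chance level itself. The tetrahedron stress oracle uses 20–30
Nelder-Mead restarts.

## Known limitations

* Synthetic realism is limited to the additive model above; real
  tremor is non-sinusoidal, non-stationary and coupled across axes.
* The joint-projection leakage described under "Sammon mapping".
* ApEn on 500-sample windows has a known negative bias at small n;
  comparisons are only made within fixed window length.
* The EDDA "auto" criterion (CV error) can be unstable between
  constraints of similar fit on small training sets; this only swaps
  near-equivalent decision boundaries.
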