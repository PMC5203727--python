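# tremorkit

Objective discrimination of Parkinson's disease (PD) treatment groups —
healthy controls (S_H), PD patients on levodopa (S_PD) and PD patients
with deep brain stimulation (S_DBS) — from wearable inertial and EMG
recordings of standard clinical tasks.

Clinical assessment of PD motor symptoms relies on subjective rating
scales. `tremorkit` implements an end-to-end objective alternative for
a glove-style sensor setup: two inertial units (3-axis accelerometer,
gyroscope, magnetometer), two EMG envelope channels, sampled at 50 Hz,
while the subject performs four tasks (finger taps, finger-to-nose,
supination/pronation, rest) for 10 s each across five trials.

## Method

For each 3-axis sensor the resultant R = sqrt(X² + Y² + Z²) is formed,
band-pass filtered (zero-phase Butterworth, order 4, 0.5–25 Hz, the
upper edge degenerating to a high-pass at 50 Hz sampling), and detrended
by removing the mean and a 20th-order least-squares polynomial. The
Hilbert transform H(x) then yields the analytic signal
z(t) = x(t) + iH(x)(t), whose modulus a(t) = |z(t)| is the instantaneous
amplitude (IA) and whose unwrapped phase derivative, θ'(t)/2π, is the
instantaneous frequency (IF) in Hz. Features are computed on the
filtered signal (FS), IA and IF per task window and channel:

* amplitude: MAV, RMS, PEAK, and mean absolute first/second differences
  of the raw (MAVFD, MAVSD) and normalized (MAVFDN, MAVSDN) signal;
* variability: interquartile range, range, SD, variance;
* regularity: approximate entropy ApEn(m = 2, r = 0.2·SD).

Per task and method combination (FS, IA, IF, FS–IA, FS–IF, IA–IF,
FS–IA–IF) the 96·|combo|-column feature matrix is projected to 2-D by
Sammon's mapping, which minimises the stress

E = (Σ d*ᵢⱼ)⁻¹ · Σᵢ<ⱼ (d*ᵢⱼ − dᵢⱼ)²/d*ᵢⱼ.

Group differences on the projection are tested by PERMANOVA (Euclidean
distance, 10,000 permutations, Bonferroni-corrected pairwise tests;
permutation at the subject level since a subject's windows are not
exchangeable), and classified by eigen-decomposition discriminant
analysis (EDDA): one Gaussian per class under a covariance constraint
chosen by 10-fold cross-validation, evaluated over 1000 subject-wise
train/test resamplings (5 training and 5 held-out subjects per group).
Results are row-normalized 3×3 confusion tables with per-class success
rates and MeanTP/StdTP summaries.

Because the original recordings are not publicly deposited, the package
includes a first-class synthetic-cohort generator (group-dependent
amplitude-modulated tremor, task-gated voluntary movement, drift,
gravity offsets, EMG envelopes) so every stage is testable against
known ground truth.

## Worked example

```
tremorkit simulate --n-h 10 --n-pd 16 --n-dbs 12 --seed 0 --rest-gap 2 --out scratch/cohort
tremorkit run --input scratch/cohort --tasks T2,T4 --combos FS,FS-IA \
    --splits 200 --n-perm 2000 --out scratch/out
```

This run (about a minute) printed the statistics table

```
task  combo  pseudo_F   p_value   sammon_stress
T2    FS     60.0800    0.0005    0.0802
T2    FS-IA  76.7860    0.0005    0.0800
T4    FS     64.2593    0.0005    0.0587
T4    FS-IA  70.6179    0.0005    0.0678
```

— large pseudo-F values with the permutation p saturated at its
minimum 1/(2000+1), confirming group separation on the simulated
cohort — and the held-out success table (`table_test_*.tsv`) reported
mean per-class rates with MeanTP 0.63–0.79 (e.g. FS-IA/T4: 0.784):
healthy subjects are recognised most reliably, and the levodopa/DBS
groups overlap each other more than either overlaps the controls, the
clinically expected pattern. The equivalent library
calls are `generate_cohort`, `preprocess_recording`, `extract_features`,
`build_matrix`, `sammon_map`, `permanova_with_pairwise`,
`make_splits`/`evaluate_splits`.

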