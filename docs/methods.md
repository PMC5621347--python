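# Methods

## Problem and model

A Parkinsonian resting tremor is a rhythmic, roughly 4–6 Hz oscillation of
the hand whose clinical severity is rated on the UPDRS resting-tremor item:
0 (absent) through 4 (marked in amplitude and present most of the time).
The rating couples two physical properties — oscillation amplitude and the
fraction of time the tremor is present — which is why the feature set mixes
time-domain amplitude/rhythm descriptors with spectral band powers.

The scoring model is an ordinary multiclass classifier over handcrafted
kinematic features; ordinality enters only through the evaluation metrics
(absolute error `e = |û − u|`, its CDF, and NAuC), not through the
classifier itself. With very few severe recordings in any realistic clinic
population, leave-one-out cross-validation is used so every recording is
scored by a model trained on all others.

## Preprocessing

* **Band-pass 1–16 Hz, 5th-order Butterworth.** Applied forward–backward
  (`sosfiltfilt`), so peaks used by the regularity features are not
  lag-shifted; the effective magnitude response is the square of the
  single-pass response. Tremor energy lives well inside the band, where the
  squared response is still ≈ 1.
* **Integration.** Displacement = acceleration integrated twice, angle =
  angular velocity integrated once, by cumulative Simpson. Trapezoid
  integration was rejected: at 125 Hz it attenuates a 10 Hz tone by ~2.1%
  per pass, breaking the analytic 1/ω² amplitude relation the displacement
  features rely on; Simpson keeps the error below ~0.2% across 2–10 Hz.
  The band-pass is re-applied after every integration pass because
  integrating broadband noise produces a random-walk drift that would
  otherwise dominate the displacement signal.
* **Segmentation.** The first and last 10 s are discarded (sensor settling,
  handling); a 30-s window is then centered in what remains, so a 50-s
  recording uses the whole trimmed region. Filtering and integration run on
  the full recording so their edge transients fall inside the discarded
  margins. The residual numerical mean of the finite window (filtfilt edge
  residue, ~1e-4 of RMS after double integration) is removed after
  segmentation, so processed signals are exactly zero-mean.
* Durations are expressed in seconds and converted by the sample rate, so
  non-125 Hz recordings are accepted unchanged.

## Features (19 per signal × 4 signals)

The composite signal is the per-sample Euclidean magnitude of the three
axes. Its "negative peaks" are local minima (the magnitude is nonnegative).
Peak detection uses a minimum separation of half the 16 Hz period
(≈ 0.031 s), forbidding super-band peaks, and a prominence floor of 5% of
the composite's interquartile range to ignore noise ripple; runs of
same-type extrema are collapsed to the extremal one so maxima and minima
strictly interleave. A signal with fewer than two usable peaks yields 0 for
the peak-based features, with a warning.

Mean amplitude averages, over every positive peak flanked by minima, the
half-sum of its drops to the preceding and following minimum. Regularity is
the mean of successive positive-peak intervals; its variability is their
(population) standard deviation.

Spectra are Welch periodograms (Hann window, 512 samples ≈ 4.1 s at 125 Hz,
50% overlap — ~0.244 Hz resolution, stable band powers on a 30-s window),
averaged across the three axes at each frequency. Peak/mean frequency and
their powers are computed over (0, 16] Hz; mean power is the PSD at the
grid frequency nearest MF (nearest-bin, not interpolated). The tremor band
is [MF−3, MF+3] Hz clamped to [0, 16]; band membership is half-open/closed
([0, f₁), [f₁, f₂], (f₂, 16]) so every bin belongs to exactly one band, and
relative powers divide by the total 0–16 Hz power. Log features are
log₁₀(max(v, 1e-12)); the floor keeps tremor-free recordings finite.

Canonical column order: signals acc, gyro, disp, angle; within each signal
the 19 features in the order declared in `features.FEATURE_ORDER`. The
order is load-bearing for reproducible selection indices.

## Feature selection

Pairwise ordering uses absolute Pearson correlation ("most unrelated" must
treat r = −0.9 as highly related). The first two features are the globally
least-correlated pair; each next feature minimizes its maximum |r| against
the selected set (minimax; a mean-|r| variant is available). Ties break by
canonical column order. Constant features have undefined correlation and
are excluded with a warning.

PCA standardizes features first by default — the 76 features span seconds,
metres and log-power, and unstandardized PCA would be dominated by a single
unit. Standardization deliberately breaks rotation invariance; the
`standardize=False` switch recovers plain PCA (and is what the
rotation-invariance property test exercises).

Inside cross-validation both reductions are refitted on each training fold
by default. Fitting on all data leaks sample-dependent (though label-free)
structure; the optimistic variant is available as `fit_on_all=True`.

## Classifiers

Defaults, all exposed: decision tree (Gini, no depth cap, min leaf 1),
random forest (100 trees, seeded), SVM (C = 1, poly degree 3, RBF
gamma = 1/(d·var)), discriminant analysis (linear by default, quadratic
available), kNN (Euclidean, uniform weights, odd k so votes cannot tie
between two classes). Scale-sensitive families (SVM, kNN, DA) are z-scored
inside each training fold; trees and forests consume raw features. No class
re-weighting or resampling: training on the imbalanced severity
distribution — and observing the resulting bias toward the dominant mild
classes — is part of the method being studied.

## Evaluation

* accuracy = CDF of e at 0; Wald CI half-width z√(p(1−p)/n), z = 1.96.
* NAuC = trapezoidal area of the five-point error CDF over [0, 4] divided
  by 4; 1.0 is perfect.
* Per-class recall/precision carry Wald intervals whose n is the grand
  total of the confusion matrix by default (`ci_n="class"` switches to the
  per-class margin). A never-predicted class has *undefined* precision,
  reported as an explicit flag, never 0 or NaN.
* RMSE is reported in two labelled variants, √(mean e²) and √(Σe²)/n,
  because the field is not consistent about the denominator.

## Synthetic generator

Each recording is `A · g(t) · [sin(2πft + φ) + 0.1·sin(4πft + φ₂)]` with f
drawn once per recording from 4–6 Hz (the classic Parkinsonian resting
band), projected onto a random unit 3-vector for the accelerometer and an
independent one for the gyroscope (wrist rotation vs fingertip
translation; gyro amplitude = 0.5 rad/s per m/s²), plus per-axis white
noise (σ = 0.01 m/s², ≈ 1 mg broadband — realistic MEMS accelerometer
noise) and random-walk drift (σ = 0.05) on all six channels. g(t) is a
two-state Markov gate with stationary duty equal to the class's duty cycle
and a 4-s mean on+off cycle, giving multi-second runs for "intermittently
present" classes. Severity ladder: amplitudes 0, 0.05, 0.15, 0.45,
1.35 m/s² (geometric, ×3 per step) and duty cycles 0, 0.3, 0.8, 0.9, 0.95,
mapping the clinical rubric's slight/infrequent → marked/most-of-the-time
progression. The default 60-s duration satisfies the 10 + 30 + 10 s
preprocessing requirement.

What the generator does *not* emulate: re-emergent/postural dynamics,
voluntary-movement artifacts, gravity leakage through orientation change,
amplitude fluctuation within an "on" period, sensor saturation, and
between-patient frequency drift within a recording. Tests passing on this
generator therefore demonstrate that the pipeline recovers amplitude,
persistence and frequency structure when it is present — not clinical
accuracy on patient data, which cannot be claimed without recordings.
Accordingly, the synthetic classes are well separated by construction and
the end-to-end LOOCV check is a property threshold (≥ 0.8), not a clinical
performance claim.

## Problem sizes and numerics

The packaged test suite and the acceptance script use 20 recordings per
class (100 total, 60 s each) for the pipeline-recovery checks — enough for
stable medians and a meaningful ≥ 95% frequency-recovery criterion while
keeping a full LOOCV sweep cheap. Frequency recovery is judged against one
Welch bin (0.244 Hz). All randomness flows from a single seed through
`numpy.random.SeedSequence` spawns, so datasets are bit-reproducible and
recordings mutually independent.

## Known limitations

* The mean-amplitude estimator is biased upward on pure noise (peaks of a
  rectified noise process); class-0 recordings therefore have small but
  nonzero amplitude features, which is also true of real sensor data.
* The pairwise ordering is greedy, not globally optimal, and its trace is
  not monotone by construction.
* Wald intervals are poor near p = 0 or 1 (e.g. a recall of 0 gets a ±0
  interval); they are used because they are the convention the evaluation
  reproduces, not because they are the best interval.
* With LOOCV and a singleton class, that fold's training set lacks the
  class entirely; the prediction is necessarily wrong. This is inherent to
  the protocol, logged, and visible in the undefined precision of the most
  severe class.
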