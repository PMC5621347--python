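# tremorscore

Automatic scoring of Parkinsonian resting-tremor severity — the UPDRS
resting-tremor item, 0 (absent) to 4 (marked in amplitude and present most
of the time) — from a wrist/finger-worn inertial measurement unit (tri-axial
accelerometer + tri-axial gyroscope, 125 Hz).

The package is for researchers in movement-disorder digital biomarkers who
want a tested reference implementation of the classic feature-based scoring
pipeline, and a synthetic tremor generator to exercise it when no patient
recordings are available.

## The pipeline

1. **Preprocess** — scale to SI units, band-pass 1–16 Hz (5th-order
   Butterworth, zero-phase), derive displacement (double integration of
   acceleration) and angle (single integration of angular velocity), and cut
   a 30-s analysis window from the middle of the recording after dropping
   the first and last 10 s.
2. **Features** — from each of the four signals (acceleration a, angular
   velocity ω, displacement x, angle θ), compute 19 features from the
   per-sample composite magnitude `mag(t) = √(x² + y² + z²)` and the
   axis-averaged Welch spectrum: mean peak-to-peak amplitude
   `Σᵢ (Amp1ᵢ + Amp2ᵢ)/2 / n`, average regularity
   `Σᵢ |tpᵢ₊₁ − tpᵢ| / (n−1)` and its SD; peak/mean frequency
   (`MF = Σ fᵢPᵢ / ΣPᵢ`), peak/mean power; absolute and relative powers in
   three adaptive bands split at MF ± 3 Hz within 0–16 Hz; and six
   log₁₀ features. 76 features per recording.
3. **Select** — pairwise-correlation ordering (first pair = globally minimal
   |Pearson r|; then greedily append the feature least correlated with the
   selected set) or PCA on z-scored features.
4. **Classify** — decision tree, SVM (linear/polynomial/RBF), discriminant
   analysis, random forest, kNN (odd k 1–11), compared under leave-one-out
   cross-validation with fold-internal selection.
5. **Evaluate** — ordinal error `e = |û − u|`: accuracy, the error CDF,
   its normalized area NAuC (trapezoid over e ∈ [0,4], divided by 4), RMSE
   variants, and per-class recall/precision with Wald 95% confidence
   intervals.

## Worked example

Simulate 20 labelled recordings (4 per class), extract features, and score
a decision tree with the top-5 pairwise-selected features under LOOCV:

```sh
tremorscore simulate --class-counts 4,4,4,4,4 --seed 7 --out demo/
tremorscore features --in demo/ --out demo/features.csv
tremorscore train-eval --features demo/features.csv \
    --family decision_tree --selection pairwise --d 5
```

```
classifier: decision_tree  selection: pairwise
n recordings          : 20
accuracy              : 60.00%  (+/- 21.47)
P(e <= x), x = 0..4   : 0.6000  0.8000  0.9500  1.0000  1.0000
NAuC                  : 0.887
RMSE                  : rms=1.1180  rms_over_n=0.2500
```

60% of the 20 recordings get exactly the true score, 80% are within one
UPDRS point, and the NAuC of 0.887 summarizes how closely the error CDF
hugs a perfect classifier's (1.0). With only four recordings per class the
Wald interval on accuracy is wide (±21.5 points).

The packaged confusion matrix of the published wrist-worn scorer (131
recordings) reproduces its printed metrics exactly:

```sh
tremorscore report --confusion src/tremorscore/data/table5_confusion.txt
```

```
n recordings          : 131
accuracy              : 85.50%  (+/- 6.03)
P(e <= x), x = 0..4   : 0.8550  0.9924  1.0000  1.0000  1.0000
NAuC                  : 0.980
...
class 4: recall 0.000 (+/- 0.000), precision undefined
```

Precision of class 4 is *undefined* (never predicted), reported as such
rather than as 0 or NaN.

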