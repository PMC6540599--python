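# Methods

## The measurement model

`enosekit` targets campaigns in which a panel of samples, graded by an
independent chemical index (here the acid value, mg KOH/g), is measured
repeatedly on a 10-sensor MOS array at 1 Hz for 39 s. The package
never models sensor chemistry; it works on the recorded response
curves. Because no such campaign is bundled, the `synthetic` module
generates one with the structure the analysis assumes:

    x_s(t) = b_s + A[s, g] (1 − exp(−t / τ_s)) + ε_t,
    ε_t ~ N(0, (f · A[s, g])²) i.i.d. per time point,

a first-order exponential rise toward a sensor- and grade-specific
plateau. This is the simplest kinetics consistent with a step change
in volatile concentration at a heated MOS surface: a fast rise, a
plateau, no overshoot. The defaults are the campaign conditions the
analysis is designed for:

| parameter | default | meaning |
|---|---|---|
| `n_grades` × `replicates_per_grade` | 6 × 30 | panel design (180 measurements) |
| `n_timepoints`, `dt` | 39, 1 s | acquisition window t = 0..38 s |
| `baseline` b_s | 1.0 | pre-exposure response level |
| `tau` τ_s | 3–8 s across sensors | rise time constant; plateau effectively reached well before the steady-state window |
| `noise_sd_frac` f | 0.02 | replicate noise sd as a fraction of the plateau increment; keeps steady-state-mean RSD ≪ 5 % |
| `drift_per_s` | 0 (off) | optional linear drift term |

Two amplitude presets encode the two regimes of interest.
`paper_like` (the default) gives grades 1–5 closely spaced plateaus
(3 % increments of each sensor's base sensitivity) and a large grade-6
jump concentrated on the ammonia-analog sensor S9 (4× its base
sensitivity, vs 0.35× elsewhere) — spoiled samples flood the array with
ammonia/amines while fresh samples smell alike. `separable` spaces all
six grades so that every pairwise plateau gap exceeds five noise
standard deviations; it exists purely for design-controlled classifier
checks. The acid values of the six grades ride along as metadata and
never enter any computation.

What the generator deliberately omits: sensor drift and memory between
measurements, correlated (sample-level) replicate variation, humidity
and temperature effects, and non-exponential multi-phase kinetics.
Tests passing on this generator therefore validate the *pipeline
mathematics and its statistical conventions*, not instrument behaviour;
in particular real inter-grade accuracies will be lower than the
near-perfect values the clean presets produce.

## Preprocessing

Curves are smoothed with a five-point Savitzky–Golay filter before
feature extraction. The polynomial order is 2: the standard choice at
this window, exactly reproducing linear signals and applying interior
weights (−3, 12, 17, 12, −3)/35. Edges use mirror extension so output
length equals input length. Baseline handling defaults to `none`
(features consume raw levels, matching the integral feature's printed
definition as a plain sum); `initial` subtracts x₀ first and is exposed
as a config switch because the area-under-curve reading of the integral
feature ("area between curve and baseline") implies it.

Min-max normalization is applied to *feature columns*, not raw traces,
since the six features have incommensurate units. Constant columns map
to 0 with a logged warning. In any train/validation protocol the
bounds are fitted on the training part only and applied unchanged to
validation data (which may therefore fall outside [0, 1]); fitting on
pooled data would leak the validation distribution into training.

## Features

Six scalars per sensor, always emitted sensor-major in the fixed order
INV, WEV, MGV, ADV, RSAV, VARV (10 × 6 = 60 columns).

Numerical conventions worth recording:

* **WEV** uses PyWavelets' db3, level 4, `symmetric` (half-point) signal
  extension, and keeps only the approximation coefficients. Symmetric
  extension is load-bearing: it yields 7 approximation coefficients for
  a 39-point trace (periodization would yield 3), the count the feature
  dimensionality is built on. Decomposing a 39-point signal four
  levels exceeds the usual max-level heuristic; the coefficients are
  boundary-influenced but well defined, and the implementation is
  verified against a brute-force cascade (extend–convolve–decimate)
  oracle to 1e-9 relative. Traces shorter than the filter (6 points)
  are rejected.
* **MGV** takes the *first* maximum when tied, measures time from t = 0,
  and returns 0 when the maximum sits at the origin (avoids 0/0 on
  non-increasing curves).
* **RSAV** needs a window start t₀, which the protocol leaves open; the
  default t₀ = 29 s takes the final 10 of 39 samples, comfortably after
  the slowest default rise (τ = 8 s ⇒ 97 % of plateau at 29 s). It is
  configurable per call and through the pipeline config.
* **VARV** is the population variance (denominator n), per its printed
  formula; the repeatability RSD, by contrast, uses the sample standard
  deviation (n − 1), the convention for replicate precision. The
  protocol specifies neither denominator; these choices are recorded
  here and frozen in tests.
* **ADV** telescopes to (x_T − x_1)/((T−1)Δt); the implementation
  computes the mean of differences and the identity is property-tested.

## Chemometrics

**RSD** (repeatability): for one grade, each sensor's steady-state mean
is computed per replicate; RSD = 100 · sd / mean across replicates.
Raw (unsmoothed) traces are used — a 10-point mean is insensitive to
the smoother. Zero mean raises a degenerate-input error rather than
returning an infinity.

**PCA** consumes min-max normalized columns and centers them (the
normalization puts columns on [0, 1] but does not center). Components
come from a full singular value decomposition; explained-variance
ratios over all components sum to 1, and requesting more components
than the rank zero-pads the ratios. Signs are fixed by making each
component's largest-magnitude loading positive, so results are
reproducible across runs and row orders.

**LDA** uses Fisher's criterion (generalized eigenproblem of
between-class over within-class scatter, via scikit-learn's eigen
solver) and classifies by nearest class centroid in the discriminant
space; no centering is applied because nearest-centroid distances are
shift-invariant. Six grades yield exactly five discriminant
functions. A singular within-class scatter (collinear features)
triggers ridge shrinkage with a logged warning. Two scoring protocols
are offered: `resubstitution` (default — the convention when one
campaign is analysed in full, and the only protocol consistent with
accuracies reported without a hold-out) and `loo_cv` (honest
leave-one-out, refitting the scaler and model in every fold).
Resubstitution is optimistically biased — under permuted labels it
scores well above chance — so the permutation-null test uses `loo_cv`.

## Classifier benchmark

Each feature code's 10-sensor block is split once, stratified: 21 of 30
replicates per grade train (126 samples), 9 validate (54). The same
sample-index split is shared across feature blocks, as when physical
samples are assigned to splits once per campaign. Five classifiers run
per block: MLP (one hidden layer of 10 units, ≤1000 iterations), random
forest (100 trees), K-nearest-neighbours with K = 3 (the one printed
hyperparameter), RBF-SVM (C = 1, scale bandwidth heuristic) and
Gaussian naive Bayes — all seeded, all behind a train-fitted min-max
scaler. Training accuracy is resubstitution on the training split.
Single-split accuracies on 54 validation samples are high-variance
(±~5 % at the observed levels), hence the CLI's `--repeats` option to
average the grid over independent splits.

## Retention index

The Kovats index interpolates linearly between bracketing n-alkanes,
with left-closed brackets (T_Rn ≤ t < T_Rn+1, final rung included) so
RI(T_Rn) = 100n exactly. Times outside the ladder raise rather than
extrapolate. The formula assumes a single linear temperature ramp;
multi-ramp programs would need a different variant, which is out of
scope.

## Pipeline and reproducibility

`run_pipeline` validates the whole config before any work, stages
outputs in a `.partial` directory and renames it into place only on
success, so failed runs leave nothing behind. One global seed fans out
to per-stage seeds via CRC-32 hashing of the stage name, keeping stages
independently reproducible; all JSON is written with sorted keys and
full float precision, so identical configs produce byte-identical
numeric artifacts.

## Problem sizes

The bundled tests and the acceptance script run the full default
campaign (180 measurements × 10 sensors × 39 points), 20-seed split
averages for classifier comparisons, 200 label permutations for the
held-out chance baseline, and 80 permutations × 30 samples for the
leave-one-out LDA null — sizes at which every stochastic check has
comfortable margin while the whole suite stays inside a coffee break.

## Known limitations

* The synthetic generator's independent per-point noise makes
  steady-state features nearly noise-free (RSD ≈ 0.4 %), so absolute
  accuracies on the presets exceed what real campaigns report; only
  orderings and structural claims transfer.
* Resubstitution LDA accuracy is an optimistic estimate by
  construction; `loo_cv` is the honest figure.
* The wavelet energy of short traces is boundary-dominated; it is a
  reproducible fingerprint, not an interpretable spectral energy.
* No drift correction or environmental compensation is implemented.
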