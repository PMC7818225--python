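# Methods

`erprep` implements a mass-univariate analysis of how event-related
potentials (ERPs) change over repeated presentations of the same visual
object, together with a synthetic data generator that emulates the kind of
study the analysis was designed for: 17 subjects, 4 blocks of 60 objects,
each object shown 6 times in immediate succession (570 ms onset asynchrony),
61 scalp channels sampled at 500 Hz.

## The statistical model

### First level

For each subject, preprocessing yields 24 condition-mean ERPs (6
presentation indices x 4 blocks). Each mean ERP is flattened into a
sequence of 32 x 32 scalp maps — one per sample of the 50–500 ms
post-stimulus window, 226 frames at 500 Hz — and the stack is smoothed with
a [16 mm, 16 mm, 16 ms] FWHM Gaussian kernel, giving one scalp x time
*volume* per condition. At every voxel, the 24 condition values are modeled
by a GLM with 8 columns,

    Y = X b + e,   X = [block indicators (4) | block-specific modulators (4)],

where the modulator for block j is a mean-centered repetition trajectory
g(r), r = 1..6, hypothesizing how amplitude evolves over presentations:

| model        | g(r)                | interpretation                      |
|--------------|---------------------|-------------------------------------|
| exponential  | exp(-(r-1)/tau)     | decay saturating over repetitions   |
| linear       | 6-r (unit steps)    | constant decrement ("null" model)   |
| chdet        | 1{r=1}              | change detection: only the first    |
|              |                     | presentation differs                |

Modulators are centered within block, which also makes them orthogonal to
their block indicator. Because the trajectories decrease, suppression of a
positive component loads *positively* on the modulator. tau defaults to 1
presentation and is exposed in the config; the reported fits record it.

### Second level

The 4 block modulator betas are averaged per subject ("pooled"), and the 17
pooled maps enter a voxelwise one-sample test: F = t² with df (1, 16). The
equivalent Z is the standard-normal deviate with the same upper-tail
probability as the F value, computed through the regularized incomplete
beta function so that tail probabilities of 1e-7 and beyond remain accurate.

Family-wise error control is voxel-level random field theory: the
F threshold is the value at which the expected Euler characteristic (EC) of
the excursion set equals alpha = 0.05. Expected EC is the dot product of
the EC densities of an F field (orders 0–3) with the resel counts of the
masked search lattice (points/edges/faces/cubes converted by the per-axis
smoothness, so edge and face resels are included). Smoothness is estimated
from the group-model residuals, standardized per voxel, via
FWHM_axis = sqrt(4 ln 2 / var(forward difference)) — estimated at the group
level, matching the summary-statistics hierarchy actually tested.
Suprathreshold voxels are reported as 26-connected clusters, up to three
peaks per cluster separated by at least 8 mm or 8 ms, each with latency,
voxel-level FWE p (expected EC at the peak F), F and equivalent Z, sorted
by cluster size.

Numerical notes. The expected-EC curve is not monotone in F (the
third-order density is negative at low thresholds for df1 = 1), so the
threshold search brackets the *rightmost* crossing of alpha and bisects to
1e-6. The third-order EC density of an F(1, v) field only decays for
v > 3, so a finite voxel-level threshold requires at least 5 subjects; the
code raises a clear error below that. At exactly df1 + df2 = 3 the density
formula is a finite 0 x Gamma(0) limit, evaluated by an epsilon
perturbation.

### Model comparison

Per voxel and subject, the Bayesian information criterion approximates the
log model evidence, LME = -(n/2) ln(RSS/n) - (k/2) ln(n) with n = 24 data
points and k = 8 parameters (the parameter count of the regression columns;
the error variance is not counted). Since k is identical across the three
models, any LME difference reduces to an RSS ratio:
dLME = (n/2) ln(RSS_B/RSS_A). Summing dLME over subjects gives the log
group Bayes factor (fixed-effects group comparison). Comparisons are
summarized inside a functional mask — the intersection ("all") of the three
models' significant-voxel masks by default, with "any" available as a flag,
since both readings of the original procedure exist — and over the whole
volume, by median/mean/SD, percent of voxels > 0, a one-sample
Kolmogorov–Smirnov test against the standard normal (no parameter
estimation; this fixed reference is what makes D = 1 attainable for a
far-shifted sample), and a Wilcoxon signed-rank test (normal approximation,
tie-corrected variance, no continuity correction). |dLME| > 5 is labeled
very strong evidence, 3–5 strong, 1–3 positive, below that weak.

## Scalp geometry

Electrode positions are the idealized spherical easycap 10-20 layout
(exact unit sphere, Cz at the vertex, exact left/right symmetry).
Flattening is azimuthal-equidistant about the vertex — arc distance from Cz
becomes the radial coordinate — followed by one uniform scale placing the
outermost electrode one pixel inside the 32 x 32 grid. The grid's physical
pitch is fixed at 4.25 mm/pixel (32 pixels ~ a flattened 85 mm head); this
scale converts the mm smoothing FWHM to pixels and is a config field, since
any such flattening must pick a scale. Scalp maps are barycentric-linear
interpolations on the Delaunay triangulation of the projected electrodes:
exact for affine fields, local, and NaN outside the convex hull (no
extrapolated voxels; out-of-hull pixels are excluded from all statistics).
Smoothing is separable Gaussian convolution with sigma = FWHM/sqrt(8 ln 2)
per axis, mask-normalized so every output value is a convex combination of
in-mask inputs and the NaN pattern never changes.

## Preprocessing

Order: exclusion of trials within 800 ms after a distractor-task target ->
1–30 Hz band-pass -> common-average re-reference (scalp channels only; the
4 EOG channels are never referenced or interpolated) -> baseline correction
to the -100–0 ms mean -> rejection of any trial exceeding +/-75 uV on any
EEG or EOG channel -> per-cell averaging. The 24 dB/octave roll-off is a
4th-order Butterworth; it is applied forward-backward (zero-phase) to avoid
latency shifts in the early 86–140 ms window, which doubles the magnitude
roll-off — the filter tests check the measured attenuation against the
squared analytic Butterworth response rather than a nominal slope. Epochs
are reflection-padded by 1 s before filtering, so the 1 Hz high-pass
transient dies inside the padding. Rejection operates on post-filter,
post-baseline values; the choice is recorded in the output metadata.

## The synthetic generator

Every trial is a fixed base waveform (posterior P1 ~100 ms, N1 ~160 ms,
P2 ~220 ms, Gaussian bumps with broad posterior topographies) plus
ground-truth repetition effects plus noise. An effect is
(-sign) * A_s * g(r) * w(channel) * env(t): a per-subject amplitude A_s ~
Normal(A, subject_sd²) truncated at zero, the repetition profile g(r), a
Gaussian spatial footprint of given FWHM around a center electrode on the
projected scalp, and a time-window envelope with 8 ms raised-cosine ramps.
sign = -1 injects a positive component that decays over repetitions
(repetition suppression); sign = +1 yields measured amplitudes that grow
(enhancement) — after mean-centering both conventions project on the
modulator identically up to sign. Noise is white Gaussian, mixed across
scalp channels by the Cholesky factor of exp(-arc distance / 65 mm),
band-limited to 1–30 Hz, and rescaled so the per-channel SD equals the
configured value (the filter's variance gain is computed from its frequency
response); EOG channels get independent noise at twice the SD. Everything
is deterministic given (seed, subject id); subject streams are spawned
independently from the dataset seed.

The four default effects mirror the repetition phenomenology the pipeline
targets: occipital suppression at 86–140 ms, midline-occipital enhancement
at 320–340 ms, right temporoparietal suppression at 322–360 ms, and right
frontotemporal suppression at 400–446 ms, all with exponential dynamics
(tau = 1). Real studies do not report these effects in uV, so the
amplitudes (2.6 / 3.0 / 2.6 / 3.0 uV at presentation 1), trial noise
(2.0 uV rms in band), spatial correlation length (65 mm) and
between-subject SD (1.2 uV) are free parameters of the generator. They were
calibrated once, before the validation suite was frozen, so that (i) every
ground-truth region clears the FWE threshold in a full-design run, (ii)
group peak F statistics land in the tens-to-low-hundreds — the regime of
published group repetition contrasts — and (iii) model and amplitude
recovery are decisive rather than marginal at footprint-edge voxels. One
caveat the calibration exposed: white-through-exponential-kernel channel
noise yields scalp fields rougher than real volume-conducted EEG, so the
synthetic resel count is higher and the FWE threshold (~45) is stricter
than thresholds typical of real data (~30); peak F values sit
correspondingly higher.

What the generator does *not* emulate: overlapping responses from the
570 ms stimulus train (epochs are generated independently, so no residual
activity from the previous trial leaks into the baseline), viewing-angle
change trials, non-stationary noise, drifting electrode impedances, eye
movements correlated with stimuli, or realistic single-trial amplitude
variability beyond additive noise. Passing recovery tests therefore show
the *estimator chain* is correct and well-calibrated under the stated
generative model, not that real data meet its assumptions.

## Validation studies (problem sizes)

The package's own qualification experiments (`erprep.validation`) scale the
design down to keep the full suite fast while preserving the quantities
under test:

* **FWE null study** — 100 runs, 17 smooth Gaussian null volumes on a
  16 x 16 x 64 grid (kernel FWHM 3 voxels, generated with padding so edge
  variance is not depleted); family-wise false-positive rate at alpha=0.05
  must lie in [0, 0.11] (RFT is conservative by construction at high
  smoothness and low df).
* **Model recovery** — 20 datasets with exponential ground truth and 10
  with categorical truth, each 17 subjects, 6 objects per block at 250 Hz,
  trial noise scaled by sqrt(6/60) so condition-cell SNR equals the full
  design's; no distractor-target events (with 6 trials per cell the 800 ms
  exclusion could empty a cell). The generating model must win the group
  Bayes factor in >= 95 % (exponential) / >= 90 % (categorical) of
  ground-truth effect voxels, pooled over datasets.
* **Amplitude recovery** — a spatially uniform, temporally flat effect is
  passed through averaging -> interpolation -> smoothing -> GLM (no filter
  or re-reference: a spatially uniform signal is annihilated by the common
  average, and a near-DC plateau by the 1 Hz high-pass, so those stages are
  deliberately outside this particular chain — they are validated
  separately). Noise-free, the modulator beta must equal the injected
  amplitude to 1e-6; at default cell-level noise the group-mean beta must
  stay within 10 % over 20 runs. For spatially localized effects the
  measurement operator itself attenuates amplitude (common-average ghost,
  interpolation, smoothing), which is why the exact-recovery statement uses
  the uniform effect.
* **Sensitivity** — one full-design dataset (60 objects, 500 Hz, artifacts
  injected and rejected); every ground-truth region must overlap a
  significant cluster of the exponential model.

## Known limitations

* Voxel-level FWE only; no cluster-extent p-values or small-volume
  correction.
* Fixed-effects model comparison (log group Bayes factor); no
  random-effects model selection across subjects.
* The exponential regressor is defined over presentation index, not time;
  tau is a config parameter, not an estimated quantity.
* The scalp flattening scale is a convention (4.25 mm/pixel); quantities
  quoted in mm depend on it and the configurable head radius.
* With fewer than 5 subjects no finite voxel-level RFT threshold exists for
  the one-sample F field (heavy tails); the group stage refuses rather than
  fabricating a threshold.
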