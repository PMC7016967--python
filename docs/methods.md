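# Methods

This note documents the models, estimators and numerical choices behind
`driversense`, including the places where the underlying method description
leaves the design genuinely open and this package had to pin a convention.

## Signals and trials

A recording bundles synchronized streams: 14-channel EEG at 128 Hz on the
consumer-headset montage (AF3, AF4, F3, F4, F7, F8, FC5, FC6, T7, T8, P7,
P8, O1, O2), single-channel PPG and GSR at 51.2 Hz, and 49-point facial
landmarks at 30 fps.  Trials are labelled time slices; incident trials are
exactly 2 s.  Slice lengths use round-half-away-from-zero on duration ×
rate, pinned because 2 s at 51.2 Hz is 102.4 samples (→ 102).  Time is
seconds from recording start; frames are 0-indexed.  All on-disk formats
are plain text (CSV signal/landmark tables, JSON manifests); reads use
round-trip float parsing so write→read is exact to the last ulp.

## EEG features

**Preprocessing.**  Zero-phase (forward–backward) 4th-order Butterworth
band-pass, 4–45 Hz by default (theta through low gamma).  A simple
amplitude-threshold artifact rejection is provided (per-channel |z| >
threshold, flagged spans repaired by linear interpolation); it is a
lightweight cleaning step, not a subspace-reconstruction method.

**Conditional entropy.**  For electrode pair (X, Y), entropies come from a
joint equal-width histogram over each channel's observed range (16 bins per
axis by default, configurable), in bits, with 0·log 0 := 0:
H computed for both marginals and the joint, I = H(X) + H(Y) − H(X,Y),
H(Y|X) = H(X,Y) − H(X), so the identity I = H(Y) − H(Y|X) holds exactly.
The plug-in estimator is biased upward by roughly bins²/(2 n ln 2); tests
hold the permutation-null mean under three times that bound.  One feature
per unordered pair gives C(14,2) = 91; since H(Y|X) ≠ H(X|Y), Y is pinned
to the later channel in the canonical electrode order.  (Published feature
counts for this construction are internally inconsistent — 91 vs 96; this
package implements the combinatorially consistent 91.)

**Band-PSD topomaps.**  Per channel, mean in-band PSD for theta (4–7 Hz),
alpha (7–13 Hz) and beta (13–30 Hz): Welch with 1 s Hann windows and 50%
overlap for windows ≥ 1 s, a zero-padded periodogram below that (sub-second
windows arise in the 30-images-per-second incident sequences, where the
window is a handful of samples and the padded spectrum is a smooth
interpolation).  Electrode positions are the azimuthal-equidistant
projection of the standard 10–20 sphere onto the unit disc (outermost
electrode at radius 0.82).  Scattered channel values are
inverse-distance-weighted (power 2) onto a 32×32 disc grid, bicubic-resized
to 224×224, and each band image is normalized by its own maximum.  The
three bands occupy the red/green/blue channels and are alpha-blended with
weights w_b = Σ_channels PSD_b / max_b Σ_channels PSD_b, clipped to [0, 1],
zero outside the head disc.  Consequences worth knowing: the image is
invariant to a common positive scaling of all three band vectors, a silent
band yields an exactly-zero color channel, and the *relative* band powers
live in the channel weights while topography lives within each channel.
The blending formula and the off-hull extrapolation behavior are
package conventions (the originals are not specified); both are
configurable.

## PPG and GSR

PPG: centered moving average (0.25 s window, shrinking at the edges),
min-max scaling to [0, 1], then peak detection: local maxima above an
adaptive threshold (0.5 × rolling 90th-percentile over 10 s, configurable —
the referenced detector's internals are not published) with a 0.5 s
refractory distance keeping the taller of any conflicting pair.  Heart rate
is peaks × 60 / duration; pNN50 is the fraction of successive RR
differences exceeding 50 ms (reported as a fraction, not %).  The six
statistical descriptors are: mean, std, mean |Δx|, the same on the
standardized signal, mean |Δ²x|, and the same standardized — the classic
difference-signal set; for a zero-variance signal the standardized entries
are 0 with a warning rather than a division failure.

GSR: same smoothing; SCR peaks are detected by prominence (≥ 0.05 µS,
1 s separation) and their height measured peak minus preceding trough, so
the tonic skin-conductance level cancels and only the phasic response is
counted; the remaining six statistics describe the tonic profile.

Spectrograms: Hann STFT (symmetric window — chosen so that time reversal
exactly reverses the column layout), 4 s windows with 75% overlap, rows
cropped to 0–5 Hz (PPG) or 0–2 Hz (GSR), log10(magnitude + 1e−8), min-max
normalized, mapped through a perceptually-uniform colormap (viridis;
bit-exact colormap identity is irrelevant because the image feeds an
embedder, not a reader), and bicubic-resized to 224×224.

## Face features

The 30-feature geometric list (22 distances + 8 angles on the 49-point
layout) is a **reconstruction**: the published description names only
example measurements (brow-center to eye midpoint, nose to lower-lip
corners, brow-center to brow-center, and angles between such segments), so
this package fixes a concrete list preserving that structure and left/right
symmetry; it is defined in one place (`face.FEATURE_SPECS`) and tested for
invariances and counts rather than specific values.  Horizontal distances
are normalized by face-box width, vertical by height, oblique by the
diagonal; angles are radians and scale-free.  A degenerate angle
(coincident points) maps to 0 with a warning.  Per-trial aggregation is
column-wise mean, 95th percentile (linear-interpolation quantile,
pinned for cross-language reproducibility) and sample (n−1) standard
deviation — hence the two-frame minimum — giving 90 values from 30
geometric columns and 12288 from a 4096-wide embedding matrix.

Face detection and landmark localization are consumed as input, not
performed.  For synthetic end-to-end runs a deterministic rasterizer
(`face.render_face`) turns a landmark frame into a synthetic blob image so
the deep-face route can execute; it does not pretend to be a photograph.

## Image embedding

All image routes share one contract: 224×224×3 floats in [0, 1] → 4096
finite values.  The deterministic `StubEmbedder` is a 7×7 average pool,
a fixed seeded N(0, 1/d) projection to 4096 dims, and half-wave
rectification — linear + ReLU, hence Lipschitz with constant ‖W‖₂/49 per
pixel.  Pretrained VGG-16 / VGG-Faces penultimate-layer backbones
("the entire penultimate layer", no feature selection) are supported when
torch and weights are present, with the standard per-channel input
normalization applied only for CNN backbones; without them the factory
fails loudly and names the stub.  Backbone choice never changes downstream
shapes.

## Classification and evaluation

**ELM.**  Hidden layer H = tribas(X·Wᵀ + b), tribas(u) = max(1 − |u|, 0),
with W, b drawn once uniform on [−1, 1] from the seed and frozen; output
weights solve (HᵀH + λI)β = Hᵀy with λ = 1e−6 (neither the initialization
nor the solver is prescribed by the source method; these are recorded
package choices).  Labels are encoded ±1 with high-attention/hazardous as
+1; a decision score of exactly 0 goes to the positive class.  Features
are PCA-reduced (30 components) and *then* min-max normalized to [−1, 1] —
this order matters: tribas is dead outside |u| ≤ 1, and unnormalized
principal coordinates saturate it.

**LSTM.**  Two stacked layers (200, 100 units), many-to-one logistic
readout from the final step, trained by SGD with momentum (defaults:
learning rate 0.01, momentum 0.9, 50 epochs, batch 16, forget-gate bias
init 1).  Implemented in NumPy with full backpropagation through time;
pure-NumPy training under a fixed seed is bit-deterministic.  Sequences
must share one length (sequence classification requires fixed-duration
trials); per-step features are PCA-reduced to 60 by default.  The
hyperparameters are package defaults — the source method fixes only the
architecture and optimizer family.

**LOSO CV.**  One fold per subject: PCA and the scaler are fit on the
training subjects only by default (leakage-safe); `scaler_scope="global"`
(CLI `--paper-faithful`) restores fitting across all subjects, the simpler
protocol at the cost of using the held-out subject's range.  Accuracy and
rank-based AUC (ties ½) are collected per subject and summarized as
mean ± std; AUC is per-subject-averaged, not pooled (a pinned convention —
either reading is defensible).  A fold whose test labels are single-class
gets an undefined (NaN) AUC and is excluded from the AUC mean.  The
reported p-value is a two-sided one-sample t-test of per-subject accuracies
against chance (0.5); pairwise modality comparisons use the paired t-test,
and multi-group comparisons one-way ANOVA, both via standard library
routines with degenerate inputs (zero-variance differences) reported as
p = 1 with a warning.

## Synthetic data

The generator reproduces the statistical structure the pipeline assumes at
the emulated cohort scale — 12 subjects, 35 attention trials each (420
total), 70 two-second incidents each (30 hazardous) — not the biophysics:

* EEG: per-channel 1/f background plus shared narrowband theta/alpha/beta
  oscillations with fixed scalp profiles (alpha occipital, beta frontal),
  giving realistic inter-channel correlation; positive-class trials scale
  alpha amplitude by e^(−0.6·effect·g) and beta by e^(+0.6·effect·g) with
  a per-subject lognormal gain g (σ = 0.2) and 15% per-trial amplitude
  jitter.  At effect 1 the beta/alpha power ratio alone separates classes
  with AUC > 0.9; at effect 0 the classes are distributionally identical.
* PPG: pulse train (Gaussian systolic peak, dicrotic bump at +0.25 s,
  baseline wander) with RR jitter of configurable scale; attention raises
  heart rate by 8 bpm·effect and damps RR variability.  An alternating
  ±jitter mode makes every successive RR difference exactly twice the
  jitter, pinning pNN50 at 0 or 1 by construction for tests.
* GSR: tonic drift plus Poisson-timed SCRs (0.7 s linear rise, 2.5 s
  exponential decay, lognormal amplitudes around 0.3 µS); attention adds
  2·effect SCRs/min.
* Landmarks: a canonical symmetric 49-point face in a 200×240 box with a
  smooth brow-raise / mouth-open oscillation whose amplitude grows with
  the effect for positive-class trials, plus 0.5 px frame jitter.

Attention trials default to 14 s — the lower end of the 14–105 s range the
emulated protocol spans — which keeps full-cohort synthesis and extraction
comfortable on one core.  One global seed fans out through
`SeedSequence(seed, spawn_key=(subject, task, trial, modality))`, so any
trial regenerates in isolation and identical configs give identical bytes.
Samples are synthesized lazily per trial; a full-cohort iteration never
holds more than one trial in memory.

What passing tests on this generator do **not** show: robustness to real
EEG artifacts (eye blinks, line noise), PPG morphology variation, sensor
drop-outs, landmark-tracker failures, or within-class nonstationarity.
The recovery results are a correctness check of the pipeline under its own
assumptions, not a claim about real recordings.

## Problem sizes used in the shipped runs

The acceptance script runs the four single-modality attention pipelines and
both incident pipelines at the full emulated scale (420 attention trials,
840 incident trials); the LSTM sequence route runs on a reduced cohort
(4 subjects × 10 incidents, 60-step sequences) — the sequence route's cost
is dominated by per-window embedding and per-fold PCA, and the reduced
cohort already exercises every code path while keeping the whole script in
the minutes range on one core.  The effect-free control reruns the EEG
route with the attention effect at exactly 0.

## Known limitations

* The 30-feature geometric list is a reconstruction (see above); absolute
  feature values are package-specific even though counts and invariances
  are not.
* The stub embedder is linear-then-rectified; it preserves linearly-decodable
  image structure but has none of a CNN's invariances, so absolute
  accuracies through the deep routes are not comparable to CNN-backed runs.
* pNN50 needs at least two RR intervals, i.e. three detected beats; very
  short or very noisy PPG windows fall back to 0 in the pipeline vector.
* The LSTM is CPU-bound NumPy; it is meant for the cohort scales used
  here, not for large datasets.
* The histogram MI estimator's upward bias grows as bins²/n; with the
  default 16 bins, trials shorter than ~2 s at 128 Hz leave few samples
  per bin and the conditional-entropy features get noisy.
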