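# Methods

## Overview

`eegspect` implements a screening pipeline that turns multi-channel EEG
into per-channel time-frequency images and classifies them into a binary
case/control decision (the positive class is labeled ASD throughout). The
chain is:

1. **Preprocessing** — common average reference (CAR), order-4 Butterworth
   low-pass at 40 Hz applied forward-backward (zero phase), per-channel
   amplitude normalization to [-1, 1], segmentation into non-overlapping
   3.5-s single-channel windows (896 samples at 256 Hz).
2. **Spectrogram imaging** — magnitude STFT of each segment, cropped to
   0-50 Hz, peak-referenced dB mapping over an 80 dB range, rendered as an
   8-bit grayscale raster (default 128x128).
3. **Classical path** — tCENTRIST texture features (local ternary patterns
   in a census-histogram scheme over a 21-block spatial pyramid), PCA to a
   0.95 retained-variance target, and a six-classifier bank (Gaussian NB,
   LDA, random forest, kNN with k = 9, logistic regression, linear SVM)
   under stratified ten-fold cross-validation.
4. **Deep path** — three small CNNs trained on the raw images with a
   stratified 70/15/15 train/validation/test split.
5. **Synthetic cohorts** — a seeded generator of labeled multi-channel
   recordings that makes the whole chain testable without clinical data.

## Preprocessing choices

The cleaning chain's order is CAR -> filter -> normalize -> segment. CAR
subtracts the instantaneous across-channel mean, so the output sums to
zero over channels at every sample and the operation is idempotent. The
IIR family and order are open choices; an order-4 Butterworth is the
standard flat-passband pick, and forward-backward application avoids
phase-shifting segment boundaries at the cost of squaring the magnitude
response (the analytic power gain is exposed as `lowpass_gain`; at 256 Hz
it is >= 0.99 at DC and <= 0.01 at 60 Hz). Normalization is per channel
over the whole recording, not per segment, so relative amplitude structure
across a channel's segments survives. A trailing partial window is
dropped; a recording shorter than one window yields an empty segment list
with a warning rather than an error.

## Spectrogram rendering

STFT frames are consecutive windows without padding, so the frame count is
`floor((N - window)/hop) + 1`. The default geometry is a 64-sample Hann
window with hop 16 and a 128-point FFT: at 256 Hz that is a 0.25-s window,
2 Hz bins and 52 frames per segment. The short window is a deliberate
design decision: census/LTP texture descriptors live on local contrast, and
a 1-s window leaves only 6 frames per 3.5-s segment — once stretched to a
128-wide image the time axis is essentially featureless, and measured
end-to-end accuracy on the separable synthetic cohort dropped from the
90s to around 80% with classifier-independent scores (the bottleneck was
the features, not the model). 2 Hz resolution still separates the
classical EEG bands.

dB mapping is referenced to the per-image peak over an 80 dB range, which
makes the rendered image invariant to segment amplitude scaling; an
all-zero magnitude matrix renders as an all-black image by policy. Row 0
carries the highest displayed frequency. Resizing is bilinear;
equal-magnitude order within a column is preserved (monotone mapping).

## tCENTRIST

For each interior pixel, neighbors are compared with a dead band of +-t
(default t = 5 on the 0-255 scale, the standard LTP setting): bit i of the
*upper* code is set when neighbor_i >= center + t, of the *lower* code when
neighbor_i <= center - t. Bit order is frozen (top-left, top, top-right,
right, bottom-right, bottom, bottom-left, left -> bits 0..7); any fixed
order is valid, this one is pinned for bit-for-bit reproducibility. Ties
at the band edges fall on the >=/<= side. Code maps cover interior pixels
only ((H-2)x(W-2), no padding). The spatial pyramid is the non-overlapping
1+4+16 = 21-block tiling (division remainders absorbed by the last block
row/column); each block contributes two 256-bin histograms (upper, lower),
each L1-normalized so features are independent of block size. Default
feature length: 512 x 21 = 10752. The descriptor is invariant to global
additive intensity shifts; at t = 0 the upper map degenerates to the plain
census (LBP ">=") transform.

## Classical learning path

PCA is fitted inside each training fold only and both fold portions are
transformed with it; pooling test predictions never touches test-fitted
statistics (a label-revealing column injected into test items only leaves
CV accuracy bit-identical — the leakage canary in the test suite). The
retained-variance target is 0.95. Inside `cross_validate` the computed
basis is capped at 256 components (randomized SVD) so ten-fold CV on
10752-dim features stays tractable on one CPU; on these features ~65
components already reach the 0.95 target, so the cap is inactive in
practice and is a numerical ceiling, not a modeling choice.

Classifier defaults are frozen and overridable: Gaussian NB; LDA with the
SVD solver (pseudo-inverse handling of singular covariance, the
"pseudolinear" variant); random forest with 100 trees; kNN with k = 9 and
Euclidean distance; L2-penalized logistic regression; linear-kernel SVM
with C = 1. Continuous scores for ROC are decision values where available,
else class-1 posteriors.

Folds are stratified at the image level by default with a fixed seed. The
headline metrics pool per-fold confusion counts; per-fold metrics are kept
alongside. Sensitivity, specificity and accuracy are percentages; F1 and
AUC are on 0-1. A metric with a zero denominator is reported as `None`,
never silently 0. AUC is the trapezoid under the empirical ROC with
midrank tie handling, equal to the normalized Mann-Whitney statistic.

**Image-level vs subject-level splitting.** Images from one subject are
correlated; with image-level folds the same subject appears in training
and test folds, so a classifier can exploit subject identity. On the null
synthetic cohort (no class signal at all) image-level ten-fold SVM reaches
~56% — significantly above chance — purely by subject memorization, while
subject-grouped folds sit at chance. Both grouping modes are provided; the
no-signal guarantees in the test suite are asserted under subject grouping
because that is the question they ask ("does the pipeline invent *class*
signal?"), and the image-level inflation is documented as the leakage
caveat it is. Under subject-grouped folds on null data, accuracy often
lands *below* chance: the classifier fits held-in subjects'
idiosyncrasies, which anti-generalize to held-out subjects. The no-signal
bound is one-sided for exactly this reason.

## CNN path

Three frozen presets (all 3x3 same-padding ReLU convolutions, 2x2 max
pools, 2-class softmax head):

* **Model 1**: conv16-pool-conv32-pool-conv64-pool-flatten-dense512(ReLU)-dense2.
* **Model 2**: model 1 plus dropout 0.2 after the last pool.
* **Model 3**: conv32-pool-conv32-pool-drop0.25-conv64-pool-conv64-pool-
  drop0.25-flatten-dense256(ReLU)-drop0.5-dense2.

The layer engine (convolution via patch-matrix multiplication,
hand-derived backpropagation, Adam) is implemented in numpy inside the
package and is verified against central finite differences in the test
suite. Training uses softmax cross-entropy, Adam at 1e-3, pixel inputs
scaled to [0, 1] and then centered by the training-set mean (the offset is
stored on the model as fitted state; without centering, the bright
uncentered spectrograms pin the early loss at chance level long enough to
exhaust a short epoch budget), batch size 64 by default (32-256
supported), and a
stratified seeded 70/15/15 split with an optional subject-wise mode. One
master seed fixes split, initialization, dropout masks and shuffling, so
runs are reproducible on a fixed thread configuration. Training aborts on
non-finite loss. No augmentation and no class weighting by default.

## Synthetic cohorts

Each channel is a sum of band-limited Gaussian noise processes (delta
1-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-45 Hz; order-4
Butterworth band-pass of white noise, unit RMS, scaled by the band
amplitude) plus pink 1/f background (RMS 0.5). Subjects carry log-normal
band random effects (log-sd 0.1) and channels a 5% gain jitter, so subject
identity is a genuine latent variable. Geometry defaults mirror a
16-channel, 256 Hz session.

The **separable** preset gives the case class alpha 0.5 / theta 1.2
against the control's alpha 1.0 / theta 0.8 (delta 1.0, beta 0.6, gamma
0.3 for both) — a factor-2 alpha difference chosen to be clearly
detectable through the image pipeline. The direction (reduced alpha,
raised theta in cases) is a generator convention that creates signal
inside the displayed 0-50 Hz band; it claims nothing about real autism
electrophysiology. The **null** preset draws both classes from the control
parameters.

What the generator does *not* emulate: eye-blink/muscle artifacts,
nonstationarity beyond random gains, volume-conduction correlation
structure between channels, or realistic class overlap. Passing the
end-to-end checks therefore shows the pipeline recovers a planted spectral
difference and invents none where absent — not that comparable accuracy
would be reached on clinical recordings.

## Problem sizes and protocol choices in the checks

The end-to-end classical check runs 10+10 subjects x 60 s (5440 images,
ten-fold SVM: ~94% pooled accuracy, AUC ~0.99); its null counterpart runs
10+10 x 21 s under subject-grouped folds and must stay within three
binomial standard deviations of the majority rate. The CNN check runs
model 3 on 8+8 subjects x 35 s at 64x64 pixels, batch 64, at most 15
epochs (early-stopped once validation accuracy reaches 0.97); its null
counterpart uses a smaller cohort and fewer epochs — training longer on
label-free data cannot create held-out signal, so the shorter protocol
tests the same property at a fraction of the cost. `scripts/acceptance.py`
re-runs the same experiments at moderately smaller cohort sizes and
records each problem size in its output.

## EDF support

Recordings are read through MNE. Written EDF files use a minimal
16-bit writer implemented in `io.py` (ASCII header, one-second records,
symmetric physical range covering the data peak), so a write/read round
trip is exact up to the digitization step; the round-trip test drives the
package's writer against MNE's independent reader.

## Known limitations

* The CNN engine is single-threaded numpy; it is sized for the small
  presets here, not for large-scale training.
* The 31-block overlapping CENTRIST pyramid variant is not implemented;
  the pyramid is the non-overlapping 21-block tiling.
* EDF writing supports integer sampling rates and one data-record layout.
* Classical-path memory scales with cohort size x 10752 features; cohorts
  of tens of subjects fit comfortably, thousands would not.
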