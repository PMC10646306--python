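# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic data does and does not emulate,
and the numerical and design choices made where the design was open.

## Signal model of the synthetic recordings

A recording is simulated per participant as

    x_c(t) = Σ_events s_c(t − t_event; labels) + n_c(t) + b_c(t)

* **Evoked components** `s_c`: each planted effect is a Gaussian temporal
  bump (default sd 15 ms; the planted-recovery fixture uses sd 5 ms so the
  component's energy stays inside its nominal latency window) of a given
  amplitude (µV) added on a set of montage channels, optionally with
  per-channel weights, whenever the presented stimulus matches the
  effect's label. Category signatures are *latency-coded*: class *i*'s
  bump is centered at one of *n* latencies spread across the window, all
  with the same polarity and the same (uniform) scalp pattern.
* **Background** `n_c`: independent per-channel 1/f^α Gaussian noise
  (default α = 1, sd 10 µV — typical ongoing-EEG magnitude).
* **Blinks** `b_c`: biphasic 400-ms transients at a Poisson rate (default
  5/min, 150 µV) scaled by a frontal-dominant topography (maximal at
  Fp1/Fp2, decaying toward posterior sites); onset samples are returned so
  tests can verify removal.

Stimuli appear once per session in seeded random order at a fixed 1,250-ms
onset-to-onset interval (500 ms stimulus + ~750 ms blank); jitter is
available but off by default so oracle indexing stays exact.

Surrogate stimuli are phase-randomized noise images whose radial amplitude
spectrum follows a per-category power-law slope (slopes spread over
[−2.8, −1.2] across categories) with a category-specific orientation-energy
bias, so both the roughness label (slope binarized at the set median) and
the oriented-energy statistics are class-informative by construction.

**What this does not emulate:** volume conduction and correlated-across-
channel background activity, eye movements beyond blinks, session
non-stationarity, electrode impedance drift, and photorealistic scene
content. Passing tests demonstrate that the pipeline recovers structure it
is built to recover; they do not certify effect sizes on real recordings.

### Why the planted signatures are latency-coded and same-polarity

Two interactions discovered while building the recovery fixture are worth
recording because they are properties of the method, not bugs:

1. **Global-average-pooled gradients cancel anti-symmetric patterns.** A
   signature of the form +O1/−O2 survives common-average re-referencing,
   but the class gradient is positive at O1 cells and negative at O2
   cells, so the Grad-CAM weights (a global average of the gradient)
   cancel to ≈0 and the map is blind to the component even when the
   classifier separates the classes perfectly.
2. **Classes that use the same cells with opposite polarity invert the
   map.** With ±bump class pairs, the out-of-window gradient field that
   the temporal convolutions spread around the informative region
   anti-aligns with the in-window pattern; the globally averaged weights
   then make the map *negative* (hence, after ReLU, zero) exactly at the
   informative cells.

Latency-coded, same-polarity signatures avoid both failure modes and are
the fixture default.

## Preprocessing

Default chain on continuous data: average re-reference → 0.5–40 Hz
band-pass (4th-order Butterworth, zero-phase via forward–backward
filtering) → ocular ICA → epoch (−400…+800 ms, onset at index 400) →
baseline correction (half-open −100…0 ms window) → ±75 µV rejection
(strict exceedance; exactly ±75 µV is retained). The chain order is a
config list and is logged with every run.

Ocular removal is FastICA on the continuous channels × time matrix (the
component count capped at the matrix rank, which average re-referencing
reduces to 18); a component is removed iff its absolute mixing weight is
maximal on Fp1/Fp2 **and** the magnitude of its time course correlates at
|r| ≥ 0.7 (configurable) with the smoothed Fp1/Fp2 amplitude envelope.
The montage has no EOG channel, so this frontal-envelope proxy is the
package's stated rule.

The synthetic smoke configuration omits the re-reference stage: surrogate
recordings are generated reference-free (there is no reference-electrode
signal to remove), and re-referencing would superimpose −2/19 of any
planted uniform-pattern component onto every other channel — a real,
class-informative signal that the classifier then legitimately uses and
the attribution legitimately highlights, defeating the purpose of a
localized ground-truth fixture. Real recordings keep the default chain.

## Dataset assembly

Retained trials are restricted to the 17 model channels (Fp1/Fp2 excluded)
and the 1–500 ms window, then z-scored per trial × channel. A training
sample averages k ~ Uniform{30…35} distinct z-scored trials of one
training-fold stimulus pooled across participants (k is capped at the
available pool, with a warning); 3,000 samples per training epoch at full
scale. Test samples average all of one participant's retained trials for a
test-fold stimulus. Splits are stratified by category with a greedy
least-loaded-fold allocation (this handles categories with fewer images
than folds, which an off-the-shelf stratified k-fold rejects); per-category
test counts across folds differ by at most one, and a provenance check
asserts that no test-fold stimulus contributes any trial to that fold's
training samples.

At the reduced smoke scale (~9 trials per stimulus instead of ~187) the
averaging range is scaled down in proportion to 2–4: keeping 30–35 would
cap every draw at the full pool and make all training samples of a
stimulus identical, which removes the sampling diversity the averaging
scheme exists to provide.

## Classifier

Input 17 × 500; ConvBlock1: 8 × (1, 64) convolution with 32-sample
replicate padding per side + batch norm (time 500 → 501); ConvBlock2:
16 × (1, 1) convolution + batch norm + ELU + average-pool 4 + dropout 0.5
(→ 125); ConvBlock3: 16 × (1, 16) with 8-sample replicate padding,
16 × (1, 1), batch norm, ELU, average-pool 8, dropout 0.5 (→ 15); flatten
(16 · 17 · 15 = 4,080) → fully connected → softmax. Pooling floor-divides
with no padding and the paddings are per side — the only arithmetic
consistent with the 4,080 flatten size, which the test suite pins against
an independent integer-arithmetic oracle. Note the architecture contains
no spatial (cross-electrode) convolution; electrodes mix only in the
fully connected layer.

Training: categorical cross-entropy, Adam (lr 1e-3, batch 64; optional
decoupled weight decay, default 0), deterministic given the config seed
(initialization, data order and dropout all derive from it). Epoch-count
defaults per target (361 category / 221 naturalness / 341 openness / 301
roughness) follow the validation-trace selection procedure; the smoke
configuration uses 20 epochs, the plateau of its own validation trace at
that scale. The layers are NumPy throughout; temporal convolutions run in
the frequency domain (rfft-based circular correlation with zero-padded
kernels; the retained region is wrap-free), which is substantially faster
than im2col at these signal lengths on one core.

## Attribution

For each within-participant test sample the model predicts a class; the
gradient of that class's pre-softmax score with respect to the ConvBlock2
convolution output (16 × 17 × 501; a post-pool tap is available) is
averaged over electrodes and time into 16 weights; the map is
ReLU(Σ_k w_k A_k), binned to 4-ms resolution, averaged over the
participant's test samples, min-max normalized to [0, 1] (a constant map
normalizes to zeros, with a warning), and averaged across participants.

Significance: per channel × bin cell, a two-tailed one-sample t-test of
the participants' normalized contributions against the **first-peak
baseline** — the maximum group contribution within the first 12 bins
(≈0–48 ms, latencies that precede cortical visual processing) — with
BH-FDR adjustment jointly across all cells. A cell enters the reported
mask iff its adjusted p < 0.05 *and* its group mean exceeds the baseline;
cells significantly below baseline are background, not contributing
periods, though their t and adjusted p are exported. Zero-variance cells
receive p = 1. Channel-group summaries collapse the mask over a group
("any", or "majority") before maximal significant runs are reported as
millisecond intervals at the bin width.

Known limitation (by construction of the method, and measurable with this
package): because the weights are *globally* averaged gradients while the
feature maps retain their full background activation, the group maps carry
a positive floor (rectified zero-mean background plus constant offsets
from convolution biases and batch-norm affines at the tap) of roughly
0.1–0.2 of the peak that neither stronger planted components nor more
averaging removes, and the ConvBlock1 kernel (64 taps) smears a planted
component's map support by roughly ±30 ms beyond its true extent. The
practical consequence: Grad-CAM localization on this architecture is
reliable about *where the map peaks* and about baseline-referenced
significance, but the top decile of map cells always includes a broad
background tail — quantitative concentration measures should be read
accordingly.

## Image statistics

Filters are log-Gabors — Gaussian transfer functions on the log2-frequency
axis with σ = 0.5 octave, at one-octave center spacing (1–64 cycles/image
for the 7-scale bank); this tiles the 4–64 c/i band to within 3 dB.
Spectral slope is the least-squares slope of log10 radial power vs log10
frequency over 4–64 c/i (DC and the Nyquist shoulder excluded); roughness
is slope > median (ties and the median itself go to class 0). The spatial
envelope pools oriented subband energy (4 scales × 8 orientations,
half-plane filters so the complex magnitude is the local envelope) in a
4 × 4 block grid, concatenated block-major → scale → orientation (512
values). Classifier baselines use a linear SVM (standardized features)
under the same stratified 5-fold split, scored by balanced accuracy per
fold with a t-test of the fold scores against 50%.

## Reduced study condition (smoke / acceptance)

4 categories × 16 images, 3 participants × 3 sessions, latency-coded
15-µV components (sd 5 ms, centers spread over 86–114 ms) on O1/O2 over
2-µV 1/f noise, blinks 5/min at 150 µV, no re-reference stage, averaging
range 2–4, 600 training samples × 20 epochs, fold 0. The component is
deliberately strong relative to the background: the fixture's purpose is
to verify recovery machinery under conditions where the expected outcome
is unambiguous, and the map floor described above scales with
noise/amplitude. The package-wide generator defaults (8 µV on 10 µV
noise) remain in the physiologically typical range. Sizes throughout the
test suite are chosen so the full suite and the acceptance script each
complete in minutes on a single core.

## Degenerate inputs and numerical conventions

Zero-variance traces raise (z-scoring) or yield p = 1 (mask cells);
constant images raise for the slope and yield zero correlations for
energy maps; the ±75 µV boundary retains exact equality; BrainVision
output is IEEE float32 multiplexed with 1-based marker positions; HDF5
containers store trials as per-column datasets; all seeds fan out from one
global seed via SHA-256 of "seed:stage", keeping every derived seed below
2^31.
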