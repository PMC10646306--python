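# scenevep

Decoding natural-scene categories and global scene properties from visual
evoked potentials (VEPs), and localizing *which* EEG channels and latencies
carry that information.

## The problem

When people glance at a natural scene they extract its category (a bedroom,
a coast, a forest, ...) and its global properties — naturalness (natural vs
man-made), openness (open vs closed), and roughness (visual complexity,
well proxied by the slope of the image's spatial power spectrum) — within a
few hundred milliseconds. Scalp EEG has the temporal resolution to watch
this unfold: if stimulus-locked VEPs carry scene information, a classifier
that decodes category or property labels from them can be interrogated for
*where* (which 10–20 electrodes) and *when* (which post-onset latencies)
the discriminative signal lives.

`scenevep` implements that full analysis as a reusable, tested pipeline:

1. **`synth`** — surrogate 256×256 grayscale scene images with controllable
   power-spectrum slope and orientation energy, and 19-channel, 1,000-Hz
   EEG recordings in which each stimulus evokes class-dependent components
   at *known* channels and latencies on top of 1/f background noise and
   frontal blink artifacts. Every downstream stage is testable against this
   planted ground truth; real BrainVision/EDF recordings drop into the same
   pipeline.
2. **`preprocess`** — average re-reference, 0.5–40 Hz zero-phase band-pass,
   ICA-based ocular removal, epoching (−400…+800 ms), baseline correction
   (−100…0 ms), and ±75 µV amplitude rejection.
3. **`dataset`** — per-trial z-scoring over the 1–500 ms window, randomly
   averaged training samples (30–35 trials of one stimulus, pooled across
   participants), within-participant test averages, and category-stratified
   5-fold splits with a trial-provenance leakage guarantee.
4. **`model`** — a compact convolutional classifier that treats an averaged
   VEP as a 17-channel × 500-sample array: three temporal convolution
   blocks (8 filters of length 64; 16 pointwise filters; 16 filters of
   length 16 + pointwise), batch norm, ELU, average pooling 4 and 8,
   dropout 0.5, and a fully connected layer from the flattened
   16 × 17 × 15 = **4,080** features to the class scores. Forward and
   backward passes are implemented in NumPy, so the gradients used by the
   attribution stage are first-class objects.
5. **`attribution`** — Grad-CAM: the predicted-class score's gradient with
   respect to the 16 ConvBlock2 feature maps is globally averaged into
   per-map weights; the rectified weighted sum is a channels × time
   contribution map, min-max normalized per participant, averaged across
   participants, and tested cell-wise against the first-peak baseline
   (maximum contribution in the first 12 four-ms bins) with BH-FDR
   correction across all channel × time cells.
6. **`image_features`** — the image statistics used for roughness labeling
   and linear-SVM baselines: radially averaged spectral slope, 7-scale
   log-Gabor subband SDs, adjacent-scale energy correlations, and a
   4 × 4-block × 4-scale × 8-orientation spatial-envelope descriptor.

Evaluation follows the study design: accuracy and top-n accuracy for the
13-way category problem (chance 1/13 ≈ 7.7%, top-2 chance 15.4%), balanced
accuracy ½·(tp/(tp+fn) + tn/(tn+fp)) for the binary properties (chance
50%), per-participant means compared against chance with two-tailed
one-sample t-tests, BH-FDR adjusted.

## Worked example

A reduced experiment — 4 scene categories × 16 surrogate images, 3
participants × 3 sessions, with 15-µV class-dependent components planted at
O1/O2 within 80–120 ms — runs end-to-end on one CPU:

```bash
scenevep run-all --smoke --seed 1 --out runs/smoke
```

which prints (abridged):

```
{"config_seed": 1, "n_trials": 576}
category: {'accuracy': 0.7179, 'top2_accuracy': 0.9231}
```

Here 576 = 64 stimuli × 3 sessions × 3 participants is the epoched trial
count, and the held-out fold-0 accuracy of 0.72 against a chance level of
0.25 (n = 39 within-participant test averages, binomial p ≈ 1e-10) shows
the classifier recovering the planted class structure. The run directory
contains the stimulus table, split plan, epochs (HDF5), per-fold training
traces and model weights, the group attribution map with its per-cell
t/FDR statistics (CSV), and a manifest of content hashes; `scenevep report
runs/smoke` summarizes it.

The same pipeline at full scale (13 categories, 232 stimuli, 11
participants × 17 sessions, 3,000 training samples per epoch for 361/221/
341/301 epochs per target) is a single config away, but expect hours, not
minutes, on a laptop.

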