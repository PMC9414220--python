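# Methods

## Protocol and epoching

The package targets 64-channel, 160 Hz EEG recorded under the PhysioNet
motor movement/imagery protocol.  Task-2 runs (~120 s) carry an annotation
track with ~30 intervals of ~4 s labelled T0 (rest), T1 (left-fist motor
imagery) or T2 (right-fist motor imagery).  Epoching takes, for each
annotation, the first 640 samples (4 s × 160 Hz) after the onset, with the
onset-to-index conversion `round(onset · fs)`; annotations with fewer than
640 samples remaining before end-of-file are skipped and tallied, never
zero-padded — padding would inject artificial class signal, and whole
intervals are what the protocol's per-run sample count assumes.  No
filtering, re-referencing or artifact rejection is applied anywhere, by
design: the representations are meant to carry the raw signal (including
any line noise present in real recordings).

When loading the real corpus, subjects 88, 92, 100 and 104 are excluded by
default (incomplete annotations in the source data); this is configurable.

## Montage geometry

The frozen selections and sub-grids all derive from one rule: the
motor-strip electrodes form a 7-column × 3-row grid (columns 5, 3, 1, z,
2, 4, 6 of the FC/C/CP rows), and every ordering is its
top-to-bottom-then-left-to-right (column-major) traversal.  The tests
verify each frozen list against a geometric oracle that sorts schematic
10-10 coordinates column-major.  The 13-channel cross keeps the
plus-sign around each of C3, Cz, C4 (corners FC5, CP5, FC1, CP1, FC2,
CP2, FC6, CP6 excluded).  Volume layouts map grid columns to depth
layers; excluded electrodes leave explicit zero slots (the corners of the
3×3 layout for the 5-channel cross, the excluded electrodes' own slots
for the 13-channel cross), preserving spatial correspondence between the
21- and 13-channel volumes.  Electrode label matching is case-insensitive
and tolerates the trailing-dot padding of the source EDF headers.

## Spectrograms and rendering

The transform is a one-sided PSD spectrogram: 160-sample (1 s) windows
every 16 samples (90% overlap), Tukey(0.25) taper (the transform
routine's conventional default, frozen here and recorded in manifests),
no detrending.  A 640-sample epoch yields 81 × 31.  The taper and all
rendering choices are parameters of `SpectrogramParams` because the
transform itself does not fix them: rendering applies log(1+P), per-image
min–max normalization, a perceptually uniform colormap (viridis), a final
per-image stretch to the full 8-bit range, and bilinear resizing (32×32
for single-channel images; stacked images keep their native
(81·n_channels) × 31 extent unless a size is requested — the published
pipeline leaves the final stacked-image size unstated, so it is left
configurable).  Stacked images concatenate per-channel power matrices
along the frequency axis in selection order, frequency increasing
downward within each block; this per-channel-transform-then-concatenate
construction is exactly what a row-wise transform of the channels × 640
matrix computes.

## The classifier zoo

Ten architectures are transcribed layer by layer into declarative specs;
`build_model` instantiates them against a concrete input shape and
computes the final flatten width at build time, so the same 2D
architectures serve 32×32 RGB images, single-plane raw matrices
(1 × n_channels × 640) and volumes (depth mapped to input planes — the
only mapping that keeps the stated 2D kernels valid on D × C × 640
tensors).  Two kernel sizes the source text leaves unstated (middle
convolution of the three-layer 2D CNN; first convolution of the two-layer
1D CNN) default to each family's first-layer style (3×3, 5) and are
overridable; kernel-1 convolutions with padding 1 are implemented exactly
as stated even though they grow the spatial extent.  Dropout rates are
unspecified upstream and default to 0.5.  Fidelity has consequences: the
two-layer 2D CNN's 5×5 first kernel does not fit the 3-row volume
tensors, so that combination raises a shape error naming the offending
layer rather than silently adapting the architecture.

The transfer models remove the classification head of an 18-layer
residual network and attach the single-/three-layer CNN heads to the
512-plane feature map (input fixed at 3×256×256, giving 512×8×8
features).  The backbone is randomly initialized: pretrained weights are
an optional extra and nothing structural depends on them, but accuracy
results with a random backbone are not comparable to pretrained transfer
learning.

All networks run on a small numpy layer framework written for this
package (im2col convolutions over BLAS matmuls, float32, explicit
backward passes, He initialization).  Batch-norm uses momentum 0.1 and
eps 1e-5; a `trainable` flag per parameter implements backbone freezing.
The training loop is plain mini-batch Adam (SGD optional) with 3-class
cross-entropy.

## Experiment harness

Splitting is a seeded permutation with floor(N·0.1) validation and test
samples and the remainder training (9450 → 7560/945/945).  The default
`sample` unit reproduces the pooled random split of the source protocol;
it leaks subjects across splits, so a stricter `subject` unit is provided
and the choice should be recorded alongside results.  Learning rate
(default 1e-3), plateau reduction (factor 0.1, patience 5 epochs on
validation accuracy), batch size 64 and epoch budget are package
defaults — the source protocol states only that such parameters were
tuned on the validation set — and the best-validation checkpoint is kept.
Accuracy is trace(confusion)/N; per-class accuracy is reported because no
class rebalancing is applied (T0 is half of all samples).

## Synthetic corpus

The generator emulates the study design (configurable subjects × runs ×
30 intervals of 4 s, 15 rest per run; the full emulated design is 105 ×
3 × 30) and writes 16-bit EDF+ with a time-stamped annotation channel.
Every channel is 1/f background noise (frequency-domain shaping of white
noise, default exponent 1, RMS 6 µV) plus two mu-band oscillatory
sources centred over C3 and C4 with Gaussian spatial falloff (σ = 3
electrode spacings — broad, so that neighbouring sub-grids receive
correlated but attenuated signal).  The class signal is contralateral
event-related desynchronization: during T1 the right-hemisphere (C4)
source's amplitude is multiplied by `erd_attenuation` (default 0.4),
during T2 the left-hemisphere source, during T0 neither.  Band-power at
C4 during T1 therefore drops to ≈ attenuation² of its rest level, which
the tests verify with a periodogram oracle.  Default mu amplitude is
12 µV with per-interval random phases; all draws flow from one generator
seeded by (seed, subject, run), so corpora are reproducible file by file.

Two deliberate stylizations depart from real scalp EEG, both chosen so
that the single-channel (`raw1d`) pipeline is a well-posed 3-class
problem:

* the two hemispheric sources sit at slightly different peak frequencies
  (mu_freq ∓ 0.5 Hz, i.e. 9.5 and 10.5 Hz, both inside the mu band) —
  with one shared frequency, a lone channel cannot tell which hemisphere
  desynchronized, capping single-vector accuracy near 0.75;
* per-channel source weights are normalized to unit sum, so total mu
  amplitude is spatially flat and rest epochs look alike on every
  channel.

Real EEG offers neither guarantee (nor spatially flat amplitudes), so
passing the recovery experiment demonstrates that the pipeline and models
can extract a lateralized band-power code end to end — not that these
accuracies transfer to real recordings.  The generator also omits
artifacts entirely (no EOG/EMG/line noise by default).

## Problem sizes and numerical choices

Count-reproduction checks stream the full emulated design (315
recordings) without materializing samples; manifests count labels only.
The recovery experiment in the test suite and acceptance script uses a
3-subject corpus (90 epochs → 5760 single-channel vectors, split
4608/576/576), the three-layer 1D CNN, inputs scaled by the global
standard deviation, and 4 epochs of Adam (batch 64, plateau factor 0.3,
patience 2) — sizes chosen so the whole experiment runs in minutes on one
CPU core; the label-shuffled control trains 2 epochs and is evaluated on
a class-balanced held-out subset so its chance level is exactly 1/3.
Held-out accuracy lands near 0.70 — roughly twice chance, with rest
decoded at ~0.95 and the two imagery classes at ~0.5 each.  That split is
informative: rest detection needs only total mu amplitude, which the
network reads easily, while telling *which* hemispheric source
desynchronized requires resolving 9.5 from 10.5 Hz, and the stacked
convolutions have a receptive field of only 9 samples (~56 ms), so the
spectral selectivity must emerge in the wide final linear layer — a
sample-hungry path.  A two-feature spectral oracle (log band amplitudes
at 9.5/10.5 Hz under a quadratic logistic model) puts the information
ceiling at this corpus scale near 0.87; closing the gap to the oracle
empirically requires far more training data than a desk-scale corpus
provides (validation accuracy plateaus at ≈0.67–0.70 across 3–8-subject
corpora and up to 12 epochs), which is consistent with this architecture
family needing the full-size corpus to reach its published accuracy.
Ties in max-pooling resolve to the first maximum; spectrogram min–max
normalization maps constant images to zero; EDF quantization uses a
per-channel symmetric physical range rounded up in its on-disk decimal
form so a write/read round-trip is exact to half a quantization step.

## Known limitations

* No GPU path; training beyond desk scale is impractical in this
  framework (the full 604,800-vector design would take days on one core).
* The residual backbone is untrained; transfer-learning accuracies are
  only meaningful with externally supplied pretrained weights.
* The generator models neither inter-subject variability beyond seeding,
  nor artifacts, nor realistic spatial mixing (see stylizations above).
* Real-corpus loading is implemented (EDF+ reader, subject exclusions)
  but untested against the actual PhysioNet files in this repository's
  offline test suite.
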