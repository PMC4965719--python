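# Methods

This note records the modelling choices behind `eegwords`: the pipeline's
assumptions, the parameters that matter, what the synthetic generator
does and does not emulate, and the numerical conventions.

## Segmentation and labels

Records are cut by a sliding window of `window_s` seconds (default 3)
stepped by `step_s` (default 1); windows never cross the record boundary,
so a record of duration *D* yields ⌊(*D* − *L*)/step⌋ + 1 fragments.
Times are seconds from record start with half-open intervals
[start, end). A fragment is labeled *seizure* when at least
`overlap_threshold` (default 0.5) of its span lies inside annotated
seizure time; labels are invariant to annotation order, and overlapping
annotations are merged on parsing.

Each channel of each fragment is independently min–max scaled to [0, 1]
before modelling. The sigmoid decoder and cross-entropy loss require
targets in [0, 1], and per-fragment scaling additionally removes
inter-subject and inter-channel amplitude offsets — amplitude is
deliberately *not* a feature; the model discriminates on waveform shape
and temporal context. A constant channel maps to 0.5. This normalization
is the package's own convention; nothing in the underlying method fixes
one.

## Sparse autoencoder

Per-channel vectors (length `round(window_s * fs)`; 768 at 256 Hz) train
a stacked autoencoder with one or two sigmoid hidden layers, the top
layer of width *M* being the dictionary layer. The cost is the summed
elementwise cross-entropy plus β · Σⱼ KL(ρ ‖ ρ̂ⱼ), with ρ̂ⱼ the batch
mean of unit *j*'s activation. Defaults: ρ = 0.05, β = 3, hidden sizes
[400, 250] (only the top size is canonical; the first layer is a free
choice), SGD with constant learning rate 0.1, Glorot-uniform weight
init, zero biases, seeded. Training is greedy layerwise pretraining
(each layer as a one-hidden-layer sparse autoencoder on the codes of the
layer below) followed by joint fine-tuning with the penalty on the top
layer.

Numerical conventions: logs are clamped at ε = 1e−10; the gradient is
the *exact* derivative of the cost as defined — the sparsity term
back-propagates through the batch-mean ρ̂ with its 1/N factor — which is
what lets the test suite demand ≤ 1e−6 agreement with central finite
differences. Non-finite losses raise a divergence error naming the
epoch.

A multichannel fragment contributes one training vector per channel; its
fragment-level hidden feature is the channel-mean of top-layer codes.
This cross-channel rule (averaging rather than concatenation or a single
chosen channel) keeps the input dimension at one channel's length and
one word per time step, and is an explicit package assumption.

## Translation and context model

Dictionary word *i* is `decode(one-hot i)`. A fragment's word
distribution is its normalized fragment-level activation; translation
samples that multinomial (seeded) by default, with a pure `argmax` mode
used wherever determinism matters (detection, evaluation). An all-zero
activation raises rather than silently yielding a uniform draw.

The CBOW model embeds each word id as a row of A (*d* = 26 by default,
*k* = 2 context words each side) and scores the center word through a
binary Huffman tree built from corpus frequencies (ties broken by word
id, so the tree is reproducible). Along the target's root-to-leaf path
each internal node contributes log σ(±⟨v, h⟩); h is the average of the
context rows (concatenation is available behind config). Training is
per-position stochastic gradient ascent with learning rate 0.025
decaying linearly to 1e−4, single-threaded for determinism; one step
updates only the path nodes and context rows, and the update gradients
are exact (each context row receives grad/2k under averaging). All M
embedding rows are initialized even for never-sampled words so
downstream lookups cannot fail. Defaults for d, k, epochs and the rates
are package reconstructions — the method itself does not pin them.

## Detection and evaluation

Fragment features are [hidden ‖ temporal] (length M + d). An SVC with
RBF kernel (C = 1; linear kernel in config) on train-set-standardized
features supplies continuous decision scores; the error rate is taken at
the native zero threshold and the ROC sweeps all thresholds, with AUC by
the trapezoid rule (identical to the rank statistic, which the tests
cross-check). The test pool can be subsampled without replacement to a
50–50 class balance (seeded), since unbalanced error rates are dominated
by the 0.83 %-style degenerate solution. Splits are random at the
fragment level, stratified by class. The downsampling baseline uniformly
decimates the flattened normalized fragment to the fused-feature
dimension; the PCA baseline projects onto components fitted on the
training split only, so neither baseline leaks test data and all methods
see identically normalized inputs.

## Synthetic cohort generator

Each channel's background is low-pass-filtered white noise (σ = 8 µV,
40 Hz cut) plus a 20 µV alpha sinusoid (10 Hz, random phase). Seizures
replace the background with a unit-RMS 3 Hz spike-and-wave (harmonics
m = 1..4 weighted 1/m) scaled to `seizure_gain` (default 6) times the
channel's background RMS, plus broadband noise at `seizure_noise_frac`
(default 1.0) of the background RMS. The ictal noise default reflects
that real ictal scalp EEG is heavily contaminated (muscle and movement
artifact); near-noiseless synthetic seizures would make the detection
task trivially separable for any method and the baseline comparison
meaningless. Events are whole-second aligned, non-overlapping, with
≥ 5 s background margins; infeasible packing raises. Cohorts jitter
each subject's spectral parameters multiplicatively,
p → p·(1 + 0.25·z), matching roughly the 2–4 Hz spread of spike-wave
frequencies across patients; subject seeds derive from the base seed.

What the generator does *not* emulate: physiological forward modelling,
inter-channel correlation structure, artifacts (eye blinks, EMG bursts)
as distinct events, state transitions within non-seizure EEG, or
electrode montage effects. Passing tests on this cohort therefore show
that the pipeline recovers a known spectral/temporal regime change under
noise and cross-subject variability — not clinical performance.

## The packaged study and problem sizes

`eegwords.study` fixes a reproducible benchmark: 4 subjects, 256 Hz,
23 channels, 240 s and 2 seizures (30–100 s) per subject, hidden sizes
[64, 32], 3 autoencoder epochs, d = 8, 5 CBOW epochs, 25 % test
fraction, balanced test pool. These sizes keep a full multi-seed
comparison fast on a single CPU while retaining the real sampling rate
and channel count; they are deliberately far smaller than a clinical
training run, where the full defaults ([400, 250] hidden units, d = 26,
tens of epochs, hour-long records) apply. On this study the fused
features reach ~0 % balanced-test error with AUC ≈ 1.0 and a lower mean
error than uniform decimation at equal dimensionality, reproducing the
method's qualitative claim; absolute clinical numbers require real data.

## I/O conventions

EDF is written with 16-bit encoding, per-channel physical ranges
re-parsed from their ASCII header fields so writer and reader agree
exactly (round trip within one quantization step), one-second data
records when the length divides evenly. Reading goes through MNE. The
CSV dialect is one row per channel with a JSON sidecar (`<file>.json`)
for sampling rate, labels and subject id. Annotation intervals travel as
`start_s,end_s` CSV; the CHB-MIT-style plain-text summary is parsed
read-only. Models serialize as a JSON shapes header followed by flat
little-endian float64 arrays, so identical seeds yield byte-identical
files.

## Known limitations

- The cross-channel averaging rule discards channel topography.
- The zero-threshold error rate does not transfer across records when
  the classifier is trained on very few subjects (score *rankings* do);
  threshold recalibration per deployment would be needed in practice.
- Word sampling makes translated sentences stochastic; argmax mode
  trades that fidelity for determinism.
- Mini-batch SGD with a constant rate is deliberately plain; modern
  optimizers would train faster but are out of scope.
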