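# Methods

## Problem setting

An ultrasonic aspirator's generator exposes nine electrical features sampled
at 1000 Hz while the instrument fragments tissue. Because the electrical
system is load-dependent, these features shift with the mechanical
properties of the tissue in contact with the tip. The task is binary
classification of tissue stiffness — *very soft* (meningioma-like) versus
*soft* (healthy-brain-like) — from either single 9-feature measurement
points (random forest, autoencoder-regularized network) or 64-sample
windows (residual CNN). Laboratory recordings of this kind are not publicly
available, so the package ships a synthetic generator that reproduces the
statistical structure the analysis relies on; every stage downstream of the
generator is agnostic to whether the data are real or synthetic.

## Synthetic recording model

One recording is a lane traversal with three phases: initial idle (1.0 s),
contact (4.5 s), final idle (1.0 s), all at 1000 Hz, nine channels. The
signal model is phenomenological:

* **Idle baseline** `idle_level` (default 0) on every channel outside the
  contact phase.
* **Contact baseline** `contact_level + class_separation · offset[class]`
  per channel. The per-class offsets are ±½ of a fixed unit-norm direction
  in channel space, so the Euclidean distance between noise-free class means
  equals `class_separation` (default 1.0) exactly — a single dial for task
  difficulty.
* **Drift** `drift_slope` (default 0.05 units/s) linear in time from contact
  onset, modelling the instrument's continuous descent into the tissue.
* **Periodic irrigation noise**: a sinusoid at `periodic_noise_hz` (default
  1.2 Hz, amplitude 1.2, per-channel random phase) superimposed on the whole
  recording with probability `periodic_noise_fraction` (default 0.5 — the
  noise is observed on a substantial but unquantified portion of real
  recordings, so half is the neutral choice). Per-channel phases matter:
  a common-mode sinusoid would be confined to one direction of channel space
  and trivially ignorable by a classifier.
* **Broadband noise**: i.i.d. Gaussian, `broadband_sigma` (default 0.3).

Defaults were chosen once so that raw-input classification is good but
imperfect and noise removal visibly helps, mimicking the qualitative
behaviour of the laboratory data. Only the first second of contact (1000
points) enters the per-sample view; the idle phases are generated for
realism and phase-boundary testing but never analysed.

Each recording draws from an RNG substream keyed on `(seed, recording_id)`,
so enlarging a dataset never perturbs previously generated recordings, and
`generate_dataset` is bit-reproducible given its seed.

What the generator does **not** emulate: physical piezoelectric resonance,
ablation mechanics, aspirator generator settings, channel-specific units or
cross-channel correlation structure beyond the class offsets, and
non-stationarities other than the linear drift. Passing tests therefore
demonstrate correctness of the pipeline and the direction of preprocessing
effects under controlled conditions — not performance on real recordings.

## Filters

* Low-pass: third-order digital Butterworth, cutoff 0.75 Hz at fs 1000 Hz
  (−3 dB at the cutoff, unit DC gain).
* Band-stop: second-order IIR notch centred at 1.2 Hz with quality factor
  0.4. Q = centre / bandwidth, so the −3 dB stopband is about 3 Hz wide —
  very wide relative to the centre frequency, implemented as specified
  rather than "corrected".

Both are applied zero-phase (forward–backward, `sosfiltfilt`), which squares
the magnitude response and cancels phase delay. Filtering acts on the full
recording before the 1 s contact window is extracted, so filter edge
transients fall outside the analysed window. A causal/streaming mode is
deliberately out of scope. Filter-accuracy tests exclude the outermost
samples, where the forward–backward padding dominates.

Note a physical consequence of the 0.75 Hz low-pass: the idle→contact step
is smeared over roughly a second, so the analysed window after low-pass
filtering contains transient, not settled, baselines. This is inherent to
the filter choice, affects all classes equally, and preserves the class
offset information.

## Normalization and input noise

Per-feature zero-mean/unit-variance scaling is fitted on the training
partition of each fold only and applied unchanged to validation and test
data; standard deviations are floored at 1e-8 to tolerate degenerate
constant channels. For the autoencoder network, Gaussian noise with
σ = 0.1 is added to training batches after normalization, as an overfitting
countermeasure; the reconstruction target is the noisy network input (plain
noise augmentation, not denoising — the distinction is immaterial at
σ = 0.1 but is fixed here for reproducibility).

## Classifiers

**Random forest**: 100 trees, Gini splits, per-sample features. It trains on
all non-test recordings of a fold (it needs no validation split).

**Autoencoder-regularized network**: encoder 9 → 32 → 9 (latent), decoder
9 → 32 → 9, classifier head 9 → 4 → 2; ReLU activations; dropout 0.3 on the
encoder and classifier hidden layers. Trained end to end with

    loss = CE(logits, y) + α · MSE(reconstruction, input),  α = 0.3,

both terms batch-mean reduced. At inference the decoder is dropped. The
closed-form parameter count from the layer sizes is 1284.

**Residual CNN**: windows of 64 samples × 9 channels; stem convolution
9 → 16; three residual blocks of two convolutions each with channels
32/32/64 (the second block does not double), stride 2 at each block start,
kernel 7 everywhere; batch norm after every convolution, order
conv → BN → ReLU → dropout (0.3), with the residual addition before the
second activation of a block; global average pooling, then a fully
connected layer to 2 logits. "Seven convolutional layers" counts the main
path (1 + 3 × 2); where a block changes shape the shortcut is a 1×1
stride-matched projection with batch norm — a pure identity is arithmetically
impossible across stride-2/channel-change boundaries. Temporal lengths trace
64 → 32 → 16 → 8. A prediction is assigned to the last sample of each
window, so the first 63 samples of every recording are never scored
(937 predictions per 1000-sample window).

**Training harness** (both networks): Adam with initial learning rate 0.01,
classic L2-style weight decay 0.001, batch size 16,384, maximum 2000 epochs.
The learning rate is multiplied by 0.1 when the training loss plateaus
(patience 20 epochs, relative threshold 1e-4); early stopping monitors
validation macro F1 with patience 50 and restores the best weights. The
patience values and the early-stopping metric are this package's choices;
only the mechanisms (plateau decay on training data, early stopping on
validation performance) and the remaining hyperparameters are fixed by the
protocol being implemented.

The engine is plain NumPy with manual backpropagation, verified against
central finite differences (tolerance 1e-4 absolute + relative). The MLP
runs in float64; the CNN in float32, which halves the memory traffic of the
im2col convolution products and has no measurable effect on scores. All
stochastic elements — initialization, dropout masks, batch shuffling, input
noise — derive from a single seeded generator, so training is deterministic
given the seed.

## Cross-validation and metrics

Folds are formed over recordings, never samples: stratified by class, each
of the five folds tests on 8 of the 40 recordings (4 per class), and the
networks' validation split takes 12.5 % of the fold's 32 non-test
recordings (4, stratified). Samples from one recording are strongly
correlated, so any sample-level split would leak; the label-permutation
null (shuffling labels at the recording level must collapse held-out F1 to
~0.5) guards the implementation against such leakage bugs.

F1, PPV and TPR are macro-averaged over the two classes (with balanced
classes this keeps F1 ≈ ACC); ACC is argmax accuracy; AUROC uses the
predicted probability of the *very soft* class. Aggregates are the mean and
standard deviation of the five fold-level values. CNN metrics cover only
the samples with 63 predecessors, a strict subset of the samples scored for
the per-sample models.

## Problem sizes for routine runs

Full network training (2000 epochs, batch 16,384) is the protocol default
but far more than the synthetic task needs. Routine runs — the test suite,
the acceptance script and the `--smoke` CLI preset — use a reduced budget
(≤ 25 epochs, batch 1024, patience 5/10) and, where a dataset-size choice
exists, two tissue models per class; recovery experiments use one or three
folds per model where noted. These are problem-size choices of this
package; the defaults remain the full protocol.

## Known limitations

* Signals are phenomenological; absolute classification scores on synthetic
  data exceed what laboratory recordings yield and should not be compared
  numerically, only directionally.
* No causal filtering: the zero-phase filters are unusable in real time.
* The channel identities (which feature is voltage, current, ...) are
  intentionally anonymous.
* No significance testing between grid cells; only means and standard
  deviations over five folds are reported.
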