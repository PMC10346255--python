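# Methods

This note documents the models, parameter choices and limitations behind
`semgkit`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

Raw multichannel sEMG is modeled as a real matrix (channels × samples) at a
known sampling rate (default 1000 Hz, 7 channels). Denoising uses an
order-4 Butterworth bandpass, 20–450 Hz, followed by a second-order IIR
notch at 50 Hz with 2 Hz 3-dB bandwidth (Q = 25). The filter order,
topology and phase handling are open design choices in this kind of
pipeline; we use order 4 (standard sEMG practice) and zero-phase
forward–backward application so that detected onset times are not biased by
group delay. Zero-phase filtering squares the magnitude response — tests
that compare measured sinusoid gain against the designed response account
for this, and they discard a warm-up margin rather than mandating padding
behavior (the notch's narrow bandwidth implies ~1 s transients).

## Active-segment detection

Detection operates on the channel-mean signal, framed at 100 ms with a
50 ms hop. A frame is active when its short-term energy *and* its variance
exceed their thresholds ("and" is the conservative choice; "or" is
configurable). Both statistics divide by the number of frame samples `l`
(an exact mean over `l` terms). Thresholds default to an adaptive rule
calibrated on the first 10 frames, assumed to be rest:
`threshold = rest_mean + 6 · rest_std` per statistic, overridable by
absolute values. The multiplier matters: frame energies are χ²-like
(right-skewed) and the 10-frame standard-deviation estimate is noisy, so a
3σ multiplier admits roughly a 1% per-frame false-alarm rate; false alarms
adjacent to a true burst extend its detected boundary by one or more hops.
A multiplier of 6 brings the per-frame false-alarm rate low enough that
boundary errors are dominated by frame quantization (at most one hop).
Runs shorter than `min_segment_frames` (default 2) are discarded; when the
expected number of repetitions is known, the highest-energy runs are kept
in temporal order. Detected intervals are half-open `[start, end)` in
0-based sample indices.

Each detected interval is mapped back onto all channels verbatim, and every
segment is linearly interpolated per channel onto the maximal detected
segment length in the dataset being assembled (overridable with a fixed
target, e.g. 2664 samples to mirror a fixed-protocol corpus). Endpoints are
preserved exactly; linear interpolation cannot overshoot the data range.

## Time–frequency representation

Each channel of a segment is framed (default 50 ms with 40% overlap, i.e. a
hop of 60% of the frame) and transformed by the plain DFT — rectangular
frames, no taper, matching the transform's defining sum; a Hann option
exists but is off by default because the classifier consumes relative
spectral shape, not calibrated band power. The complex spectrum is
decomposed into real, imaginary, magnitude and full-quadrant phase (phase
of a zero bin is defined as 0), truncated to the one-sided half
(`floor(N/2)+1` bins — lossless for real signals). Which decomposition
feeds the classifier is a free choice; magnitude is the default, and a
`stacked` option supplies all four as separate input channels. The
flattening of the (channels × frames × bins) tensor into classifier input
is frame-major with ascending bins, and is exactly invertible.

The 50 ms default frame is the middle of the sweepable 20/50/100 ms grid
the experiment harness exposes; it balances temporal resolution (more
frames) against spectral resolution (more bins per frame).

## Classifier

The network is a 1-D parallel ("Inception"-style) CNN whose point is a
large receptive field without parameter growth or degradation:

* **STEM**: conv(32 filters, kernel 7, stride 2) → Leaky ReLU →
  max-pool(2) → conv(32, kernel 3) → Leaky ReLU → max-pool(2). Composition
  of the stem is an open choice; this is a conventional two-stage
  reduce-and-extract stem, and it is fully configurable.
* **Inception-ResNet A** (×2 by default): three parallel branches,
  conv(16 filters; kernels 8, 12, 24; dilation 5; 'same' padding) with
  Leaky ReLU, merged by element-wise summation, plus a residual shortcut
  branch (identity when channel counts match, else a 1×1 projection);
  Leaky ReLU on the merge. Summation merging (rather than concatenation)
  requires equal branch widths and is the default; concatenation would be a
  trivial extension.
* **Inception-ResNet B** (×1 by default): branches use 64 filters
  (kernels 8/12/24, dilation 3), then 16 kernels of size 3 reduce the
  width; shortcut and merge as in A. The dilation-rate assignment (5 in A
  branches, 3 in B branches) is one consistent reading of "rates 5 and 3
  in different branches"; both are configurable per block. The 1×3
  reduction convs are undilated (they are dimensionality reductions, not
  context aggregators).
* **Head**: dropout (rate 0.8, interpreted literally as the probability of
  dropping a unit; a `dropout_is_keep_prob` flag flips the reading) →
  flatten → dense(n_classes) → softmax.

Leaky ReLU slope defaults to 0.3; weights are Glorot-uniform from a seeded
generator, so identical (config, seed) builds are bit-identical. Branch
filter counts for block A (16) match B's post-reduction width so residual
sums type-check. Ablation variants: `baseline` (no shortcut, dilations
forced to 1), `residual_only`, `dilation_only`, `full`.

The engine behind these layers is a small numpy implementation:
convolutions are lowered to batched GEMMs through an im2col gather, with
the column gather and scatter done as `kernel`-length slice loops (cheap
vectorized adds); max-pooling stores argmax indices; training uses a fused
softmax/cross-entropy gradient and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-7).
Float32 is the working precision; gradient-check tests run the same layers
in float64 against central differences. Parameter counting is dual-path:
the layer table's closed form `filters × (kernel × in_channels + bias)`
(dense: `out × (in + bias)`) must equal the instantiated model's array
sizes exactly, for every variant.

## Receptive fields

For a layer with kernel `k`, stride `s`, dilation `d`, the effective kernel
is `k + (k−1)(d−1)`; stacks compose via `rf ← rf + (k_eff − 1)·jump`,
`jump ← jump·stride`. Pooling layers enter with the pool size as the
kernel; padding is ignored (it shifts indices, it does not extend reach).
An independent oracle composes exact per-layer tap-index sets for one
central output element and measures the span; a property test checks
agreement on randomized stacks. The report prints both `kernel` and
`k_eff` per layer so the effect of dilation is visible at a glance.

## Synthetic data generator

The generator emulates the acquisition protocol statistically, not
physiologically: sEMG is amplitude-modulated band-limited Gaussian noise —
the standard surrogate capturing the second-order statistics (energy,
variance, spectrum) that this pipeline thresholds and transforms. Defaults
mirror the protocol: 10 subjects, 10 gestures, 5 repetitions, 7 channels,
1000 Hz, active durations uniform in 2000–2664 ms, 4 s rest between
repetitions, activation-to-rest amplitude ratio 20 dB (the rest-noise
amplitude and SNR are not protocol-determined; 20 dB is typical of clean
surface recordings and is exposed in config).

Gesture classes differ in three ways real gestures differ:

* **Channel-gain pattern**: a random per-channel gain vector, normalized to
  unit RMS so classes differ in *pattern* rather than gross amplitude.
* **Envelope**: 60% of classes are "static" (single plateau); 40% are
  "dynamic" with 2–3 phases, each phase holding its own gain vector, with
  smooth crossfades between phases (muscles re-shape without relaxing).
* **Spectral emphasis**: each class's carrier occupies a 120 Hz sub-band,
  centers spread over 60–450 Hz, standing in for class-specific recruitment
  spectra. Bands start at 60 Hz so burst onsets do not excite ringing of
  the zero-phase 20 Hz band edge or of the narrow 50 Hz notch.

Burst envelopes switch on over a 100 ms edge: a quiescent lead-in (50% of
the edge) followed by a fast raised-cosine rise, emulating gradual
motor-unit recruitment followed by rapid activation. This calibration makes
the annotated support edges recoverable by the frame-quantized detector:
the threshold crossing lands deterministically in the frame with 50–100
samples of burst overlap, so boundary errors are dominated by the hop
quantization rather than by carrier noise. Per-subject variability is
multiplicative log-normal gain jitter (σ = 0.15). All randomness flows
from one `SeedSequence`, so identical (protocol, seed) reproduces the
dataset bit for bit; a quality-control check verifies ≥90% of active-window
power lies in 20–450 Hz and that rest windows are spectrally flat.

Samples are counted per the protocol convention — one sample is one channel
of one repetition's segment — giving 100 basic structures and 3500 samples
by default. Because each sample is a single channel, classes must be
separable from one channel alone; the class-specific sub-bands and
envelopes guarantee this, and a linear-classifier test on per-channel
energies confirms the separability floor the CNN builds on.

What passing tests on this generator do **not** show: robustness to real
sEMG nonstationarity (fatigue, electrode shift, crosstalk), to
motor-unit-level waveform structure, or to inter-subject variability beyond
gain scaling. Results on synthetic data bound pipeline correctness, not
field performance.

## Training and evaluation protocol

Stratified split: per class, ~30% to test, then ~30% of the remaining
training samples to validation, with largest-remainder rounding so totals
match the global fractions; deterministic under the split seed. Training
minimizes categorical cross-entropy with Adam (default learning rate 1e-3,
batch 32); defaults run 150 epochs, and the pipeline's learnability check
uses 30 epochs, which suffices on the synthetic protocol. Undefined
precision/recall (empty denominator) is reported as 0. The experiment
harness derives all stage seeds from one master seed and writes
reproducible CSV reports; the ablation and frame-length sweeps reuse one
dataset and one split so their reports are comparable.

Problem sizes used by the shipped checks: the full default protocol
(100 recordings, 3500 samples) for dataset assembly, separability and
learnability; 100 seeded recordings at 15 dB for segmentation recovery; a
miniature 2-subject × 3-gesture protocol for the sweep-structure and
CLI checks.

## Known limitations

* The training engine is CPU-bound numpy; it is sized for the bundled
  protocol (minutes per full training run), not for large corpora.
* Detection assumes an initial rest period for threshold calibration and
  one gesture per active run; overlapping gestures and gapless protocols
  need absolute thresholds.
* The Ninapro-DB1-style loader maps stimulus runs to recordings but is an
  adapter only; no claims are made about benchmark performance on it.
* Comparison backbones (VGG-style, plain ResNets, other Inception
  generations) are out of scope; the ablation variants isolate the
  residual and dilation mechanisms within this architecture only.
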