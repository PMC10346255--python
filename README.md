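# semgkit

Surface electromyography (sEMG) records the electrical activity of muscles
through skin electrodes; multichannel forearm sEMG carries enough
information about muscle coactivation to recognize sign-language hand
gestures. `semgkit` is a toolkit for that task: it implements the complete
recognition pipeline — denoising, muscle-activity onset detection,
time–frequency feature extraction, and a parallel 1-D convolutional
classifier — together with a protocol-faithful synthetic sEMG generator so
that every stage is testable end to end without human recordings.

## Pipeline

1. **Preprocessing** (`semgkit.preprocess`): 20–450 Hz order-4 Butterworth
   bandpass plus a 50 Hz notch (Q = 25), both applied zero-phase so gesture
   onsets are not delayed.
2. **Active-segment detection** (`semgkit.segmentation`): the channel-mean
   signal is cut into sliding frames (100 ms, 50 ms hop) and each frame's
   short-term energy `E = (1/l) Σ x(n)²` and variance
   `Var = (1/l) Σ (x(n) − x̄)²` are compared with rest-calibrated
   thresholds; maximal supra-threshold runs become gesture repetitions,
   which are mapped back to all channels and linearly interpolated to a
   common length.
3. **Time–frequency transform** (`semgkit.tf_transform`): sliding-window
   1-D DFT, `X(k) = Σ_{n=0}^{N−1} x(n) e^{−j2πnk/N}` (frames of 20/50/100 ms,
   40% overlap), decomposed into real part, imaginary part, magnitude
   `√(re² + im²)` and phase `atan2(im, re)`; the one-sided magnitude matrix
   is the default classifier input.
4. **Classifier** (`semgkit.model`): a 1-D Inception network with residual
   shortcuts and dilated convolutions. A STEM block (conv–pool twice)
   reduces dimensionality; Inception blocks run three parallel branches
   with kernels 1×8, 1×12 and 1×24 (dilation 5 in type-A blocks, 3 in
   type-B blocks whose 64-filter branches are reduced by 16 1×3 kernels),
   merged by element-wise summation plus a residual shortcut
   `H(x) = F(w, x) + x`; dropout (0.8), flatten, dense and softmax close
   the network. Ablation variants (`baseline`, `residual_only`,
   `dilation_only`, `full`) isolate the contribution of each mechanism.
   Dilation widens the receptive field at zero parameter cost: a conv layer
   holds `filters × (kernel × in_channels + 1)` parameters regardless of
   its dilation rate.
5. **Receptive-field calculator** (`semgkit.receptive_field`): geometric
   receptive fields of layer stacks, verified against an exact
   index-dependency oracle.
6. **Training & evaluation** (`semgkit.train_eval`): stratified 70/30
   train/test split with 30% of the training set as validation, Adam on
   categorical cross-entropy, per-class precision/recall/F1 and confusion
   matrices.

The networks run on a compact, fully seeded numpy engine (`semgkit.nn`)
with im2col-based 1-D convolutions and manual backpropagation — no GPU or
deep-learning framework required.

## Synthetic protocol

`semgkit.synthetic_data` emulates a ten-subject acquisition protocol: 10
gesture classes × 5 repetitions on 7 channels at 1000 Hz, repetitions
separated by 4 s of rest. Signals are amplitude-modulated band-limited
Gaussian noise with class-specific channel-gain patterns, carrier sub-bands
and envelopes (static plateaus or multi-phase "dynamic" gestures), with
log-normal per-subject gain jitter; exact burst windows are carried as
annotations. One *sample* is one channel of one repetition's active
segment, so the default protocol yields 10 × 10 = 100 basic structures and
100 × 5 × 7 = 3500 samples.

## Worked example

```python
from semgkit import (ProtocolConfig, generate_dataset, ModelConfig,
                     build_variant, SplitSpec, TrainConfig,
                     stratified_split, train, evaluate)
from semgkit.experiment import features_from_samples

ds = generate_dataset(ProtocolConfig())          # 100 structures, 3500 samples
x = features_from_samples(ds.samples, ds.fs, "time-frequency", 50.0, 0.4)
tr, va, te = stratified_split(ds.labels, SplitSpec(seed=0))
net = build_variant(ModelConfig(n_classes=10, input_length=x.shape[2]), "full", seed=0)
hist = train(net, {"train": (x[tr], ds.labels[tr]), "val": (x[va], ds.labels[va])},
             TrainConfig(epochs=30, seed=0))
print(round(hist["val_acc"][-1], 3))
rep = evaluate(net, x[te], ds.labels[te])
print("test acc", round(rep.accuracy, 4), "macro f1", round(rep.macro_f1, 4))
```

On one CPU core this takes roughly nine minutes and prints

```
0.981
test acc 0.9867 macro f1 0.9867
```

— the full network, trained 30 epochs on the default protocol's 50 ms
magnitude spectra, separates the ten synthetic gesture classes almost
perfectly (chance level is 0.1).

The receptive-field report for the default architecture:

```
$ semgkit rf-report --blocks-a 2 --blocks-b 1
layer              kernel  stride  dilation  k_eff  rf
stem.conv1         7       2       1         7      7
stem.pool1         2       2       1         2      9
stem.conv2         3       1       1         3      17
stem.pool2         2       2       1         2      21
A1.branch3.conv    24      1       5         116    941
A2.branch3.conv    24      1       5         116    1861
B1.branch3.conv    24      1       3         70     2413
B1.branch3.reduce  3       1       1         3      2429
```

`k_eff` is the dilated kernel's reach and `rf` the cumulative receptive
field in input samples: with dilation, three Inception blocks already see
~2400 samples of a ~2300-sample input. The same architecture holds 138,058
trainable parameters with or without dilation.

Other subcommands: `simulate`, `preprocess`, `segment`, `transform`,
`run`, `ablate`, `sweep-frames`, `evaluate` (see `semgkit --help`).

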