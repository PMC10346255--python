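"""Builder for the 1-D Inception network with residual shortcuts and
dilated convolutions (IRDC net), plus its ablation variants.

Architecture (input: batch x channels x length):

    STEM:  conv(32, k7, s2) -> LeakyReLU -> maxpool(2)
           -> conv(32, k3) -> LeakyReLU -> maxpool(2)
    n_blocks_A x Inception-ResNet A:
           branches 1-3: conv(16, k in {8, 12, 24}, dilation 5, 'same')
                          -> LeakyReLU
           merged by element-wise sum, + residual shortcut (branch 4),
           LeakyReLU on the merge
    n_blocks_B x Inception-ResNet B:
           branches 1-3: conv(64, k in {8, 12, 24}, dilation 3, 'same')
                          -> LeakyReLU -> conv(16, k3) -> LeakyReLU
           merged by sum, + residual shortcut, LeakyReLU
    dropout(0.8) -> flatten -> dense(n_classes) -> softmax

The residual shortcut is the identity when input and output channel counts
match and a 1x1 projection otherwise. Summation merging requires equal
branch shapes, hence 'same' padding and equal filter counts per branch.

Ablation variants:

    baseline       no residual shortcut, all dilations forced to 1
    residual_only  dilations forced to 1, shortcut kept
    dilation_only  shortcut removed, dilations kept
    full           as configured

Dilation widens a kernel's reach without adding taps, so the trainable
parameter count of a conv layer — filters * (kernel * in_channels + 1 with
bias) — is invariant to the dilation rate; :func:`count_parameters`
recomputes totals from the layer table and must match the instantiated
model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn

__all__ = [
    "ModelConfig", "LayerSpec", "VARIANTS",
    "build_irdc_net", "build_variant", "count_parameters", "layer_table",
]

VARIANTS = ("baseline", "residual_only", "dilation_only", "full")

STEM_MIN_INPUT = 8  # two stride-2 stages each followed by a pool of 2


@dataclass(frozen=True)
class ModelConfig:
    """Architecture settings; defaults follow the 10-gesture protocol."""

    n_classes: int = 10
    input_channels: int = 1
    input_length: int = 2288
    n_blocks_A: int = 2
    n_blocks_B: int = 1
    branch_kernels: tuple[int, int, int] = (8, 12, 24)
    dilation_A: int = 5
    dilation_B: int = 3
    filters_branch_A: int = 16
    filters_branch_B: int = 64
    filters_reduce_B: int = 16
    stem_filters: int = 32
    dropout_rate: float = 0.8
    dropout_is_keep_prob: bool = False
    leaky_slope: float = 0.3
    use_residual: bool = True
    use_dilation: bool = True

    def __post_init__(self) -> None:
        if self.n_blocks_A < 0 or self.n_blocks_B < 0:
            raise ValueError("block counts must be >= 0")
        if self.n_blocks_A == 0 and self.n_blocks_B == 0:
            raise ValueError("at least one Inception block is required")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if min(self.branch_kernels) < 1 or min(self.dilation_A, self.dilation_B) < 1:
            raise ValueError("kernels and dilations must be >= 1")
        if self.input_length < STEM_MIN_INPUT:
            raise ValueError(
                f"input_length {self.input_length} too short for the STEM "
                f"pooling chain; minimum is {STEM_MIN_INPUT}"
            )

    @property
    def drop_probability(self) -> float:
        return 1.0 - self.dropout_rate if self.dropout_is_keep_prob else self.dropout_rate


@dataclass(frozen=True)
class LayerSpec:
    """One row of the network description table."""

    kind: str  # conv | pool | add | concat | dense | dropout | activation
    name: str
    kernel: int | None = None
    stride: int = 1
    dilation: int = 1
    filters: int | None = None
    in_channels: int | None = None
    units_in: int | None = None
    units_out: int | None = None
    bias: bool = True


def _spec_params(spec: LayerSpec) -> int:
    if spec.kind == "conv":
        per_filter = spec.kernel * spec.in_channels + (1 if spec.bias else 0)
        return spec.filters * per_filter
    if spec.kind == "dense":
        return spec.units_out * (spec.units_in + (1 if spec.bias else 0))
    return 0


def count_parameters(model_or_specs) -> int:
    """Trainable-parameter count from a layer table or a built network.

    For a conv layer: ``filters * (kernel * in_channels + bias)``; dilation
    and stride do not enter. For a dense layer: ``out * (in + bias)``.
    """
    if isinstance(model_or_specs, nn.Network):
        specs = model_or_specs.layer_specs
    else:
        specs = list(model_or_specs)
    for spec in specs:
        if spec.kind == "conv" and None in (spec.kernel, spec.filters, spec.in_channels):
            raise ValueError(f"incomplete conv spec: {spec}")
        if spec.kind == "dense" and None in (spec.units_in, spec.units_out):
            raise ValueError(f"incomplete dense spec: {spec}")
    return sum(_spec_params(s) for s in specs)


class _Builder:
    def __init__(self, config: ModelConfig, seed: int) -> None:
        self.cfg = config
        self.rng = np.random.default_rng(seed)
        self.rng_box = nn.RngBox(seed + 1)
        self.specs: list[LayerSpec] = []

    def conv(self, c_in: int, c_out: int, kernel: int, *, stride: int = 1,
             dilation: int = 1, name: str) -> nn.Conv1D:
        self.specs.append(LayerSpec(
            kind="conv", name=name, kernel=kernel, stride=stride,
            dilation=dilation, filters=c_out, in_channels=c_in, bias=True,
        ))
        return nn.Conv1D(c_in, c_out, kernel, stride=stride, dilation=dilation,
                         rng=self.rng, name=name)

    def act(self, name: str) -> nn.LeakyReLU:
        self.specs.append(LayerSpec(kind="activation", name=name))
        return nn.LeakyReLU(self.cfg.leaky_slope, name=name)

    def pool(self, size: int, name: str) -> nn.MaxPool1D:
        self.specs.append(LayerSpec(kind="pool", name=name, kernel=size, stride=size))
        return nn.MaxPool1D(size, name=name)


def _branch_dilation(config: ModelConfig, base: int) -> int:
    return base if config.use_dilation else 1


def _stem(b: _Builder) -> tuple[list[nn.Layer], int, int]:
    cfg = b.cfg
    layers: list[nn.Layer] = [
        b.conv(cfg.input_channels, cfg.stem_filters, 7, stride=2, name="stem.conv1"),
        b.act("stem.act1"),
        b.pool(2, "stem.pool1"),
        b.conv(cfg.stem_filters, cfg.stem_filters, 3, name="stem.conv2"),
        b.act("stem.act2"),
        b.pool(2, "stem.pool2"),
    ]
    length = -(-cfg.input_length // 2) // 2  # conv stride 2, pool 2
    length = length // 2  # second pool (conv2 preserves length)
    return layers, cfg.stem_filters, length


def _block_a(b: _Builder, idx: int, c_in: int) -> tuple[nn.InceptionResBlock, int]:
    cfg = b.cfg
    dil = _branch_dilation(cfg, cfg.dilation_A)
    c_out = cfg.filters_branch_A
    branches = []
    for j, k in enumerate(cfg.branch_kernels, start=1):
        name = f"A{idx}.branch{j}"
        branches.append(nn.Sequential([
            b.conv(c_in, c_out, k, dilation=dil, name=f"{name}.conv"),
            b.act(f"{name}.act"),
        ], name=name))
    b.specs.append(LayerSpec(kind="add", name=f"A{idx}.merge"))
    shortcut = None
    if cfg.use_residual:
        if c_in != c_out:
            shortcut = b.conv(c_in, c_out, 1, name=f"A{idx}.shortcut")
        b.specs.append(LayerSpec(kind="add", name=f"A{idx}.residual_add"))
    block = nn.InceptionResBlock(
        branches, shortcut, cfg.use_residual, b.act(f"A{idx}.act"), name=f"A{idx}",
    )
    return block, c_out


def _block_b(b: _Builder, idx: int, c_in: int) -> tuple[nn.InceptionResBlock, int]:
    cfg = b.cfg
    dil = _branch_dilation(cfg, cfg.dilation_B)
    c_out = cfg.filters_reduce_B
    branches = []
    for j, k in enumerate(cfg.branch_kernels, start=1):
        name = f"B{idx}.branch{j}"
        branches.append(nn.Sequential([
            b.conv(c_in, cfg.filters_branch_B, k, dilation=dil, name=f"{name}.conv"),
            b.act(f"{name}.act1"),
            b.conv(cfg.filters_branch_B, c_out, 3, name=f"{name}.reduce"),
            b.act(f"{name}.act2"),
        ], name=name))
    b.specs.append(LayerSpec(kind="add", name=f"B{idx}.merge"))
    shortcut = None
    if cfg.use_residual:
        if c_in != c_out:
            shortcut = b.conv(c_in, c_out, 1, name=f"B{idx}.shortcut")
        b.specs.append(LayerSpec(kind="add", name=f"B{idx}.residual_add"))
    block = nn.InceptionResBlock(
        branches, shortcut, cfg.use_residual, b.act(f"B{idx}.act"), name=f"B{idx}",
    )
    return block, c_out


def build_irdc_net(config: ModelConfig, seed: int = 0) -> nn.Network:
    """Instantiate the network; the layer table is ``network.layer_specs``.

    Weight initialization and dropout are seeded, so identical
    (config, seed) yields an identical model.
    """
    b = _Builder(config, seed)
    layers, channels, length = _stem(b)
    for i in range(config.n_blocks_A):
        block, channels = _block_a(b, i + 1, channels)
        layers.append(block)
    for i in range(config.n_blocks_B):
        block, channels = _block_b(b, i + 1, channels)
        layers.append(block)
    b.specs.append(LayerSpec(kind="dropout", name="dropout"))
    layers.append(nn.Dropout(config.drop_probability, b.rng_box))
    b.specs.append(LayerSpec(kind="flatten", name="flatten"))
    layers.append(nn.Flatten())
    n_features = channels * length
    b.specs.append(LayerSpec(
        kind="dense", name="head", units_in=n_features, units_out=config.n_classes,
    ))
    layers.append(nn.Dense(n_features, config.n_classes, rng=b.rng, name="head"))
    b.specs.append(LayerSpec(kind="activation", name="softmax"))
    network = nn.Network(layers, b.rng_box)
    network.layer_specs = b.specs
    network.config = config
    return network


def build_variant(config: ModelConfig, variant: str, seed: int = 0) -> nn.Network:
    """Build one of the ablation variants (see module docstring)."""
    if variant == "baseline":
        cfg = replace(config, use_residual=False, use_dilation=False)
    elif variant == "residual_only":
        cfg = replace(config, use_residual=True, use_dilation=False)
    elif variant == "dilation_only":
        cfg = replace(config, use_residual=False, use_dilation=True)
    elif variant == "full":
        cfg = config
    else:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    return build_variant_config(cfg, seed)


def build_variant_config(cfg: ModelConfig, seed: int = 0) -> nn.Network:
    return build_irdc_net(cfg, seed)


def layer_table(network: nn.Network) -> str:
    """Render the network description as an aligned text table."""
    rows = [("kind", "name", "kernel", "stride", "dilation", "filters", "params")]
    for s in network.layer_specs:
        rows.append((
            s.kind, s.name,
            "-" if s.kernel is None else str(s.kernel),
            str(s.stride), str(s.dilation),
            "-" if s.filters is None else str(s.filters),
            str(_spec_params(s)),
        ))
    rows.append(("total", "", "", "", "", "", str(count_parameters(network.layer_specs))))
    widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)) for row in rows
    )
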