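"""Geometric receptive-field calculator for 1-D layer stacks.

The receptive field of one output element is the span of input samples that
can influence it. A dilated kernel of ``kernel`` taps spaced ``dilation``
apart reaches ``kernel + (kernel - 1) * (dilation - 1)`` samples; stacking
layers composes reaches through the cumulative stride ("jump"):

    rf_0 = 1, jump_0 = 1
    rf   <- rf + (k_eff - 1) * jump
    jump <- jump * stride

Padding does not change the receptive field (it only shifts which inputs
are real samples), so the calculator ignores it. Pooling layers are plain
``RFLayer`` entries with the pool size as the kernel — the dependency
geometry is identical.

:func:`dependency_oracle` verifies the closed form by explicitly composing
per-layer tap positions for one central output element and measuring the
span of input indices reached.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import ModelConfig

__all__ = [
    "RFLayer", "effective_kernel", "stack_rf", "dependency_oracle",
    "rf_table", "model_rf_layers",
]


@dataclass(frozen=True)
class RFLayer:
    """Geometry of one 1-D conv or pooling layer."""

    kernel: int
    stride: int = 1
    dilation: int = 1

    def __post_init__(self) -> None:
        if min(self.kernel, self.stride, self.dilation) < 1:
            raise ValueError(f"kernel/stride/dilation must be >= 1, got {self}")


def effective_kernel(layer: RFLayer) -> int:
    """Reach of a single dilated kernel: kernel + (kernel-1)*(dilation-1)."""
    return layer.kernel + (layer.kernel - 1) * (layer.dilation - 1)


def stack_rf(layers: Sequence[RFLayer]) -> int:
    """Receptive field, in input samples, of a stack (input-to-output order)."""
    if not layers:
        raise ValueError("empty layer stack")
    rf, jump = 1, 1
    for layer in layers:
        rf += (effective_kernel(layer) - 1) * jump
        jump *= layer.stride
    return rf


def dependency_oracle(layers: Sequence[RFLayer], input_len: int) -> int:
    """Span of input indices reached by one central output element.

    Composes the exact index-dependency set layer by layer (output to
    input). Raises if the support would be clipped by the input boundary,
    asking for a longer input.
    """
    if not layers:
        raise ValueError("empty layer stack")
    indices = {0}  # indices in the deepest layer's coordinate system
    for layer in reversed(layers):
        indices = {
            i * layer.stride + k * layer.dilation
            for i in indices
            for k in range((layer.kernel))
        }
    span = max(indices) - min(indices) + 1
    # centre the support and check it fits inside the input
    offset = (input_len - span) // 2
    if offset < 0 or offset + span > input_len:
        raise ValueError(
            f"input of {input_len} samples too short for a support of {span}; "
            f"supply input_len >= {span}"
        )
    return span


def model_rf_layers(config: ModelConfig) -> list[tuple[str, RFLayer]]:
    """Named layer geometries along the widest path through the classifier.

    Covers the STEM chain and, per Inception block, the largest-kernel
    branch (which dominates the receptive field; the summation merge takes
    the maximum over branches).
    """
    dil_a = config.dilation_A if config.use_dilation else 1
    dil_b = config.dilation_B if config.use_dilation else 1
    k_max = max(config.branch_kernels)
    named: list[tuple[str, RFLayer]] = [
        ("stem.conv1", RFLayer(7, stride=2)),
        ("stem.pool1", RFLayer(2, stride=2)),
        ("stem.conv2", RFLayer(3)),
        ("stem.pool2", RFLayer(2, stride=2)),
    ]
    for i in range(config.n_blocks_A):
        named.append((f"A{i + 1}.branch3.conv", RFLayer(k_max, dilation=dil_a)))
    for i in range(config.n_blocks_B):
        named.append((f"B{i + 1}.branch3.conv", RFLayer(k_max, dilation=dil_b)))
        named.append((f"B{i + 1}.branch3.reduce", RFLayer(3)))
    return named


def rf_table(named_layers: Iterable[tuple[str, RFLayer]]) -> str:
    """Per-layer table: kernel, effective kernel, cumulative receptive field."""
    rows = [("layer", "kernel", "stride", "dilation", "k_eff", "rf")]
    rf, jump = 1, 1
    for name, layer in named_layers:
        k_eff = effective_kernel(layer)
        rf += (k_eff - 1) * jump
        jump *= layer.stride
        rows.append((name, str(layer.kernel), str(layer.stride),
                     str(layer.dilation), str(k_eff), str(rf)))
    widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
    return "\n".join(
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)) for row in rows
    )
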