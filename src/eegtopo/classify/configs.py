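"""CNN architecture descriptions and the layer-size arithmetic.

Spatial sizes follow y = (n + 2p - f)/s + 1 for convolutions and
y = (n - f)/s + 1 for pooling; both must produce integers, otherwise the
configuration is rejected with the offending layer named.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

__all__ = [
    "CnnConfig",
    "CONFIGS",
    "conv_output_size",
    "pool_output_size",
    "layer_sizes",
    "flatten_size",
]


def conv_output_size(n: int, f: int = 3, p: int = 1, s: int = 1) -> int:
    num = n + 2 * p - f
    if num % s != 0:
        raise ValueError(f"conv size ({n} + 2*{p} - {f})/{s} + 1 is not an integer")
    return num // s + 1


def pool_output_size(n: int, f: int = 2, s: int = 2) -> int:
    num = n - f
    if num % s != 0:
        raise ValueError(f"pool size ({n} - {f})/{s} + 1 is not an integer")
    return num // s + 1


@dataclass(frozen=True)
class CnnConfig:
    """A VGG-style plan: stacks of (conv count, kernels), each followed by a
    2x2/stride-2 max pool, ending in a fully connected embedding layer."""

    name: str
    conv_plan: Tuple[Tuple[int, int], ...]
    kernel: int = 3
    stride: int = 1
    padding: int = 1
    pool: int = 2
    pool_stride: int = 2
    fc_nodes: int = 512

    def __post_init__(self) -> None:
        if not self.conv_plan:
            raise ValueError("conv_plan must contain at least one stack")
        for count, kernels in self.conv_plan:
            if count < 1 or kernels < 1:
                raise ValueError(f"invalid conv stack ({count}, {kernels})")


CONFIGS = {
    "A": CnnConfig("A", ((2, 32),)),
    "B": CnnConfig("B", ((2, 32), (2, 64))),
    "C": CnnConfig("C", ((2, 32), (2, 64), (1, 128))),
    "D": CnnConfig("D", ((4, 32), (2, 64), (1, 128))),
}


def layer_sizes(cfg: CnnConfig, input_size: int = 32, in_channels: int = 3):
    """Per-layer (description, spatial size, channels) trace through the plan."""
    trace: List[Tuple[str, int, int]] = [("input", input_size, in_channels)]
    size, channels = input_size, in_channels
    for si, (count, kernels) in enumerate(cfg.conv_plan, start=1):
        for li in range(1, count + 1):
            try:
                size = conv_output_size(size, cfg.kernel, cfg.padding, cfg.stride)
            except ValueError as exc:
                raise ValueError(f"stack {si} conv {li}: {exc}") from exc
            channels = kernels
            trace.append((f"conv{si}.{li}-{kernels}", size, channels))
        try:
            size = pool_output_size(size, cfg.pool, cfg.pool_stride)
        except ValueError as exc:
            raise ValueError(f"stack {si} pool: {exc}") from exc
        trace.append((f"pool{si}", size, channels))
    if size < 1:
        raise ValueError(f"spatial size collapsed to {size} before flatten")
    trace.append(("flatten", 1, size * size * channels))
    trace.append(("fc", 1, cfg.fc_nodes))
    return trace


def flatten_size(cfg: CnnConfig, input_size: int = 32, in_channels: int = 3) -> int:
    trace = layer_sizes(cfg, input_size, in_channels)
    return trace[-2][2]
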