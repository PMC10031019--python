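"""Hybrid channel + spatial attention block used at every decoder fusion."""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from ..autodiff import Tensor
from ..autodiff import nn
from ..autodiff.functional import channel_pool, global_avg_pool2d

__all__ = ["HybridAttentionBlock"]


class HybridAttentionBlock(nn.Module):
    """Sum of a channel-gated and a spatial-gated copy of the input.

    Channel branch: global average pool -> bottleneck MLP -> per-channel
    sigmoid gate.  Spatial branch: mean & max over channels -> 7x7
    convolution -> per-pixel sigmoid gate.

    ``gate_override`` (testing hook): when set to a float, both gates are
    replaced by that constant, so 1.0 degenerates the block to twice the
    identity and 0.0 to the zero map.
    """

    def __init__(self, channels: int, reduction: int = 4,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction)
        self.channels = channels
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)
        self.spatial_conv = nn.Conv2d(2, 1, 7, rng=rng)
        self.gate_override: Optional[float] = None

    def _gates(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        n, c, h, w = x.shape
        if self.gate_override is not None:
            g = float(self.gate_override)
            return (Tensor(np.full((n, c, 1, 1), g, np.float32)),
                    Tensor(np.full((n, 1, h, w), g, np.float32)))
        pooled = global_avg_pool2d(x)  # (N, C)
        cg = self.fc2(self.fc1(pooled).relu()).sigmoid().reshape(n, c, 1, 1)
        sg = self.spatial_conv(channel_pool(x)).sigmoid()  # (N,1,H,W)
        return cg, sg

    def forward_parts(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        """Return the two gated maps separately (for instrumentation)."""
        cg, sg = self._gates(x)
        return x * cg, x * sg

    def forward(self, x: Tensor) -> Tensor:
        channel_gated, spatial_gated = self.forward_parts(x)
        return channel_gated + spatial_gated
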