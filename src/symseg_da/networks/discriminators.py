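"""Adversarial discriminators.

``PixelDiscriminator`` is a patch-style convolutional classifier on
images (three stride-2 stages, so a 64x64 input yields an 8x8 score
map).  ``FeatureDiscriminator`` classifies bottleneck feature maps.
Both end in a sigmoid, so scores lie strictly inside (0,1).
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from ..autodiff import Tensor, no_grad
from ..autodiff import nn

__all__ = ["PixelDiscriminator", "FeatureDiscriminator", "discriminate_pixel", "discriminate_feature"]


class PixelDiscriminator(nn.Module):
    def __init__(self, base_width: int = 16, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c = base_width
        self.base_width = c
        self.body = nn.Sequential(
            nn.Conv2d(1, c, 4, stride=2, pad=1, rng=rng), nn.LeakyReLU(0.2),
            nn.Conv2d(c, 2 * c, 4, stride=2, pad=1, rng=rng), nn.InstanceNorm2d(2 * c), nn.LeakyReLU(0.2),
            nn.Conv2d(2 * c, 4 * c, 4, stride=2, pad=1, rng=rng), nn.InstanceNorm2d(4 * c), nn.LeakyReLU(0.2),
            nn.Conv2d(4 * c, 1, 3, rng=rng), nn.Sigmoid(),
        )

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != 1:
            raise ValueError(f"pixel discriminator expects a 1-channel image, got {c} channels")
        if h % 8 != 0 or w % 8 != 0:
            raise ValueError(f"pixel discriminator input must be divisible by 8, got {h}x{w}")
        return self.body(x)


class FeatureDiscriminator(nn.Module):
    def __init__(self, in_channels: int, width: int = 64,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        # no normalization here: bottleneck maps can be as small as 2x2 and
        # instance statistics over a single pixel collapse the scores
        self.body = nn.Sequential(
            nn.Conv2d(in_channels, width, 3, rng=rng), nn.LeakyReLU(0.2),
            nn.Conv2d(width, width, 3, stride=2, rng=rng), nn.LeakyReLU(0.2),
            nn.Conv2d(width, 1, 1, rng=rng), nn.Sigmoid(),
        )

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(
                f"feature discriminator expects {self.in_channels} channels, got {c}"
            )
        return self.body(x)


def _scores(d: nn.Module, arr: Union[np.ndarray, Tensor]) -> np.ndarray:
    if isinstance(arr, Tensor):
        arr = arr.data
    x = np.asarray(arr, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[None]
    with no_grad():
        return d(Tensor(x)).data


def discriminate_pixel(d: PixelDiscriminator, image: Union[np.ndarray, Tensor]) -> np.ndarray:
    """Patch realness scores of an image (inference, no gradients)."""
    return _scores(d, image)


def discriminate_feature(d: FeatureDiscriminator, features: Union[np.ndarray, Tensor]) -> np.ndarray:
    """Realness scores of a bottleneck feature map (inference, no gradients)."""
    return _scores(d, features)
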