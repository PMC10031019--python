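"""Bidirectional image translators (ResNet-style encoder/decoder).

Encoder: one stride-1 convolution to the base width, two stride-2
downsampling blocks, then ``n_res`` residual blocks.  Decoder: two
trainable transposed-convolution upsampling blocks and an output
convolution with tanh.  Images live in [0,1] at the interface and in
[-1,1] internally.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from ..autodiff import Tensor, no_grad
from ..autodiff import nn

__all__ = ["Translator", "translate"]


class ResBlock(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.body = nn.Sequential(
            nn.Conv2d(channels, channels, 3, rng=rng),
            nn.InstanceNorm2d(channels),
            nn.ReLU(),
            nn.Conv2d(channels, channels, 3, rng=rng),
            nn.InstanceNorm2d(channels),
        )

    def forward(self, x: Tensor) -> Tensor:
        return x + self.body(x)


class Translator(nn.Module):
    """G: [0,1] image -> [0,1] image of the same spatial size."""

    def __init__(self, base_width: int = 16, n_res: int = 2,
                 rng: Optional[np.random.Generator] = None, outer_kernel: int = 3):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c = base_width
        self.base_width = c
        self.n_res = n_res
        self.outer_kernel = outer_kernel
        self.encoder = nn.Sequential(
            nn.Conv2d(1, c, outer_kernel, rng=rng), nn.InstanceNorm2d(c), nn.ReLU(),
            nn.Conv2d(c, 2 * c, 3, stride=2, rng=rng), nn.InstanceNorm2d(2 * c), nn.ReLU(),
            nn.Conv2d(2 * c, 4 * c, 3, stride=2, rng=rng), nn.InstanceNorm2d(4 * c), nn.ReLU(),
            *[ResBlock(4 * c, rng) for _ in range(n_res)],
        )
        self.decoder = nn.Sequential(
            nn.ConvTranspose2d(4 * c, 2 * c, 4, 2, 1, rng=rng), nn.InstanceNorm2d(2 * c), nn.ReLU(),
            nn.ConvTranspose2d(2 * c, c, 4, 2, 1, rng=rng), nn.InstanceNorm2d(c), nn.ReLU(),
            nn.Conv2d(c, 1, outer_kernel, rng=rng), nn.Tanh(),
        )

    @staticmethod
    def _check_size(h: int, w: int) -> None:
        if h % 4 != 0 or w % 4 != 0:
            raise ValueError(
                f"translator input spatial size must be divisible by 4 "
                f"(two stride-2 stages), got {h}x{w}"
            )

    def forward(self, x: Tensor) -> Tensor:
        """x: (N,1,H,W) in [0,1] -> (N,1,H,W) in (0,1)."""
        n, c, h, w = x.shape
        self._check_size(h, w)
        z = self.encoder(x * 2.0 - 1.0)
        y = self.decoder(z)  # tanh, in (-1,1)
        return (y + 1.0) * 0.5


def _to_batch(image: np.ndarray) -> tuple[np.ndarray, tuple]:
    arr = np.asarray(image, dtype=np.float32)
    orig = arr.shape
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    elif arr.ndim != 4:
        raise ValueError(f"expected (H,W), (N,H,W) or (N,1,H,W) image, got shape {orig}")
    return arr, orig


def translate(t: Translator, image: Union[np.ndarray, Tensor]) -> np.ndarray:
    """Apply a translator to a [0,1] image (inference, no gradients)."""
    if isinstance(image, Tensor):
        image = image.data
    arr, orig = _to_batch(image)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("translate: image values must lie in [0,1]")
    with no_grad():
        out = t(Tensor(arr)).data
    return out.reshape(orig)
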