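"""Symmetric segmentation modules.

Encoder-decoder with four resolution stages, skip connections fused by a
hybrid attention block, and a sigmoid head.  Two encoder backbones:

* ``"tiny"`` — plain strided convolution stages (desk-scale default);
* ``"efficientnet-b0"`` — a Mobile-Inverted-Bottleneck (MBConv) stack
  with squeeze-excitation, following the B0 stage layout down to 1/16
  resolution (randomly initialized; no weight downloads).

The deepest encoder output is the bottleneck feature map exposed for
feature-level discrimination.
"""

from __future__ import annotations

from typing import List, Optional, Tuple, Union

import numpy as np

from ..autodiff import Tensor, concat, no_grad
from ..autodiff import nn
from ..autodiff.functional import global_avg_pool2d, upsample_nearest2d
from .attention import HybridAttentionBlock
from .translator import _to_batch

__all__ = ["Segmenter", "segment_probs", "encode_bottleneck"]

N_STAGES = 4  # input sizes must be divisible by 2**N_STAGES


class _SqueezeExcite(nn.Module):
    def __init__(self, channels: int, reduced: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(channels, reduced, rng=rng)
        self.fc2 = nn.Linear(reduced, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, _, _ = x.shape
        s = self.fc1(global_avg_pool2d(x))
        s = s * s.sigmoid()  # swish
        gate = self.fc2(s).sigmoid().reshape(n, c, 1, 1)
        return x * gate


class MBConv(nn.Module):
    """Mobile inverted bottleneck: expand -> depthwise -> SE -> project."""

    def __init__(self, cin: int, cout: int, expand: int, k: int, stride: int,
                 rng: np.random.Generator, se_ratio: float = 0.25):
        super().__init__()
        mid = cin * expand
        self.use_skip = stride == 1 and cin == cout
        layers: List[nn.Module] = []
        if expand != 1:
            layers += [nn.Conv2d(cin, mid, 1, rng=rng), nn.BatchNorm2d(mid), nn.Swish()]
        layers += [nn.DepthwiseConv2d(mid, k, stride=stride, rng=rng),
                   nn.BatchNorm2d(mid), nn.Swish(),
                   _SqueezeExcite(mid, max(1, int(cin * se_ratio)), rng),
                   nn.Conv2d(mid, cout, 1, rng=rng), nn.BatchNorm2d(cout)]
        self.body = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        out = self.body(x)
        if self.use_skip:
            out = out + x
        return out


def _conv_stage(cin: int, cout: int, rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(cin, cout, 3, stride=2, rng=rng), nn.BatchNorm2d(cout), nn.ReLU(),
        nn.Conv2d(cout, cout, 3, rng=rng), nn.BatchNorm2d(cout), nn.ReLU(),
    )


class _TinyEncoder(nn.Module):
    def __init__(self, base_width: int, rng: np.random.Generator):
        super().__init__()
        c = base_width
        self.stage_channels = [c, 2 * c, 4 * c, 8 * c]
        self.s1 = _conv_stage(1, c, rng)
        self.s2 = _conv_stage(c, 2 * c, rng)
        self.s3 = _conv_stage(2 * c, 4 * c, rng)
        self.s4 = _conv_stage(4 * c, 8 * c, rng)

    def forward(self, x: Tensor) -> List[Tensor]:
        f1 = self.s1(x)
        f2 = self.s2(f1)
        f3 = self.s3(f2)
        f4 = self.s4(f3)
        return [f1, f2, f3, f4]


class _MBConvEncoder(nn.Module):
    """B0-style stage layout truncated at 1/16 resolution; the last layer
    of each resolution level feeds the matching skip connection."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.stage_channels = [16, 24, 40, 112]
        self.stem = nn.Sequential(nn.Conv2d(1, 32, 3, stride=2, rng=rng),
                                  nn.BatchNorm2d(32), nn.Swish())
        self.g1 = MBConv(32, 16, expand=1, k=3, stride=1, rng=rng)
        self.g2 = nn.Sequential(MBConv(16, 24, 6, 3, 2, rng), MBConv(24, 24, 6, 3, 1, rng))
        self.g3 = nn.Sequential(MBConv(24, 40, 6, 5, 2, rng), MBConv(40, 40, 6, 5, 1, rng))
        self.g4 = nn.Sequential(MBConv(40, 80, 6, 3, 2, rng), MBConv(80, 80, 6, 3, 1, rng),
                                MBConv(80, 112, 6, 5, 1, rng), MBConv(112, 112, 6, 5, 1, rng))

    def forward(self, x: Tensor) -> List[Tensor]:
        f1 = self.g1(self.stem(x))
        f2 = self.g2(f1)
        f3 = self.g3(f2)
        f4 = self.g4(f3)
        return [f1, f2, f3, f4]


class _FusionStage(nn.Module):
    """Upsample, merge with the matching encoder skip, attend."""

    def __init__(self, cin: int, cskip: int, rng: np.random.Generator):
        super().__init__()
        self.reduce = nn.Conv2d(cin, cskip, 3, rng=rng)
        self.norm1 = nn.BatchNorm2d(cskip)
        self.fuse = nn.Conv2d(2 * cskip, cskip, 3, rng=rng)
        self.norm2 = nn.BatchNorm2d(cskip)
        self.attention = HybridAttentionBlock(cskip, rng=rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        up = self.norm1(self.reduce(upsample_nearest2d(x, 2))).relu()
        fused = self.norm2(self.fuse(concat([up, skip], axis=1))).relu()
        return self.attention(fused)


class Segmenter(nn.Module):
    """F: [0,1] image -> per-pixel nodule probability map in (0,1)."""

    def __init__(self, mode: str = "tiny", base_width: int = 16,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if mode == "tiny":
            self.encoder = _TinyEncoder(base_width, rng)
        elif mode == "efficientnet-b0":
            self.encoder = _MBConvEncoder(rng)
        else:
            raise ValueError(f"unknown segmenter mode {mode!r} (use 'tiny' or 'efficientnet-b0')")
        self.mode = mode
        self.base_width = base_width
        chans = self.encoder.stage_channels
        self.d3 = _FusionStage(chans[3], chans[2], rng)
        self.d2 = _FusionStage(chans[2], chans[1], rng)
        self.d1 = _FusionStage(chans[1], chans[0], rng)
        self.final = nn.Sequential(
            nn.Conv2d(chans[0], chans[0], 3, rng=rng), nn.BatchNorm2d(chans[0]), nn.ReLU(),
        )
        self.head = nn.Conv2d(chans[0], 1, 1, rng=rng)

    @staticmethod
    def _check_size(h: int, w: int) -> None:
        d = 2 ** N_STAGES
        if h % d != 0 or w % d != 0:
            raise ValueError(
                f"segmenter input spatial size must be divisible by {d} "
                f"({N_STAGES} downsampling stages), got {h}x{w}"
            )

    def forward_with_features(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        n, c, h, w = x.shape
        self._check_size(h, w)
        f1, f2, f3, f4 = self.encoder(x)
        y = self.d3(f4, f3)
        y = self.d2(y, f2)
        y = self.d1(y, f1)
        y = self.final(upsample_nearest2d(y, 2))
        probs = self.head(y).sigmoid()
        return probs, f4

    def forward(self, x: Tensor) -> Tensor:
        probs, _ = self.forward_with_features(x)
        return probs

    def encode(self, x: Tensor) -> Tensor:
        """Deepest encoder feature map (the latent code)."""
        n, c, h, w = x.shape
        self._check_size(h, w)
        return self.encoder(x)[-1]


def segment_probs(f: Segmenter, image: Union[np.ndarray, Tensor]) -> np.ndarray:
    """Inference helper: probability map for a [0,1] image, no gradients."""
    if isinstance(image, Tensor):
        image = image.data
    arr, orig = _to_batch(image)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("segment_probs: image values must lie in [0,1]")
    was_training = f.training
    f.eval()
    try:
        with no_grad():
            out = f(Tensor(arr)).data
    finally:
        f.train(was_training)
    return out.reshape(orig)


def encode_bottleneck(f: Segmenter, image: Union[np.ndarray, Tensor]) -> np.ndarray:
    """Inference helper: bottleneck features of a [0,1] image."""
    if isinstance(image, Tensor):
        image = image.data
    arr, _ = _to_batch(image)
    was_training = f.training
    f.eval()
    try:
        with no_grad():
            out = f.encode(Tensor(arr)).data
    finally:
        f.train(was_training)
    return out
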