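"""The full model bundle: two translators, two symmetric segmenters and
four discriminators, built from one config and checkpointed as one file."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, Union

import numpy as np

from .discriminators import FeatureDiscriminator, PixelDiscriminator
from .segmenter import Segmenter
from .translator import Translator

__all__ = ["NetworkConfig", "ModelBundle", "build_bundle"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture scale. ``tiny`` is the desk-scale default; ``paper``
    uses the published depths (8 residual blocks, MBConv backbone)."""

    scale: str = "tiny"
    translator_width: int = 16
    translator_res_blocks: int = 2
    translator_outer_kernel: int = 3
    segmenter_mode: str = "tiny"
    segmenter_width: int = 16
    discriminator_width: int = 16
    feature_discriminator_width: int = 64

    @classmethod
    def tiny(cls, width: int = 16) -> "NetworkConfig":
        return cls(scale="tiny", translator_width=width, translator_res_blocks=2,
                   segmenter_mode="tiny", segmenter_width=width, discriminator_width=width)

    @classmethod
    def paper(cls) -> "NetworkConfig":
        return cls(scale="paper", translator_width=64, translator_res_blocks=8,
                   translator_outer_kernel=7,
                   segmenter_mode="efficientnet-b0", segmenter_width=0,
                   discriminator_width=64, feature_discriminator_width=128)


class ModelBundle:
    """Holds G_{S->T}, G_{T->S}, F_S, F_T and the four discriminators.

    The two members of every family are architecturally identical (same
    constructor) with independent parameters.
    """

    NET_NAMES = ("g_s2t", "g_t2s", "f_s", "f_t", "d_s_pix", "d_t_pix", "d_s_feat", "d_t_feat")

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        ss = np.random.SeedSequence(seed).spawn(8)
        rngs = [np.random.default_rng(s) for s in ss]
        self.g_s2t = Translator(config.translator_width, config.translator_res_blocks,
                                rngs[0], config.translator_outer_kernel)
        self.g_t2s = Translator(config.translator_width, config.translator_res_blocks,
                                rngs[1], config.translator_outer_kernel)
        self.f_s = Segmenter(config.segmenter_mode, config.segmenter_width or 16, rngs[2])
        self.f_t = Segmenter(config.segmenter_mode, config.segmenter_width or 16, rngs[3])
        bottleneck = self.f_s.encoder.stage_channels[-1]
        self.d_s_pix = PixelDiscriminator(config.discriminator_width, rngs[4])
        self.d_t_pix = PixelDiscriminator(config.discriminator_width, rngs[5])
        self.d_s_feat = FeatureDiscriminator(bottleneck, config.feature_discriminator_width, rngs[6])
        self.d_t_feat = FeatureDiscriminator(bottleneck, config.feature_discriminator_width, rngs[7])

    def networks(self) -> Dict[str, object]:
        return {name: getattr(self, name) for name in self.NET_NAMES}

    def train(self) -> None:
        for net in self.networks().values():
            net.train()

    def eval(self) -> None:
        for net in self.networks().values():
            net.eval()

    # ------------------------------------------------------------------
    def save(self, path: Union[str, Path]) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for name, net in self.networks().items():
            for key, value in net.state_dict().items():
                arrays[f"{name}/{key}"] = value
        arrays["__config__"] = np.frombuffer(
            json.dumps({"config": asdict(self.config), "seed": self.seed}).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ModelBundle":
        with np.load(Path(path)) as archive:
            meta = json.loads(bytes(archive["__config__"]).decode())
            bundle = cls(NetworkConfig(**meta["config"]), seed=meta["seed"])
            for name, net in bundle.networks().items():
                prefix = name + "/"
                state = {k[len(prefix):]: archive[k] for k in archive.files if k.startswith(prefix)}
                net.load_state_dict(state)
        return bundle

    def load_into(self, path: Union[str, Path]) -> None:
        """Load a checkpoint into this bundle; refuse architecture mismatch."""
        with np.load(Path(path)) as archive:
            meta = json.loads(bytes(archive["__config__"]).decode())
            if NetworkConfig(**meta["config"]) != self.config:
                raise ValueError(
                    f"checkpoint architecture {meta['config']} does not match bundle config "
                    f"{asdict(self.config)}"
                )
            for name, net in self.networks().items():
                prefix = name + "/"
                state = {k[len(prefix):]: archive[k] for k in archive.files if k.startswith(prefix)}
                net.load_state_dict(state)

    def parameter_hash(self, names=None) -> Dict[str, bytes]:
        """Digest of every network's parameters (stage-isolation checks)."""
        import hashlib

        out = {}
        for name, net in self.networks().items():
            if names is not None and name not in names:
                continue
            h = hashlib.sha256()
            for pname, p in sorted(net.named_parameters()):
                h.update(pname.encode())
                h.update(np.ascontiguousarray(p.data).tobytes())
            out[name] = h.hexdigest()
        return out


def build_bundle(scale: str = "tiny", seed: int = 0, **overrides) -> ModelBundle:
    if scale == "tiny":
        config = NetworkConfig.tiny()
    elif scale == "paper":
        config = NetworkConfig.paper()
    else:
        raise ValueError(f"unknown scale {scale!r} (use 'tiny' or 'paper')")
    if overrides:
        from dataclasses import replace

        config = replace(config, **overrides)
    return ModelBundle(config, seed=seed)
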