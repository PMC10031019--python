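"""Run configuration: YAML schema, validation, resolution.

Every entry point validates its configuration before any computation;
unknown keys are rejected with the offending path so typos fail fast.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from typing import Dict, List, Optional, Tuple

from .losses import LossWeights
from .phantom import DomainStyle, PhantomConfig, STYLE_PRESETS

__all__ = ["DomainSpec", "RunConfig", "ConfigError"]

VARIANTS = ("full", "no_translation", "no_feature_gan", "no_consistency", "no_da")


class ConfigError(ValueError):
    pass


def _check_keys(d: dict, allowed: set, path: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys at {path}: {sorted(unknown)}")


def _build_dataclass(cls, d: dict, path: str):
    names = {f.name for f in fields(cls)}
    _check_keys(d, names, path)
    try:
        return cls(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config at {path}: {exc}") from exc


@dataclass(frozen=True)
class DomainSpec:
    """One synthetic domain: anatomy config + site style + sample counts."""

    n: int = 100
    test_count: Optional[int] = None
    test_fraction: Optional[float] = None
    preset: Optional[str] = None
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    style: DomainStyle = field(default_factory=DomainStyle)

    @classmethod
    def from_dict(cls, d: dict, path: str) -> "DomainSpec":
        _check_keys(d, {"n", "test_count", "test_fraction", "preset", "phantom", "style"}, path)
        d = dict(d)
        phantom = _build_dataclass(PhantomConfig, d.pop("phantom", {}), f"{path}.phantom")
        preset = d.pop("preset", None)
        style_dict = d.pop("style", {})
        if preset is not None:
            if preset not in STYLE_PRESETS:
                raise ConfigError(f"{path}.preset: unknown preset {preset!r} "
                                  f"(choose from {sorted(STYLE_PRESETS)})")
            base = STYLE_PRESETS[preset]
            style = replace(base, **style_dict) if style_dict else base
        else:
            style = _build_dataclass(DomainStyle, style_dict, f"{path}.style")
        spec = cls(phantom=phantom, style=style, preset=preset, **d)
        if spec.test_count is None and spec.test_fraction is None:
            spec = replace(spec, test_fraction=0.2)
        return spec


@dataclass(frozen=True)
class Stage1Config:
    epochs: int = 2
    lr_translation: float = 2e-4
    lr_discriminator: float = 2e-4


@dataclass(frozen=True)
class Stage2Config:
    epochs: int = 8
    lr_segmentation: float = 1e-3


@dataclass(frozen=True)
class Stage3Config:
    epochs: int = 2
    lr_translation: float = 1e-4
    lr_discriminator: float = 1e-4
    lr_segmentation: float = 5e-4


@dataclass(frozen=True)
class StageSchedule:
    """The three-step optimization schedule. ``epochs = 0`` skips a stage."""

    stage1: Stage1Config = field(default_factory=Stage1Config)
    stage2: Stage2Config = field(default_factory=Stage2Config)
    stage3: Stage3Config = field(default_factory=Stage3Config)
    batch_size: int = 8
    betas: Tuple[float, float] = (0.5, 0.999)
    consistency_symmetric: bool = False
    consistency_stop_grad: Optional[str] = None  # None | "source_branch"
    update_discriminators_stage3: bool = True
    augment_baseline: bool = False  # flip/rotate augmentation for the no_da baseline

    def __post_init__(self):
        for stage in (self.stage1, self.stage2, self.stage3):
            if stage.epochs < 0:
                raise ConfigError("stage epochs must be >= 0")
        for name, lr in (("stage1.lr_translation", self.stage1.lr_translation),
                         ("stage1.lr_discriminator", self.stage1.lr_discriminator),
                         ("stage2.lr_segmentation", self.stage2.lr_segmentation),
                         ("stage3.lr_translation", self.stage3.lr_translation),
                         ("stage3.lr_discriminator", self.stage3.lr_discriminator),
                         ("stage3.lr_segmentation", self.stage3.lr_segmentation)):
            if lr <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.consistency_stop_grad not in (None, "source_branch"):
            raise ConfigError("consistency_stop_grad must be null or 'source_branch'")

    @classmethod
    def from_dict(cls, d: dict, path: str = "schedule") -> "StageSchedule":
        allowed = {f.name for f in fields(cls)}
        _check_keys(d, allowed, path)
        d = dict(d)
        kwargs = {}
        for name, sub in (("stage1", Stage1Config), ("stage2", Stage2Config), ("stage3", Stage3Config)):
            if name in d:
                kwargs[name] = _build_dataclass(sub, d.pop(name), f"{path}.{name}")
        if "betas" in d:
            d["betas"] = tuple(d["betas"])
        return cls(**kwargs, **d)


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration for training / ablation runs."""

    seed: int = 0
    network_scale: str = "tiny"
    network_width: Optional[int] = None
    domains: Dict[str, DomainSpec] = field(default_factory=dict)
    pairs: List[Tuple[str, str]] = field(default_factory=list)
    variants: List[str] = field(default_factory=lambda: ["full"])
    schedule: StageSchedule = field(default_factory=StageSchedule)
    weights: LossWeights = field(default_factory=LossWeights)
    aggregation: str = "per_image_mean"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.network_scale not in ("tiny", "paper"):
            raise ConfigError(f"network_scale must be 'tiny' or 'paper', got {self.network_scale!r}")
        for v in self.variants:
            if v not in VARIANTS:
                raise ConfigError(f"unknown variant {v!r} (choose from {VARIANTS})")
        for pair in self.pairs:
            if len(pair) != 2:
                raise ConfigError(f"each pair must be [source, target], got {pair}")
            for name in pair:
                if name not in self.domains:
                    raise ConfigError(f"pair references undefined domain {name!r}")
        if self.aggregation not in ("per_image_mean", "pooled"):
            raise ConfigError(f"aggregation must be per_image_mean or pooled, got {self.aggregation!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        allowed = {f.name for f in fields(cls)}
        _check_keys(d, allowed, "config")
        d = dict(d)
        kwargs = {}
        if "domains" in d:
            doms = d.pop("domains")
            if not isinstance(doms, dict):
                raise ConfigError("config.domains must be a mapping of name -> domain spec")
            kwargs["domains"] = {
                name: DomainSpec.from_dict(spec, f"domains.{name}") for name, spec in doms.items()
            }
        if "pairs" in d:
            kwargs["pairs"] = [tuple(p) for p in d.pop("pairs")]
        if "schedule" in d:
            kwargs["schedule"] = StageSchedule.from_dict(d.pop("schedule"))
        if "weights" in d:
            kwargs["weights"] = _build_dataclass(LossWeights, d.pop("weights"), "weights")
        return cls(**kwargs, **d)

    def resolved(self) -> dict:
        """Plain-dict form for the resolved-config provenance file."""
        out = asdict(self)
        out["pairs"] = [list(p) for p in self.pairs]
        out["schedule"]["betas"] = list(self.schedule.betas)
        return out
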