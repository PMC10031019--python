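"""Three-stage optimization schedule, ablation variants and experiments.

Stage 1 trains the translation module adversarially (discriminator steps
on the printed adversarial sums, generator steps on the non-saturating
term plus cycle and identity losses).  Stage 2 trains both segmenters
supervised on source images and their translations.  Stage 3 jointly
refines everything under the weighted total objective, with one
discriminator update and one generator/segmenter update per step.

Ablation variants: ``full``, ``no_translation`` (raw images everywhere,
no adversarial/cycle/identity terms, consistency degenerates to Dice
between the two branches on the same raw image), ``no_feature_gan``
(feature-level adversarial terms zeroed), ``no_consistency`` (lambda_consis
= 0), ``no_da`` (source-only supervised segmenter, evaluated cross-domain).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .autodiff import Tensor, no_grad
from .autodiff.optim import Adam
from .config import RunConfig, StageSchedule, VARIANTS
from .losses import (
    LossReport,
    LossWeights,
    adv_loss_source,
    consistency_loss,
    cycle_loss,
    generator_adv_loss,
    identity_loss,
    seg_supervised_loss,
    soft_dice_loss,
    total_loss,
)
from .metrics import SegMetrics, binarize, evaluate_pairs, pair_table
from .networks import ModelBundle, build_bundle
from .phantom import DomainDataset, generate_domain_dataset

__all__ = [
    "AblationVariant",
    "TrainHistory",
    "train_stage1",
    "train_stage2",
    "train_stage3",
    "evaluate_on_target",
    "run_experiment",
]


@dataclass(frozen=True)
class AblationVariant:
    tag: str = "full"

    def __post_init__(self):
        if self.tag not in VARIANTS:
            raise ValueError(f"unknown ablation variant {self.tag!r} (choose from {VARIANTS})")


@dataclass
class TrainHistory:
    """Per-step loss reports, per-epoch validation metrics, stage marks."""

    steps: List[dict] = field(default_factory=list)
    val_metrics: List[dict] = field(default_factory=list)
    stage_boundaries: List[dict] = field(default_factory=list)

    def record_step(self, step: int, stage: str, report: LossReport,
                    weights: Optional[LossWeights] = None, **extra) -> None:
        row = {"step": step, "stage": stage, **report.as_dict(), **extra}
        if weights is not None:
            row.update({"lambda_adv": weights.lambda_adv, "lambda_cycle": weights.lambda_cycle,
                        "lambda_iden": weights.lambda_iden, "lambda_seg": weights.lambda_seg,
                        "lambda_consis": weights.lambda_consis})
        for key, value in row.items():
            if isinstance(value, float) and not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at step {step} ({stage}): {key}={value}; "
                    "training aborted (GAN stability guard)"
                )
        self.steps.append(row)

    def mark_stage(self, stage: str, step: int) -> None:
        self.stage_boundaries.append({"stage": stage, "step": step, "time": time.time()})

    def record_val(self, epoch: int, stage: str, metrics: SegMetrics) -> None:
        self.val_metrics.append({"epoch": epoch, "stage": stage, "pa": metrics.pa,
                                 "dsc": metrics.dsc, "tpr": metrics.tpr, "tnr": metrics.tnr})

    def steps_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    @property
    def next_step(self) -> int:
        return self.steps[-1]["step"] + 1 if self.steps else 0


# ---------------------------------------------------------------------------
# batching helpers


def _stack_images(samples: Sequence, idx: Iterable[int]) -> np.ndarray:
    return np.stack([samples[i].image for i in idx])[:, None].astype(np.float32)


def _stack_masks(samples: Sequence, idx: Iterable[int]) -> np.ndarray:
    masks = []
    for i in idx:
        if samples[i].mask is None:
            raise ValueError(f"sample {samples[i].id} has no mask but a labeled batch was requested")
        masks.append(samples[i].mask)
    return np.stack(masks)[:, None].astype(np.float32)


def _epoch_batches(n_source: int, n_target: int, batch_size: int,
                   rng: np.random.Generator) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Pair shuffled source batches with (cyclically reused) target batches."""
    src = rng.permutation(n_source)
    tgt = rng.permutation(n_target) if n_target > 0 else np.array([], dtype=int)
    out = []
    for start in range(0, n_source, batch_size):
        s_idx = src[start : start + batch_size]
        if n_target > 0:
            t_pos = (np.arange(start, start + len(s_idx)) % n_target)
            t_idx = tgt[t_pos]
        else:
            t_idx = np.array([], dtype=int)
        out.append((s_idx, t_idx))
    return out


def _augment_batch(images: np.ndarray, masks: np.ndarray,
                   rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Random flips / 90-degree rotations (baseline-only option)."""
    images = images.copy()
    masks = masks.copy()
    for i in range(images.shape[0]):
        if rng.random() < 0.5:
            images[i] = images[i, :, :, ::-1]
            masks[i] = masks[i, :, :, ::-1]
        k = int(rng.integers(0, 4))
        if k:
            images[i] = np.rot90(images[i], k, axes=(1, 2))
            masks[i] = np.rot90(masks[i], k, axes=(1, 2))
    return np.ascontiguousarray(images), np.ascontiguousarray(masks)


def _encode_eval(segmenter, arr: np.ndarray) -> np.ndarray:
    was = segmenter.training
    segmenter.eval()
    try:
        with no_grad():
            return segmenter.encode(Tensor(arr)).data
    finally:
        segmenter.train(was)


# ---------------------------------------------------------------------------
# stage 1: adversarial translation pretraining


def _discriminator_step(bundle: ModelBundle, d_opt: Adam, xs: np.ndarray, xt: np.ndarray,
                        use_feature_gan: bool,
                        fakes: Optional[Tuple[np.ndarray, np.ndarray]] = None) -> Tuple[float, float]:
    """One update of all discriminators on the printed adversarial sums,
    with translator outputs detached.  ``fakes = (fake_t, fake_s)`` reuses
    translations already computed during the generator step."""
    if fakes is not None:
        fake_t, fake_s = fakes
    else:
        with no_grad():
            fake_t = bundle.g_s2t(Tensor(xs)).data
            fake_s = bundle.g_t2s(Tensor(xt)).data
    if use_feature_gan:
        z_s_real = _encode_eval(bundle.f_s, xs)
        z_s_fake = _encode_eval(bundle.f_s, fake_s)
        z_t_real = _encode_eval(bundle.f_t, xt)
        z_t_fake = _encode_eval(bundle.f_t, fake_t)
        feat_s_real = bundle.d_s_feat(Tensor(z_s_real))
        feat_s_fake = bundle.d_s_feat(Tensor(z_s_fake))
        feat_t_real = bundle.d_t_feat(Tensor(z_t_real))
        feat_t_fake = bundle.d_t_feat(Tensor(z_t_fake))
    else:
        # feature-level terms zeroed: feed chance scores that carry no gradient
        half = np.full((1,), 0.5, np.float32)
        feat_s_real = feat_s_fake = feat_t_real = feat_t_fake = Tensor(half)
    adv_s = adv_loss_source(feat_s_real, feat_s_fake,
                            bundle.d_s_pix(Tensor(xs)), bundle.d_s_pix(Tensor(fake_s)))
    adv_t = adv_loss_source(feat_t_real, feat_t_fake,
                            bundle.d_t_pix(Tensor(xt)), bundle.d_t_pix(Tensor(fake_t)))
    d_opt.zero_grad()
    (adv_s + adv_t).backward()
    d_opt.step()
    return float(adv_s.data), float(adv_t.data)


def train_stage1(source: DomainDataset, target: DomainDataset, bundle: ModelBundle,
                 schedule: StageSchedule, rng: np.random.Generator,
                 weights: LossWeights = LossWeights(),
                 history: Optional[TrainHistory] = None,
                 use_feature_gan: bool = True) -> TrainHistory:
    """Adversarial pretraining of the translation module.

    Updates the two translators and all four discriminators; segmenter
    parameters are untouched (their frozen encoders provide the feature
    maps the feature discriminators see).
    """
    history = history or TrainHistory()
    src_train = source.subset("train")
    tgt_train = target.subset("train")
    if schedule.stage1.epochs == 0:
        return history
    if not src_train or not tgt_train:
        raise ValueError("train_stage1: both domains need a nonempty train split")

    g_params = bundle.g_s2t.parameters() + bundle.g_t2s.parameters()
    d_params = (bundle.d_s_pix.parameters() + bundle.d_t_pix.parameters()
                + bundle.d_s_feat.parameters() + bundle.d_t_feat.parameters())
    g_opt = Adam(g_params, lr=schedule.stage1.lr_translation, betas=schedule.betas)
    d_opt = Adam(d_params, lr=schedule.stage1.lr_discriminator, betas=schedule.betas)
    f_params = bundle.f_s.parameters() + bundle.f_t.parameters()

    step = history.next_step
    history.mark_stage("stage1", step)
    for epoch in range(schedule.stage1.epochs):
        for s_idx, t_idx in _epoch_batches(len(src_train), len(tgt_train),
                                           schedule.batch_size, rng):
            xs = _stack_images(src_train, s_idx)
            xt = _stack_images(tgt_train, t_idx)

            # generator step first; its (detached) fakes feed the
            # discriminator step below, saving two translator passes
            xs_t, xt_t = Tensor(xs), Tensor(xt)
            fake_t = bundle.g_s2t(xs_t)
            fake_s = bundle.g_t2s(xt_t)
            recon_s = bundle.g_t2s(fake_t)
            recon_t = bundle.g_s2t(fake_s)
            iden_s = bundle.g_t2s(xs_t)
            iden_t = bundle.g_s2t(xt_t)
            if use_feature_gan:
                bundle.f_s.eval()
                bundle.f_t.eval()
                gen_feat_s = bundle.d_s_feat(bundle.f_s.encode(fake_s))
                gen_feat_t = bundle.d_t_feat(bundle.f_t.encode(fake_t))
            else:
                gen_feat_s = gen_feat_t = Tensor(np.full((1,), 0.5, np.float32))
            gen_adv_s = generator_adv_loss(gen_feat_s, bundle.d_s_pix(fake_s))
            gen_adv_t = generator_adv_loss(gen_feat_t, bundle.d_t_pix(fake_t))
            cyc = cycle_loss(xs_t, xt_t, recon_s, recon_t)
            iden = identity_loss(xs_t, xt_t, iden_s, iden_t)
            # seg/consis terms are identically zero this stage, so the full
            # weighted sum is still exactly the stage-1 objective
            report, total = total_loss(gen_adv_s, gen_adv_t, cyc, iden, 0.0, 0.0, weights)
            g_opt.zero_grad()
            for p in f_params:
                p.grad = None
            total.backward()
            for p in f_params:  # frozen this stage
                p.grad = None
            g_opt.step()

            d_s, d_t = _discriminator_step(bundle, d_opt, xs, xt, use_feature_gan,
                                           fakes=(fake_t.data, fake_s.data))
            history.record_step(step, "stage1", report, weights=weights,
                                d_loss_s=d_s, d_loss_t=d_t, epoch=epoch)
            step += 1
    return history


# ---------------------------------------------------------------------------
# stage 2: supervised segmentation on source + translated source


def train_stage2(source: DomainDataset, bundle: ModelBundle, schedule: StageSchedule,
                 rng: np.random.Generator, history: Optional[TrainHistory] = None,
                 use_translation: bool = True,
                 weights: LossWeights = LossWeights()) -> TrainHistory:
    """Supervised training of F_S on (x_s, GT) and F_T on (G_{S->T}(x_s), GT).

    Translators are frozen; with ``use_translation=False`` (the
    no-translation ablation) F_T trains on the raw source images.
    """
    history = history or TrainHistory()
    src_train = source.subset("train")
    if schedule.stage2.epochs == 0:
        return history
    if not src_train:
        raise ValueError("train_stage2: source train split is empty")
    for sample in src_train:
        if sample.mask is None:
            raise ValueError(f"train_stage2: unlabeled source sample {sample.id}")

    f_opt = Adam(bundle.f_s.parameters() + bundle.f_t.parameters(),
                 lr=schedule.stage2.lr_segmentation, betas=(0.9, 0.999))
    step = history.next_step
    history.mark_stage("stage2", step)
    bundle.f_s.train()
    bundle.f_t.train()
    for epoch in range(schedule.stage2.epochs):
        for s_idx, _ in _epoch_batches(len(src_train), 0, schedule.batch_size, rng):
            xs = _stack_images(src_train, s_idx)
            gt = _stack_masks(src_train, s_idx)
            if use_translation:
                with no_grad():
                    xs_translated = bundle.g_s2t(Tensor(xs)).data
            else:
                xs_translated = xs
            p_s = bundle.f_s(Tensor(xs))
            p_t = bundle.f_t(Tensor(xs_translated))
            seg = seg_supervised_loss(p_s, p_t, gt)
            report, total = total_loss(0.0, 0.0, 0.0, 0.0, seg, 0.0, weights)
            f_opt.zero_grad()
            total.backward()
            f_opt.step()
            history.record_step(step, "stage2", report, weights=weights, epoch=epoch)
            step += 1
    return history


# ---------------------------------------------------------------------------
# stage 3: joint refinement under the total objective


def train_stage3(source: DomainDataset, target: DomainDataset, bundle: ModelBundle,
                 schedule: StageSchedule, variant: AblationVariant, rng: np.random.Generator,
                 weights: LossWeights = LossWeights(),
                 history: Optional[TrainHistory] = None) -> TrainHistory:
    """Joint refinement of the whole network under the weighted total loss,
    with the ablation variant's terms removed."""
    history = history or TrainHistory()
    tag = variant.tag
    if schedule.stage3.epochs == 0:
        return history

    if tag == "no_da":
        return _train_source_only(source, bundle, schedule, rng, history, weights)

    src_train = source.subset("train")
    tgt_train = target.subset("train")
    if not src_train or not tgt_train:
        raise ValueError("train_stage3: both domains need a nonempty train split")
    for sample in src_train:
        if sample.mask is None:
            raise ValueError(f"train_stage3: unlabeled source sample {sample.id}")

    use_translation = tag != "no_translation"
    use_feature_gan = tag not in ("no_feature_gan", "no_translation")
    eff_weights = weights
    if tag == "no_consistency":
        eff_weights = replace(weights, lambda_consis=0.0)
    if tag == "no_translation":
        eff_weights = replace(weights, lambda_adv=0.0, lambda_cycle=0.0, lambda_iden=0.0)

    g_params = (bundle.g_s2t.parameters() + bundle.g_t2s.parameters()) if use_translation else []
    f_params = bundle.f_s.parameters() + bundle.f_t.parameters()
    if use_translation:
        # separate learning rates for translators and segmenters
        gen_opt = Adam(g_params, lr=schedule.stage3.lr_translation, betas=schedule.betas)
        seg_opt = Adam(f_params, lr=schedule.stage3.lr_segmentation, betas=(0.9, 0.999))
    else:
        gen_opt = Adam(f_params, lr=schedule.stage3.lr_segmentation, betas=(0.9, 0.999))
        seg_opt = None
    d_params = bundle.d_s_pix.parameters() + bundle.d_t_pix.parameters()
    if use_feature_gan:
        d_params += bundle.d_s_feat.parameters() + bundle.d_t_feat.parameters()
    d_opt = Adam(d_params, lr=schedule.stage3.lr_discriminator, betas=schedule.betas)

    step = history.next_step
    history.mark_stage(f"stage3[{tag}]", step)
    bundle.f_s.train()
    bundle.f_t.train()
    for epoch in range(schedule.stage3.epochs):
        for s_idx, t_idx in _epoch_batches(len(src_train), len(tgt_train),
                                           schedule.batch_size, rng):
            xs = _stack_images(src_train, s_idx)
            gt = _stack_masks(src_train, s_idx)
            xt = _stack_images(tgt_train, t_idx)

            xs_t, xt_t = Tensor(xs), Tensor(xt)
            if use_translation:
                fake_t = bundle.g_s2t(xs_t)
                fake_s = bundle.g_t2s(xt_t)
                recon_s = bundle.g_t2s(fake_t)
                recon_t = bundle.g_s2t(fake_s)
                iden_s = bundle.g_t2s(xs_t)
                iden_t = bundle.g_s2t(xt_t)
                cyc = cycle_loss(xs_t, xt_t, recon_s, recon_t)
                iden = identity_loss(xs_t, xt_t, iden_s, iden_t)
            else:
                fake_t, fake_s = xs_t, xt_t  # raw images stand in for translations
                cyc = Tensor(np.zeros((), np.float32))
                iden = Tensor(np.zeros((), np.float32))

            p_s_src, _ = bundle.f_s.forward_with_features(xs_t)
            p_t_trans, z_fake_t = bundle.f_t.forward_with_features(fake_t)
            use_consistency = eff_weights.lambda_consis > 0.0
            if use_consistency:
                # the only consumer of F_T(x_t) / F_S(x_{t->s}) predictions is
                # the consistency term; the ablation removes the computation
                # entirely (otherwise batch-norm statistics would still adapt
                # to real target images as a side effect)
                p_t_tgt, _ = bundle.f_t.forward_with_features(xt_t)
                p_s_fake, z_fake_s = bundle.f_s.forward_with_features(fake_s)
            else:
                p_t_tgt = None
                z_fake_s = bundle.f_s.encode(fake_s)

            if use_translation:
                if use_feature_gan:
                    gen_feat_s = bundle.d_s_feat(z_fake_s)
                    gen_feat_t = bundle.d_t_feat(z_fake_t)
                else:
                    gen_feat_s = gen_feat_t = Tensor(np.full((1,), 0.5, np.float32))
                gen_adv_s = generator_adv_loss(gen_feat_s, bundle.d_s_pix(fake_s))
                gen_adv_t = generator_adv_loss(gen_feat_t, bundle.d_t_pix(fake_t))
            else:
                gen_adv_s = Tensor(np.zeros((), np.float32))
                gen_adv_t = Tensor(np.zeros((), np.float32))

            seg = seg_supervised_loss(p_s_src, p_t_trans, gt)
            if use_consistency:
                consis_ref = (p_s_fake.detach() if schedule.consistency_stop_grad == "source_branch"
                              else p_s_fake)
                consis = consistency_loss(p_t_tgt, consis_ref)
                if schedule.consistency_symmetric:
                    consis = consis + consistency_loss(p_s_src, p_t_trans)
            else:
                consis = Tensor(np.zeros((), np.float32))

            report, total = total_loss(gen_adv_s, gen_adv_t, cyc, iden, seg, consis, eff_weights)
            gen_opt.zero_grad()
            if seg_opt is not None:
                seg_opt.zero_grad()
            for p in d_params:
                p.grad = None
            total.backward()
            for p in d_params:  # discriminators update only in their own step
                p.grad = None
            gen_opt.step()
            if seg_opt is not None:
                seg_opt.step()

            d_s = d_t = 0.0
            if use_translation and schedule.update_discriminators_stage3:
                d_s, d_t = _discriminator_step(bundle, d_opt, xs, xt, use_feature_gan,
                                               fakes=(fake_t.data, fake_s.data))
            history.record_step(step, f"stage3[{tag}]", report, weights=eff_weights,
                                d_loss_s=d_s, d_loss_t=d_t, epoch=epoch)
            step += 1
    return history


def _train_source_only(source: DomainDataset, bundle: ModelBundle, schedule: StageSchedule,
                       rng: np.random.Generator, history: TrainHistory,
                       weights: LossWeights = LossWeights()) -> TrainHistory:
    """The no-DA baseline: F_S supervised on source only; translators,
    discriminators and F_T never touched."""
    src_train = source.subset("train")
    if not src_train:
        raise ValueError("no_da baseline: source train split is empty")
    f_opt = Adam(bundle.f_s.parameters(), lr=schedule.stage2.lr_segmentation, betas=(0.9, 0.999))
    step = history.next_step
    history.mark_stage("stage3[no_da]", step)
    bundle.f_s.train()
    for epoch in range(schedule.stage3.epochs):
        for s_idx, _ in _epoch_batches(len(src_train), 0, schedule.batch_size, rng):
            xs = _stack_images(src_train, s_idx)
            gt = _stack_masks(src_train, s_idx)
            if schedule.augment_baseline:
                xs, gt = _augment_batch(xs, gt, rng)
            p_s = bundle.f_s(Tensor(xs))
            seg = soft_dice_loss(p_s, gt)
            report, total = total_loss(0.0, 0.0, 0.0, 0.0, seg, 0.0, weights)
            f_opt.zero_grad()
            total.backward()
            f_opt.step()
            history.record_step(step, "stage3[no_da]", report, weights=weights, epoch=epoch)
            step += 1
    return history


# ---------------------------------------------------------------------------
# evaluation and experiments


def evaluate_on_target(bundle: ModelBundle, target: DomainDataset, variant: AblationVariant,
                       split: str = "test", aggregation: str = "per_image_mean",
                       threshold: float = 0.5) -> SegMetrics:
    """Segment the target split and score against its ground truth.

    The ``no_da`` baseline is evaluated with F_S (cross-domain); all other
    variants use the target-branch segmenter F_T.
    """
    samples = target.subset(split)
    if not samples:
        raise ValueError(f"target has no {split!r} samples")
    segmenter = bundle.f_s if variant.tag == "no_da" else bundle.f_t
    was = segmenter.training
    segmenter.eval()
    preds, gts = [], []
    try:
        with no_grad():
            for sample in samples:
                if sample.mask is None:
                    raise ValueError(f"target sample {sample.id} has no ground truth for evaluation")
                probs = segmenter(Tensor(sample.image[None, None])).data[0, 0]
                preds.append(binarize(probs, threshold))
                gts.append(sample.mask)
    finally:
        segmenter.train(was)
    return evaluate_pairs(preds, gts, aggregation)


def train_variant(source: DomainDataset, target: DomainDataset, config: RunConfig,
                  variant: AblationVariant, seed: int,
                  pretrained: Optional[ModelBundle] = None,
                  stage12_history: Optional[TrainHistory] = None,
                  ) -> Tuple[ModelBundle, TrainHistory]:
    """Run the full schedule for one variant.

    ``no_da`` trains F_S from scratch (stages 1-2 skipped).  Other
    variants run stage 1 (skipped for ``no_translation``), stage 2, then
    the variant's stage 3.  ``pretrained`` short-circuits stages 1-2 with
    an already-trained bundle (so ablations can share them).
    """
    overrides = {}
    if config.network_width:
        overrides = dict(translator_width=config.network_width, segmenter_width=config.network_width,
                         discriminator_width=config.network_width)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA5)))
    if pretrained is not None:
        bundle = pretrained
        history = stage12_history or TrainHistory()
    else:
        bundle = build_bundle(config.network_scale, seed=seed, **overrides)
        history = TrainHistory()
        if variant.tag == "no_da":
            pass  # only stage 3 (source-only supervised training)
        else:
            if variant.tag != "no_translation":
                train_stage1(source, target, bundle, config.schedule, rng,
                             weights=config.weights, history=history,
                             use_feature_gan=variant.tag != "no_feature_gan")
            train_stage2(source, bundle, config.schedule, rng, history=history,
                         use_translation=variant.tag != "no_translation")
    train_stage3(source, target, bundle, config.schedule, variant, rng,
                 weights=config.weights, history=history)
    return bundle, history


def build_domains(config: RunConfig, seed: int) -> Dict[str, DomainDataset]:
    domains = {}
    for offset, (name, spec) in enumerate(sorted(config.domains.items())):
        domains[name] = generate_domain_dataset(
            spec.phantom, spec.style, spec.n,
            test_fraction=spec.test_fraction, test_count=spec.test_count,
            seed=int(np.random.SeedSequence((seed, offset)).generate_state(1)[0]),
            domain=name,
        )
    return domains


def run_experiment(config: RunConfig, out_dir: Optional[Path] = None) -> pd.DataFrame:
    """Run every configured (source, target) pair and variant; return the
    cross-domain metric table (plus an Average row over pairs)."""
    if not config.pairs:
        raise ValueError("run_experiment: config.pairs is empty")
    domains = build_domains(config, config.seed)
    rows = []
    all_histories: List[Tuple[str, TrainHistory]] = []
    for source_name, target_name in config.pairs:
        for tag in config.variants:
            variant = AblationVariant(tag)
            bundle, history = train_variant(domains[source_name], domains[target_name],
                                            config, variant, config.seed)
            metrics = evaluate_on_target(bundle, domains[target_name], variant,
                                         aggregation=config.aggregation)
            rows.append({"source": source_name, "target": target_name, "variant": tag,
                         "pa": metrics.pa, "dsc": metrics.dsc,
                         "tpr": metrics.tpr, "tnr": metrics.tnr})
            all_histories.append((f"{source_name}->{target_name}[{tag}]", history))
            if out_dir is not None:
                ckpt = Path(out_dir) / "checkpoints" / f"{source_name}__{target_name}__{tag}.npz"
                bundle.save(ckpt)

    table = pd.DataFrame(rows, columns=["source", "target", "variant", "pa", "dsc", "tpr", "tnr"])
    avg = table[["pa", "dsc", "tpr", "tnr"]].mean()
    table = pd.concat(
        [table, pd.DataFrame([{"source": "Average", "target": "", "variant": "", **avg.to_dict()}])],
        ignore_index=True,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "metrics.csv", index=False, float_format="%.6f")
        frames = []
        for label, history in all_histories:
            df = history.steps_frame()
            if not df.empty:
                df.insert(0, "run", label)
                frames.append(df)
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                out_dir / "history.csv", index=False, float_format="%.6f"
            )
    return table
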