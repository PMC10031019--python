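"""Training objectives: adversarial (pixel + feature), cycle, identity,
supervised soft-Dice, cross-branch consistency, and the weighted total.

All losses accept either raw numpy arrays or autodiff tensors and return
an autodiff :class:`~symseg_da.autodiff.Tensor` scalar, so the same code
path serves unit tests and training.

Conventions:

* the printed adversarial sums are the discriminator objectives
  (``adv_loss_source`` / ``adv_loss_target``); generators minimize the
  non-saturating counterpart ``generator_adv_loss``;
* the soft Dice form is ``1 - (2*sum(p*q) + eps) / (sum(p) + sum(q) + eps)``
  with ``eps = 1`` by default, pixel sums per sample, mean over batch;
* realness scores are clamped to ``[1e-7, 1 - 1e-7]`` before logs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .autodiff import Tensor, astensor

__all__ = [
    "LossWeights",
    "LossReport",
    "soft_dice_loss",
    "adv_loss_source",
    "adv_loss_target",
    "generator_adv_loss",
    "cycle_loss",
    "identity_loss",
    "seg_supervised_loss",
    "consistency_loss",
    "total_loss",
]

SCORE_CLAMP = 1e-7

ArrayOrTensor = Union[np.ndarray, Tensor]


@dataclass(frozen=True)
class LossWeights:
    """Weights of the total objective; defaults are the published values."""

    lambda_adv: float = 1.0
    lambda_cycle: float = 1.0
    lambda_iden: float = 1.0
    lambda_seg: float = 10.0
    lambda_consis: float = 2.0

    def __post_init__(self):
        for name in ("lambda_adv", "lambda_cycle", "lambda_iden", "lambda_seg", "lambda_consis"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class LossReport:
    """Per-term scalar values of one optimization step."""

    adv_s: float
    adv_t: float
    cycle: float
    iden: float
    seg: float
    consis: float
    total: float

    def as_dict(self) -> dict:
        return {
            "adv_s": self.adv_s, "adv_t": self.adv_t, "cycle": self.cycle,
            "iden": self.iden, "seg": self.seg, "consis": self.consis, "total": self.total,
        }


def _check_same_shape(a: Tensor, b: Tensor, op: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{op}: shape mismatch {a.shape} vs {b.shape}")


def _scores(x: ArrayOrTensor, name: str) -> Tensor:
    t = astensor(x)
    if t.data.min() < 0.0 or t.data.max() > 1.0:
        raise ValueError(f"{name}: realness scores must lie in (0,1)")
    return t.clip(SCORE_CLAMP, 1.0 - SCORE_CLAMP)


def soft_dice_loss(pred: ArrayOrTensor, ref: ArrayOrTensor, eps: float = 1.0) -> Tensor:
    """Smoothed Dice loss in [0, 1); symmetric in its two arguments.

    Accepts (H, W), (N, H, W) or (N, 1, H, W) maps; sums run over all
    pixels of a sample and the result is averaged over the batch.
    """
    if eps <= 0:
        raise ValueError(f"eps must be > 0, got {eps}")
    p = astensor(pred)
    q = astensor(ref)
    _check_same_shape(p, q, "soft_dice_loss")
    if p.ndim == 2:
        axes = (0, 1)
    else:
        axes = tuple(range(1, p.ndim))
    inter = (p * q).sum(axis=axes)
    sums = p.sum(axis=axes) + q.sum(axis=axes)
    dice = (2.0 * inter + eps) / (sums + eps)
    return (1.0 - dice).mean()


def _bce_real(scores: Tensor) -> Tensor:
    return (-(scores.log())).mean()


def _bce_fake(scores: Tensor) -> Tensor:
    return (-((1.0 - scores).log())).mean()


def adv_loss_source(dfeat_real: ArrayOrTensor, dfeat_fake: ArrayOrTensor,
                    dpix_real: ArrayOrTensor, dpix_fake: ArrayOrTensor) -> Tensor:
    """Discriminator objective of one domain.

    ``real`` scores come from genuine domain images/features, ``fake``
    scores from translated ones; expectations are means over batch and
    patch scores.  At chance (all scores 0.5) the value is 4*ln 2.
    """
    feat_real = _scores(dfeat_real, "dfeat_real")
    feat_fake = _scores(dfeat_fake, "dfeat_fake")
    pix_real = _scores(dpix_real, "dpix_real")
    pix_fake = _scores(dpix_fake, "dpix_fake")
    return (_bce_fake(feat_fake) + _bce_real(feat_real)
            + _bce_fake(pix_fake) + _bce_real(pix_real))


# the target-domain loss has the identical form with domain roles swapped
adv_loss_target = adv_loss_source


def generator_adv_loss(dfeat_fake: ArrayOrTensor, dpix_fake: ArrayOrTensor) -> Tensor:
    """Non-saturating generator objective: E[-log D(fake)] over both levels."""
    feat_fake = _scores(dfeat_fake, "dfeat_fake")
    pix_fake = _scores(dpix_fake, "dpix_fake")
    return _bce_real(feat_fake) + _bce_real(pix_fake)


def cycle_loss(x_s: ArrayOrTensor, x_t: ArrayOrTensor,
               recon_s: ArrayOrTensor, recon_t: ArrayOrTensor) -> Tensor:
    """L1 reconstruction error of both round trips, summed."""
    xs, xt = astensor(x_s), astensor(x_t)
    rs, rt = astensor(recon_s), astensor(recon_t)
    _check_same_shape(xs, rs, "cycle_loss")
    _check_same_shape(xt, rt, "cycle_loss")
    return (rs - xs).abs().mean() + (rt - xt).abs().mean()


def identity_loss(x_s: ArrayOrTensor, x_t: ArrayOrTensor,
                  iden_s: ArrayOrTensor, iden_t: ArrayOrTensor) -> Tensor:
    """L1 penalty on translators altering images already in their output
    domain: ``iden_s`` is G_{T->S}(x_s), ``iden_t`` is G_{S->T}(x_t)."""
    return cycle_loss(x_s, x_t, iden_s, iden_t)


def seg_supervised_loss(pred_source: ArrayOrTensor, pred_translated: ArrayOrTensor,
                        gt_mask: ArrayOrTensor, eps: float = 1.0) -> Tensor:
    """Supervised Dice of both branches on a labeled source sample."""
    if gt_mask is None:
        raise ValueError("seg_supervised_loss: source samples must carry a ground-truth mask")
    return soft_dice_loss(pred_source, gt_mask, eps) + soft_dice_loss(pred_translated, gt_mask, eps)


def consistency_loss(pred_target: ArrayOrTensor, pred_translated: ArrayOrTensor,
                     eps: float = 1.0) -> Tensor:
    """Dice agreement between the target branch on x_t and the source
    branch on its translation to the source domain."""
    return soft_dice_loss(pred_target, pred_translated, eps)


def total_loss(adv_s: ArrayOrTensor, adv_t: ArrayOrTensor, cycle: ArrayOrTensor,
               iden: ArrayOrTensor, seg: ArrayOrTensor, consis: ArrayOrTensor,
               weights: LossWeights = LossWeights()) -> tuple[LossReport, Tensor]:
    """Weighted total objective.

    Returns the per-term report (floats) and the total as a tensor so
    gradients can flow; the report's ``total`` equals the weighted sum of
    its terms within floating-point tolerance.
    """
    terms = {"adv_s": adv_s, "adv_t": adv_t, "cycle": cycle,
             "iden": iden, "seg": seg, "consis": consis}
    tensors = {}
    for name, value in terms.items():
        t = astensor(value)
        if t.data.size != 1:
            raise ValueError(f"total_loss: term {name} must be scalar, got shape {t.shape}")
        if not np.isfinite(t.data).all():
            raise ValueError(f"total_loss: term {name} is not finite ({float(t.data)})")
        tensors[name] = t
    total = (weights.lambda_adv * (tensors["adv_s"] + tensors["adv_t"])
             + weights.lambda_cycle * tensors["cycle"]
             + weights.lambda_iden * tensors["iden"]
             + weights.lambda_seg * tensors["seg"]
             + weights.lambda_consis * tensors["consis"])
    # the reported total is recomputed in float64 from the reported terms so
    # the report decomposes exactly (the float32 backward tensor rounds at
    # ~2e-6 for totals of magnitude ~16)
    values = {name: float(t.data) for name, t in tensors.items()}
    total_value = (weights.lambda_adv * (values["adv_s"] + values["adv_t"])
                   + weights.lambda_cycle * values["cycle"]
                   + weights.lambda_iden * values["iden"]
                   + weights.lambda_seg * values["seg"]
                   + weights.lambda_consis * values["consis"])
    report = LossReport(adv_s=values["adv_s"], adv_t=values["adv_t"], cycle=values["cycle"],
                        iden=values["iden"], seg=values["seg"], consis=values["consis"],
                        total=total_value)
    return report, total
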