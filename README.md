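# symseg-da

Bidirectional, symmetric domain adaptation for cross-site binary
ultrasound nodule segmentation — exercisable end to end on synthetic
two-domain speckle phantoms at desk scale, on one CPU.

The framework couples:

* a **bidirectional image translation module** (two ResNet-style
  translators `G_S→T`, `G_T→S` with trainable deconvolution upsampling),
* two **symmetric segmentation modules** `F_S`, `F_T` (encoder–decoder
  with skip connections and hybrid channel+spatial attention; `tiny`
  strided-conv backbone or an MBConv/squeeze-excite backbone),
* **pixel-level and feature-level adversarial alignment** (patch
  discriminators on images, classifiers on encoder bottleneck maps),
* cycle, identity, supervised soft-Dice and cross-branch **consistency
  losses**, combined by a weighted total (defaults λ_adv=λ_cycle=λ_iden=1,
  λ_seg=10, λ_consis=2),
* a **three-stage schedule**: (1) adversarial translation pretraining,
  (2) supervised segmentation on source + translated source,
  (3) joint refinement under the total objective — plus ablation
  variants (`no_translation`, `no_feature_gan`, `no_consistency`,
  `no_da`).

Since no GPU framework is assumed, all networks run on a small
reverse-mode autodiff engine written on numpy (`symseg_da.autodiff`),
verified by finite-difference tests. Everything is single-threaded and
fully deterministic given a seed.

## Synthetic two-domain phantoms

Real multi-site ultrasound data is private; the `phantom` module
generates the key property instead: identical anatomy statistics
(hypoechoic nodules with irregular boundaries on gamma-speckled tissue)
rendered under two different site styles (gamma / contrast / brightness /
blur / texture / inversion). `phantom.standard_benchmark()` returns the
standard source/target pair used by the experiments.

## CLI

```sh
symseg-da phantom  --config cfg.yaml --out DIR --seed 7    # generate PNG datasets
symseg-da train    --config run.yaml --out RUNDIR          # 3-stage schedule per pair
symseg-da ablate   --config run.yaml --out DIR --variants full,no_da
symseg-da translate --checkpoint ck.npz --direction s2t --images DIR --out DIR
symseg-da segment   --checkpoint ck.npz --branch target --images DIR --out DIR
symseg-da evaluate  --pred PRED_DIR --gt GT_DIR --out metrics.csv
```

A run config is a YAML mapping (unknown keys are rejected), e.g.

```yaml
seed: 7
network_width: 8           # tiny-scale width override
domains:
  source: {n: 210, test_count: 10, preset: clinic_a, phantom: {image_size: 64}}
  target: {n: 250, test_count: 50, preset: clinic_b,
           phantom: {image_size: 64, speckle_shape: 25.0}}
pairs: [[source, target]]
variants: [full, no_da]
schedule:
  batch_size: 8
  stage1: {epochs: 1}
  stage2: {epochs: 6}
  stage3: {epochs: 1}
```

Each run writes `metrics.csv` (per-pair PA/DSC/TPR/TNR plus an Average
row), `history.csv` (per-step loss terms and the λ weights used),
checkpoints and a `resolved-config.yaml` for provenance.

## Layout

```
src/symseg_da/
  autodiff/        numpy reverse-mode engine (tensor, conv ops, layers, Adam)
  phantom.py       two-domain speckle phantom generator
  networks/        translators, segmenters, attention, discriminators, bundle
  losses.py        adversarial / cycle / identity / Dice / consistency / total
  metrics.py       PA, DSC, TPR, TNR from pixel confusion counts
  train.py         three-stage schedule, ablations, experiments
  preprocess_io.py crop/resize/split + PNG/CSV/YAML I/O
  config.py        validated run configuration
  cli.py           `symseg-da` entry point
```
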