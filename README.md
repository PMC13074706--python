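# seedfusion

Non-destructive seed quality assessment asks two questions at once: *which
cultivar is this seed* (fine-grained, visually ambiguous between related
varieties) and *will it germinate* (invisible from the surface — the
embryo's physiological state hides under the seed coat). `seedfusion` is a
tested implementation of a dual-spectral, language-guided pipeline that
answers both jointly from paired visible (RGB) and short-wave infrared
(SWIR, 900–1700 nm) images: SWIR penetrates the coat and responds to
internal moisture/lipid state, while per-class encyclopedic text
descriptions act as semantic anchors that sharpen species discrimination,
especially with few labelled samples.

It is aimed at researchers in agricultural image analysis who want a
runnable, CPU-only reference of the architecture and its evaluation
protocols — everything runs on a built-in synthetic scene generator, so no
camera rig, dataset download or GPU is required.

## The model

Three blocks over registered, cropped RGB+IR seed pairs:

1. **Knowledge–vision alignment** — frozen image/text encoders, trainable
   projections into a joint space, `z_v = MLP_v(f_v)`, `z_t = MLP_t(f_t)`;
   symmetric InfoNCE with learnable temperature τ; cross-attention
   injection `F_sem = LayerNorm(z_v + softmax(QKᵀ/√d_k)V)` with residual
   `F_res = F_sem − z_v`.
2. **Dual-spectral fusion** — CBAM channel/spatial gating of the IR
   feature map (`M_c`, `M_s`, both sigmoid-bounded, so refinement only
   attenuates), multi-scale (1/3/5/7 px) visible aggregation, and ternary
   fusion `F_s = MLP(Concat(F_ir_att, F_vis_ms, F_res))`.
3. **Joint-learning head** — species by cosine matching of `F_sem`
   against L2-normalised per-class text prototypes (open-set: a new class
   is a new row, no new weights); viability by a 2-way softmax on `F_s`;
   objective `L = λ·L_cls + (1−λ)·L_via + L_con` with λ = 0.6.

The pipeline around the model covers checkerboard homography estimation
(normalised DLT), bilinear IR-to-RGB registration, Otsu-based ROI
extraction, synchronized dual-modal augmentation, 77-token text
serialization, confusion/AUC metrics, the N-shot protocol, and paired
fusion/component ablations. The conveyor throughput bound
`F_c = R_s / N_f`, `T_m = F_c` is included as an analytic model.

Because no GPU stack is assumed, the network layer is a compact
reverse-mode autodiff engine over numpy (`seedfusion.nn`) with
finite-difference-verified gradients; image I/O and classical vision go
through scikit-image.

## Worked example

```python
import numpy as np
from seedfusion.synthetic import (generate_manifest, DEFAULT_CLASS_COUNTS,
                                  render_scene, embryo_ir_means,
                                  ViabilitySignalSpec)
from seedfusion.throughput import min_frame_rate, min_inference_throughput

m = generate_manifest(DEFAULT_CLASS_COUNTS, seed=42)
print(f"manifest: {len(m)} seeds, {m.n_viable} viable")

rows = [r for r in m.rows if r.scene_id == "S0001"]
scene = render_scene(rows, viability_spec=ViabilitySignalSpec(0.3), seed=42)
means = embryo_ir_means(scene)
viable = [mu for mu, (_, v) in zip(means, scene.labels) if v == "viable"]
dead = [mu for mu, (_, v) in zip(means, scene.labels) if v == "non_viable"]
print(f"embryo IR mean: viable={np.mean(viable):.3f} "
      f"vs non-viable={np.mean(dead):.3f}")
print(f"bound: Fc = Tm = {min_inference_throughput(min_frame_rate(500, 50))} fps")
```

prints

```
manifest: 6005 seeds, 3077 viable
embryo IR mean: viable=0.624 vs non-viable=0.494
bound: Fc = Tm = 10.0 fps
```

The manifest reproduces the reference collection (12 classes, 6005 seeds,
3077 viable). The embryo-region infrared means separate viable from
non-viable seeds by construction (effect size 0.3 before registration
blur and noise) — a simple threshold on this statistic already reaches
≥ 99% accuracy, which is the oracle ceiling the trained model is measured
against. The throughput line says a 500 seeds/s conveyor imaged at ~50
seeds per frame needs 10 camera frames and 10 model inferences per second.

On the desk-scale synthetic study (600 seeds, 64 px crops, 20 epochs, one
CPU) the paired ablation in the test suite shows the designed modality
split: viability accuracy ≈ 0.51 for the RGB-only branch (chance — RGB
never sees the label), ≈ 0.95 for IR-only and ≈ 0.96 for ternary fusion,
while species accuracy orders the other way (RGB-only well above
IR-only). Run it yourself:

```sh
seedfusion ablate --modes rgb_only ir_only ternary --seed 1 --out results/
seedfusion synth --classes desk --per-class 5 --seed 42 --out data/
seedfusion fewshot --n 1 --n 5 --repeats 5
seedfusion throughput --rs 500 --nf 50 --measured-fps 95
```

## Layout

```
src/seedfusion/
  synthetic/      manifests, paired RGB/IR scenes, texts, checkerboards
  preprocessing/  homography, registration, ROI, normalisation,
                  augmentation, tokenizer
  nn/             numpy autodiff engine, layers, AdamW + cosine schedule
  kva.py dsf.py jlh.py model.py    the three blocks and their composition
  data.py         scenes -> registered, labelled training samples
  train_eval/     training loop, metrics, N-shot protocol, ablations
  throughput.py   conveyor bounds
  cli.py          `seedfusion` command
docs/methods.md   model, study conditions, numerical conventions
```
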