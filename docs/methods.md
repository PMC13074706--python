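# Methods

`seedfusion` implements a dual-spectral, language-guided pipeline for seed
phenotyping: joint identification of crop species and detection of seed
viability from paired visible (RGB) and short-wave infrared (SWIR) still
images, with per-class encyclopedic text descriptions injected as semantic
priors. This note documents the model, the synthetic study conditions, the
numerical choices, and what the test suite does and does not establish.

## The model

**Knowledge–vision alignment (KVA).** A frozen visual encoder and a frozen
text encoder produce features `fv` and `ft`. Trainable two-layer MLP heads
project both into a joint space of width `d`:

    zv = MLP_v(fv),   zt = MLP_t(ft)

A symmetric InfoNCE loss with learnable temperature τ aligns image–text
pairs; embeddings are L2-normalised before the similarity so that τ is
scale-meaningful. Single-head scaled dot-product cross-attention (query
`zv`; keys/values the per-class text prototypes) injects semantics:

    Fsem = LayerNorm(zv + softmax(QKᵀ/√dk) V),   Fres = Fsem − zv

The residual `Fres` carries the injected semantic increment forward into
fusion. The text side of attention defaults to pooled per-class prototype
means (mean of the projected per-description embeddings); a token-level
variant is a config option.

**Dual-spectral fusion (DSF).** The IR crop passes through a compact
convolutional backbone and is refined by CBAM-style gating: channel
weights `Mc = σ(MLP(AvgPool F) + MLP(MaxPool F))` with a shared MLP, then
spatial weights `Ms = σ(Conv7×7([AvgPool_c; MaxPool_c]))`. Both gates are
sigmoid-bounded, so refinement only attenuates — an invariant the tests
assert elementwise. The visible stem is aggregated at four receptive
fields (1/3/5/7 px kernels), concatenated, reduced 1×1 and ReLU-gated.
Ternary fusion global-average-pools both maps and maps
`MLP(Concat(Firatt, Fvisms, Fres))` to the fused vector `Fs`.

**Joint-learning head (JLH).** Species is predicted metrically — cosine
similarity of `Fsem` against the L2-normalised prototype bank — so adding
a class needs no new parameters (asserted structurally). Viability is a
2-way softmax head on `Fs`. The multi-task objective is

    L_total = λ·L_cls + (1−λ)·L_via + w_con·L_con,   λ = 0.6, w_con = 1

Cosine scores in [−1, 1] make a raw softmax nearly uniform, so `L_cls`
temperature-scales them by 1/τ (shared with the contrastive temperature);
raw cosines remain a config option. The contrastive term co-trains by
default; a two-phase align-then-task schedule is a config option.

## Scale and runtime choices

The reference-scale design (224 px crops, ResNet-18-class IR backbone,
ViT/Transformer encoders, d = 512) is impractical to train on a single
CPU, so the package ships a *desk configuration* used by all tests:
64 px crops, 16-channel convolutional branches, joint width d = 32, fusion
64→64→32, batch 16, 20 epochs. All widths are `ModelConfig` fields, so the
reference widths remain reachable. The frozen encoders are deliberately
tiny and training-free — a random-weight convolutional stem (images) and a
bag-of-embeddings encoder (text) — standing behind the same contract as
pluggable pre-trained backbones: deterministic, frozen, fixed output
width. Random frozen projections preserve colour statistics and coarse
shape linearly, which is the information the desk-scale tasks need.

Optimisation follows AdamW (β₁ = 0.9, β₂ = 0.999, weight decay 1e-4) with
cosine annealing 1e-4 → 1e-6. τ initialises at 0.07 and is clamped to
[1e-3, 100] in log-space after each step.

## The synthetic study conditions

The generator defines the conditions every stochastic test runs under; it
is not a tuning dial.

- **Manifest.** Default per-class counts reproduce the reference
  collection: 12 classes, 6005 seeds, 3077 viable / 2928 non-viable. Desk
  experiments use 50 seeds/class (600 total), 25 seeds/scene.
- **Scenes.** Seeds are ellipses on a <2%-reflectance background, grid or
  Poisson-disc layout, rendered at 1/4 of the sensor resolutions
  (612×512 RGB, 80×64 IR; full scale is a switch). Orientation jitter is
  ±15° — grid-arranged ground-truthing lays seeds roughly axis-aligned,
  and this keeps the bounding-box aspect a usable species cue.
- **Species appearance.** Each class has a distinct (aspect, colour,
  stripe) signature; colours are spaced so a nearest-centroid classifier
  on (mean colour, aspect) exceeds 95% accuracy — the generator-level
  statement that species are visually recoverable.
- **Viability signal.** Only the IR channel reads the viability label
  (unless `rgb_viability_leak > 0`, which adds surface darkening to
  emulate artificial-aging artefacts). The embryo — the central concentric
  ellipse covering 25% of seed area — has mean intensity 0.78 for viable
  seeds, depressed by `effect_size` (default 0.3) for non-viable ones,
  plus per-pixel Gaussian noise (σ = 0.01). The real IR contrast between
  viable and non-viable seeds is not quantified anywhere we can cite;
  0.3 was fixed once as a plainly-recoverable signal (a threshold on the
  embryo-region mean separates classes at ≥99%) and is a free parameter,
  not an estimate of nature.
- **Geometry.** The true IR→RGB homography is scale-dominated
  (≈7.65×/8×) with small translation and mild projective terms. The
  pipeline never uses it directly: registration estimates a homography
  from a rendered 10×7 checkerboard via Hartley-normalised DLT (no RANSAC
  — calibration corners are clean) and reprojection error propagates.

What the generator does **not** emulate: physically-based optics,
photorealistic seed texture, conveyor motion blur, illumination drift,
occlusion or seed stacking. Passing tests therefore demonstrate that the
architecture recovers the signals the generator encodes under realistic
resolution/registration/noise conditions — not field performance on real
seed lots.

## Preprocessing

Boxes are 0-based half-open; coordinates are (x, y) = (column, row).
Otsu's threshold is computed on **log**-luma: with a background-heavy
histogram and seed coats spanning jet black to cream, linear-domain Otsu
settles mid-foreground and drops dark classes, while log compression
restores the background/foreground bimodality. Closing uses a 5×5 square
element; components under 25 px are noise. The 10 px box margin is defined
at full sensor resolution and scaled with the frame (min 2 px). RGB crops
are z-scored with the canonical ImageNet statistics; the IR channel (which
has none) uses dataset-level statistics with a 0.5/0.25 fallback for
unit-scale synthetic data. Augmentation samples one geometric transform
per pair (flips p = 0.5, rotation ±15°, scale 0.8–1.2) applied identically
to both modalities; brightness/contrast jitter (±10%) touches RGB only and
Gaussian noise (σ = 0.01) IR only. The tokenizer is a deterministic
word-level vocabulary with character-piece fallback, total over any ASCII
input, emitting [CLS]/[SEP]-framed, 77-token padded id/mask pairs; a
pre-trained tokenizer can be plugged in.

## Evaluation harnesses

Metrics follow the confusion identities with macro averaging for
multi-class and the 0/0 → 0 convention (logged). AUC is the Mann–Whitney
rank statistic, cross-checked in tests against trapezoidal ROC integration
and an independent library. The desk harness uses a stratified 70/15/15
split (scene-level splitting is available and used where leakage matters);
five-fold cross-validation is a config option not exercised by default
for runtime. The N-shot protocol draws N ∈ {1, 5, 10, 20} per class, five
repeats, reporting mean ± sd; adaptation trains only projection heads,
attention and temperature over precomputed frozen features. Ablations
(rgb_only / ir_only / early / late / ternary; full / no_kva / no_dsf /
baseline) share seeds, splits and schedules, so comparisons are paired.
Early fusion stacks registered IR as a fourth input channel through a
widened stem; late fusion averages post-softmax probabilities. When KVA is
ablated, species prediction falls back to a class-sized linear head
(deliberately losing the open-set property).

## Numerical and degenerate-case conventions

- (a−b)+b ≠ a in floating point, so the attention block recomposes
  `Fsem := zv + Fres` after computing the residual, making
  `Fres + zv = Fsem` bitwise.
- Softmax/log-softmax subtract a detached rowwise max for stability.
- `max`-reductions split gradient evenly across ties.
- Empty frames yield empty ROI lists, not errors; an all-constant frame
  short-circuits before Otsu.
- A non-finite training loss aborts with a diagnostic rather than
  continuing.
- Temperature positivity is structural (log-parameterisation) and bounded
  by clamping.

## Known limitations

- The frozen desk encoders are random projections; absolute species
  accuracy at desk scale (≈0.3 over 12 classes) is far below what
  pre-trained encoders reach, and the suites therefore assert *relative*
  contrasts (modality margins, monotonicity, recoverability) rather than
  absolute headline accuracies.
- The numpy training stack is single-threaded and desk-sized; it is not a
  performance baseline.
- Viability is binary; continuous vigor grading is out of scope.
- The throughput model is analytic; measured fps is reported by the CLI
  but is hardware-dependent and never used as a pass/fail criterion.
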