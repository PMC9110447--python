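# Methods

## Problem

Surgical workflow recognition assigns one of P predefined phases (e.g.
*preparation*, *calot triangle dissection*, …) to every frame of an untrimmed
laparoscopic video.  `surgphase` implements a *causal* pipeline — predictions
at time t use only frames ≤ t — so the same model is usable both
intra-operatively and for post-operative review.  The design premise is
data-centric: dense phase labels are cheap, pixel-wise scene segmentation
(anatomy + instruments) is expensive and therefore exists only for a very
small fraction of frames (< 5%).  A simple model that *jointly* exploits both
annotation streams can match far more complex phase-only architectures.

## Model

### Multi-task frame encoder

A residual-network backbone of depth 18/50/152, with the final residual stage
removed, produces shared features f_B.  Each task branch owns its *own copy*
of that final stage:

* **scene branch** — scene head S(f_B) → f_S, then a segmentation module:
  ×4 bilinear upscale, 3×3 conv + batch-norm reducing channels four-fold
  (2048 → 512 at depth 50), ReLU, 1×1 conv to S classes, bilinear upscale to
  the exact input resolution, softmax.  Trained with pixel-wise cross-entropy
  **on annotated frames only**; frames without masks contribute exactly zero
  loss and zero gradient.
* **phase branch** — phase head P(f_B) → f_P; branch features are fused,
  global-average-pooled, and classified by a fully connected layer + softmax.
* **instrument branch** (optional) — a third head supervised with frame-level
  instrument-presence bits through a sigmoid; mirrors the phase branch.

**Fusion.**  The default is fast normalised fusion

    f = Σ_i  ReLU(α_i) / (Σ_j ReLU(α_j) + ε) · f_i ,   ε = 1e-4,

with one learnable scalar per branch, all initialised to 1 (symmetric start).
The coefficients are non-negative and sum to < 1, approaching 1 as
Σ ReLU(α) → ∞.  Two convolutional alternatives are provided for ablation:
concatenation + 1×1 conv + batch-norm, and per-branch 1×1 conv + batch-norm +
ReLU before concatenation; an optional skip connection adds the pre-fusion
f_P to the fused map (identity addition — shapes match by construction).

The joint objective is the unweighted sum L = L_S + L_P (+ L_I).  Batch-norm
statistics are updated in a single joint forward/backward pass.  f_S enters
the fusion *before* the segmentation module's upscaling, which is what makes
it shape-compatible with f_P.

### Temporal model

Per-frame fused features (global-average-pooled, taken before the fully
connected layer) feed a two-stage dilated causal temporal convolutional
network: each stage is a 1×1 input projection, L dilated residual layers
(kernel k, dilation 2^i, causal left padding (k−1)·2^i), and a 1×1 output
projection + softmax; stage s > 1 refines the *softmax probabilities* of
stage s−1.  There is no pooling and no fully connected layer, so parameters
are independent of sequence length.  The closed-form receptive field is
1 + (k−1)(2^L − 1) per stage and 1 + num_stages·(k−1)·(2^L − 1) in total.

The temporal loss per stage is cross-entropy plus a truncated MSE with
clamping bound c = 4, summed over stages:

    L_T = Σ_s [ CE(y, ŷ_s) + mean_{t,p} clamp(onehot(y) − ŷ_s, 0, c)² ].

The truncation is applied to the annotation-minus-prediction *difference*
before squaring (the operator acts on the difference in the formula as
written); since the difference lies in [−1, 1], the term penalises only
under-confidence in the true class.  Two alternative readings are selectable
(`square_then_clamp`, and the consecutive-frame log-probability smoothing
used by earlier multi-stage TCN work, weighted 0.15); the default is
as-written.  All stages are supervised and summed, the multi-stage
convention.

## Training procedure

1. **Encoder** — SGD with momentum 0.9 and weight decay 0.001; one-cycle
   schedule (30% cosine warm-up from peak/25, cosine decay to peak/10⁴) with
   peak learning rate 0.05·B/256, recomputed from the batch size; a
   class-balanced sampler drawing exactly `samples_per_class` frames per
   phase per epoch (without replacement when the class pool suffices);
   horizontal flip + ±15° rotation (masks receive the identical geometric
   transform, nearest-neighbour) and ±20% brightness/contrast/saturation
   jitter (image only).  The *last* epoch's weights are kept — no
   validation-based selection.  Full-scale defaults: batch 128, 40 epochs,
   2000 samples per class (= 14,000 frames/epoch for 7 phases).
2. **Feature extraction** — the encoder is frozen (eval mode, running
   batch-norm statistics) and the fused GAP feature is written for every
   frame at the working frame rate (1 fps).
3. **Temporal model** — whole-video sequences, SGD (same momentum/decay) at
   a fixed 3e-4 learning rate (whole-video gradients are an order of
   magnitude denser than frame batches; larger rates diverge under
   momentum).

Scale jitter is deliberately omitted from the augmentations: at the small
image sizes used for CPU-scale experiments, rescaling index masks degrades
mask fidelity disproportionately.  Cross-validation plumbing keeps
mask-bearing videos pinned to the training side of every fold.

## Synthetic benchmark

The generator emulates the *structure* of the real task, not its appearance:
videos traverse phases in canonical order with Gaussian dwell lengths
(minimum dwell 5 frames, last phase absorbing the remainder); each frame is
a textured background, up to three slowly drifting elliptical "anatomy"
blobs, and up to two fast-moving elongated "instrument" bars.  Which object
classes are visible is a deterministic function of the phase, so phase
identity is recoverable exactly from segmentation-level information.
Crucially, all anatomy classes share one per-video tissue tone and all
instruments one metallic tone (plus per-video jitter, per-pixel Gaussian
noise and global illumination jitter), while classes differ by *consistent
shape geometry* — so global colour statistics do not identify the visible
objects, and pixel-level supervision carries usable signal that phase labels
alone surface more slowly.  Dense ground-truth masks exist for every frame;
only `round(mask_fraction · T)` frames per mask-bearing video are exposed as
annotation, and mask-bearing videos are pinned to the training split.

What the synthetic study shows, and what it cannot.  The temporal claim is
robust at desk scale: the causal TCN reliably collapses dozens of spurious
frame-wise phase transitions per video to near the true segment count while
raising accuracy, across every seed tried.  The supervision claim is only
partially reproducible at this scale: linear probes on the global-average-
pooled branch features consistently show that sparse-mask training improves
the learned representation (a few points of probe accuracy), but the
*end-to-end* F1 margin between the multi-task and phase-only encoders is
within seed-to-seed noise after five epochs from scratch.  Two structural
reasons: the full-scale recipe fine-tunes a pretrained backbone for 40
epochs on tens of thousands of real frames with thousands of masks, whereas
here both encoders start cold; and in any generator where the phase
determines scene content exactly, the plentiful phase labels already carry
the information the few masks teach, so the auxiliary loss buys little that
five epochs can cash in.  The package reports the measured comparison
rather than claiming the full-scale result, and none of this bears on real
laparoscopic video, which also differs in appearance statistics, occlusion,
class imbalance and annotation noise.

## Study conditions (scaled-down supervision study)

30 videos × 120 frames at 64×48, P = 5 phases, S = 6 scene classes, masks on
5% of frames of the 10 mask-bearing videos (pinned into the 20-video
training split); depth-18 backbone at base_width 8 (branch channels 64) with
the stem max-pool disabled (`stem_pool=False`) — at 64×48 the standard
stride-32 stem leaves the scene feature map at 2×2, where the segmentation
branch degenerates to predicting background everywhere; the stride-16 stem
restores enough resolution for the scene branch to learn;
batch 64, 5 epochs of 600 balanced samples per class with both augmentation
families on; two-stage TCN with 6 layers per stage and 32 hidden channels,
25 epochs.  These sizes keep a seeded run to a few minutes on one CPU core.
Augmentation matters here for the same reason it does at full scale: colour
jitter suppresses global-colour shortcuts, so the shape-level discrimination
that pixel supervision teaches is what differentiates the encoders.  The
phase-only baseline is the *same architecture* trained with L_P alone, so
the comparison isolates the effect of the sparse supervision signal.  Both
directional outcomes (multi-task F1 > phase-only F1; TCN transitions ≤
frame-wise transitions) are evaluated over three seeds with a ≥ 2-of-3
majority rule.

## Numerical choices

* Model weights and activations in float32 (about 2× CPU throughput at these
  sizes); the autodiff engine itself is dtype-agnostic and float64 by
  default, which is what the finite-difference gradient checks use.
  Python-scalar constants are kept "weak" so float32 graphs never silently
  upcast.
* Weight init He-normal (fan-out) for convolutions,
  uniform ±1/√fan_in for fully connected layers, drawn from one
  `numpy.random.Generator` per model seed in construction order.
* Bilinear interpolation uses the non-corner-aligned convention
  (`src = (dst + 0.5)·scale − 0.5`, clipped), implemented as separable
  row-stochastic resampling matrices; the final scene upscale always targets
  exactly the input resolution, so non-divisible-by-32 inputs (e.g. 400×300)
  are handled by floor-arithmetic downsampling and exact upsampling.
* Cross-entropy is computed as −log(p + 1e-12) on softmax outputs.
* clamp propagates gradient only strictly inside (0, c).
* Batch-norm: batch statistics in training, running statistics (momentum
  0.1) in evaluation.  By default the segmentation decoder (and hence its
  batch-norm) is evaluated only on annotated frames, where its loss is
  defined; `TrainConfig.scene_decoder_on_all` switches to running it on the
  whole batch, which couples annotated and unannotated frames through the
  batch statistics.  The scene *head* always runs on every frame, since the
  phase branch fuses its features.
* Degenerate inputs: all fusion alphas negative yields the all-zero fused
  map (ε guards the division); a batch with no annotated frame yields a
  constant-zero scene loss outside the autodiff graph; a T = 1 sequence is
  valid for the TCN.

## Known limitations

* The NumPy networks are CPU-scale research code: fine for the desk-scale
  study and unit verification, not for 400×300 × 40-epoch training.
* No pre-trained backbone weights are bundled; `pretrained_init` loads a
  user-supplied checkpoint instead of downloading one.
* No dropout in the temporal stages and no label smoothing, keeping runs
  bit-reproducible.
* The balanced sampler assumes every phase class occurs in the training
  pool and fails loudly otherwise.
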