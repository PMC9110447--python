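# surgphase

Causal surgical phase estimation from laparoscopic video, driven by a
data-centric idea: dense per-frame phase labels are cheap, pixel-wise scene
segmentation (anatomy + instruments) is expensive and therefore exists only
for a tiny fraction of frames — yet a simple model that *jointly* learns both
can beat far more elaborate phase-only architectures.

## Who this is for

Researchers in surgical workflow recognition / surgical data science who want
a self-contained, CPU-runnable reference implementation of the
sparse-supervision multi-task pipeline: encoder, losses, temporal model,
training orchestration, metrics, and a synthetic benchmark that exercises
every stage without access to the clinical datasets.

## The model

**Multi-task encoder.**  A residual backbone (depth 18/50/152) without its
final residual stage produces shared features f_B; task branches each own a
copy of that final stage.  The scene branch decodes f_S into a pixel-wise
segmentation Ŝ (×4 bilinear upscale → 3×3 conv+BN with a 4× channel reduction,
2048→512 at depth 50 → ReLU → 1×1 conv to S classes → upscale to input
resolution → softmax) and is supervised **only on annotated frames**.  The
phase branch fuses f_S and f_P by *fast normalised fusion*

&nbsp;&nbsp;&nbsp;&nbsp; f = Σᵢ ReLU(αᵢ)/(Σⱼ ReLU(αⱼ) + ε) · fᵢ ,  ε = 10⁻⁴,

with learnable scalars αᵢ, then GAP → FC → softmax gives P̂.  The joint loss
is L = L_S + L_P (+ L_I for an optional instrument-presence branch).
Concatenation-based fusion variants and a phase-feature skip connection are
available for ablation.

**Temporal model.**  Frozen-encoder per-frame features feed a two-stage
dilated *causal* TCN (dilations 2ⁱ, left padding, no pooling or FC layers);
stage s refines the softmax of stage s−1.  Training uses cross-entropy plus a
truncated MSE, clamp bound c = 4:

&nbsp;&nbsp;&nbsp;&nbsp; L_T = Σ_s CE(y, ŷ_s) + mean clamp(onehot(y) − ŷ_s, 0, c)².

All networks are implemented on a compact NumPy reverse-mode autodiff engine
(`surgphase.autodiff` / `surgphase.nn`) — no GPU framework required.

## Worked example

Train the whole pipeline on the built-in synthetic benchmark (30 videos ×
120 frames, 5 phases, 6 scene classes, masks on 5 % of the frames of the 10
mask-bearing training videos):

```python
from surgphase import benchmark
result = benchmark.run_seed(seed=0)
for k in ("f1_phase_only", "f1_multitask", "accuracy_tcn", "f1_tcn",
          "transitions_framewise", "transitions_tcn", "transitions_true"):
    print(f"{k:24s} {result[k]:.3f}")
```

```
f1_phase_only            0.615
f1_multitask             0.504
accuracy_tcn             0.792
f1_tcn                   0.791
transitions_framewise    35.200
transitions_tcn          6.000
transitions_true         4.000
```

Reading: the frame-wise encoder alone is noisy (F1 ≈ 0.5–0.6 on this run,
with ~35 spurious phase transitions per test video); the causal TCN on its
frozen features reaches 0.79 accuracy/F1 and collapses the transitions to 6
(the true videos average 4.0) — temporal smoothing without using future
frames, the pipeline's robust effect at this scale.  The run also reports
the multi-task vs phase-only encoder comparison; after five epochs from
scratch that margin is within seed-to-seed noise (here the phase-only
encoder happens to be ahead), which `docs/methods.md` discusses in detail.
A run takes a few minutes on one CPU core.

The same pipeline is scriptable from the shell:

```bash
surgphase synth-generate --config cfg.yaml --out data/ --seed 0
surgphase run-all        --config cfg.yaml --out run/  --seed 0
surgphase evaluate --pred run/predictions --data data/ --out report.json
```

Real datasets are consumed through the same readers: frames as PNG, phase
annotations as `frame<TAB>phase-name` TSV (25 fps files are subsampled to
1 fps), masks as class-index PNG, instrument presence as binary TSV columns.
`surgphase.io.ClassCatalog.cholec80()` ships the standard 7-phase /
13-scene-class catalog.

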