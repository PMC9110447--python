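"""Two-stage training orchestration.

Stage 1 trains the multi-task encoder on class-balanced frame batches with
the joint loss L = L_S + L_P (+ L_I); the weights of the *last* epoch are
kept, with no validation-based selection.  Stage 2 freezes the encoder,
extracts the fused per-frame feature for every frame of every video, and
trains the temporal model on whole-video sequences with the truncated-MSE
temporal loss.

The balanced sampler draws exactly ``samples_per_class`` frames per phase
class each epoch (without replacement when the class pool suffices, with
replacement otherwise).  The learning rate follows a single-cycle schedule —
cosine warm-up to ``0.05 * B / 256`` then cosine decay toward zero.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from . import encoder as enc
from . import losses
from . import nn
from .io import VideoRecord
from .losses import UNLABELLED, ClampSpec
from .temporal import TCN, TCNConfig
from .autodiff import Tensor


@dataclasses.dataclass
class TrainConfig:
    """Optimisation hyperparameters; defaults follow the full-scale recipe
    (SGD momentum 0.9, weight decay 0.001, batch 128, 40 epochs, 2000 balanced
    samples per class, one-cycle schedule peaking at 0.05*B/256)."""

    batch_size: int = 128
    epochs: int = 40
    momentum: float = 0.9
    weight_decay: float = 0.001
    samples_per_class: int = 2000
    seed: int = 0
    augment_geometric: bool = True
    augment_colour: bool = True
    warmup_fraction: float = 0.3
    div_factor: float = 25.0       # initial lr = max_lr / div_factor
    final_div_factor: float = 1e4  # final lr = max_lr / final_div_factor
    tcn_epochs: int = 25
    tcn_lr: float = 3e-4
    tcn_loss_variant: str = "clamp_then_square"
    clamp_c: float = 4.0
    scene_decoder_on_all: bool = False

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @property
    def max_lr(self) -> float:
        """Peak learning rate, recomputed from the batch size each access."""
        return 0.05 * self.batch_size / 256.0


@dataclasses.dataclass
class EpochSample:
    """Ordered (video id, frame index) draws for one epoch — exactly
    ``samples_per_class`` occurrences of every phase class."""

    pairs: list

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def balanced_sample_indices(phase_labels: dict, samples_per_class: int,
                            seed, num_classes: int | None = None) -> EpochSample:
    """Class-balanced epoch sample over a pool of per-frame phase labels.

    ``phase_labels`` maps video id -> (T,) integer labels.  Every class in
    ``range(num_classes)`` must occur in the pool; classes with fewer than
    ``samples_per_class`` frames are drawn with replacement.
    """
    pools: dict[int, list] = {}
    max_label = -1
    for vid, labels in phase_labels.items():
        labels = np.asarray(labels, dtype=int)
        max_label = max(max_label, int(labels.max(initial=-1)))
        for idx, lab in enumerate(labels):
            pools.setdefault(int(lab), []).append((vid, idx))
    if num_classes is None:
        num_classes = max_label + 1
    rng = np.random.default_rng(seed)
    chosen = []
    for c in range(num_classes):
        pool = pools.get(c, [])
        if not pool:
            raise ValueError(f"phase class {c} is absent from the sampling pool")
        if len(pool) >= samples_per_class:
            picks = rng.choice(len(pool), size=samples_per_class, replace=False)
        else:
            picks = rng.choice(len(pool), size=samples_per_class, replace=True)
        chosen.extend(pool[i] for i in picks)
    order = rng.permutation(len(chosen))
    return EpochSample([chosen[i] for i in order])


def lr_at(step: int, total_steps: int, config: TrainConfig) -> float:
    """Single-cycle schedule: cosine warm-up to the peak, cosine decay to
    ~zero.  The peak value 0.05*B/256 is attained exactly at the end of the
    warm-up."""
    if not 0 <= step < total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps})")
    peak = config.max_lr
    warm = max(int(round(config.warmup_fraction * total_steps)), 1)
    warm = min(warm, total_steps - 1) if total_steps > 1 else 0
    if total_steps == 1:
        return peak
    if step <= warm:
        start = peak / config.div_factor
        return float(start + (peak - start) * 0.5 * (1 - np.cos(np.pi * step / warm)))
    final = peak / config.final_div_factor
    frac = (step - warm) / (total_steps - 1 - warm)
    return float(final + (peak - final) * 0.5 * (1 + np.cos(np.pi * frac)))


# ---------------------------------------------------------------------------
# data augmentation (geometric transforms shared with the mask)
# ---------------------------------------------------------------------------

def augment_frame(image: np.ndarray, mask: np.ndarray | None,
                  rng: np.random.Generator, geometric: bool = True,
                  colour: bool = True):
    """Horizontal flip + small rotation (shared with the mask, nearest
    interpolation) and brightness/contrast/saturation jitter (image only)."""
    img = image.astype(np.float64)
    if geometric:
        if rng.random() < 0.5:
            img = img[:, ::-1]
            if mask is not None:
                mask = mask[:, ::-1]
        angle = rng.uniform(-15.0, 15.0)
        img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False,
                             order=1, mode="nearest")
        if mask is not None:
            mask = ndimage.rotate(mask, angle, axes=(0, 1), reshape=False,
                                  order=0, mode="constant", cval=UNLABELLED)
    if colour:
        brightness = rng.uniform(0.8, 1.2)
        contrast = rng.uniform(0.8, 1.2)
        saturation = rng.uniform(0.8, 1.2)
        mean = img.mean()
        img = (img - mean) * contrast + mean
        grey = img.mean(axis=-1, keepdims=True)
        img = grey + (img - grey) * saturation
        img = img * brightness
    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, (mask.copy() if mask is not None and mask.base is not None else mask)


# ---------------------------------------------------------------------------
# encoder training
# ---------------------------------------------------------------------------

def _encoder_step(model: enc.Encoder, images, masks, annotated, phase_ann,
                  presence, phase_only: bool, decoder_on_all: bool = False):
    """One joint forward/backward pass; returns (loss Tensor, L_S, L_P, L_I).

    The scene head always runs on the whole batch (the phase branch fuses its
    features).  The segmentation decoder itself runs on the annotated frames
    only by default; ``decoder_on_all`` runs it on the whole batch instead, in
    which case its batch-norm statistics couple annotated and unannotated
    frames.  Either way the loss sees only annotated frames' masks.
    """
    x = model.preprocess(images)
    out_hw = (x.data.shape[2], x.data.shape[3])
    f_b = model.forward_backbone(x)
    f_s = model.scene_head(f_b)
    sel = np.flatnonzero(annotated)
    if sel.size and not phase_only:
        from . import autodiff as ad
        if decoder_on_all:
            seg = model.scene_module(f_s, out_hw)
            l_s = losses.scene_loss(seg, masks, annotated)
        else:
            seg = model.scene_module(ad.take(f_s, sel, axis=0), out_hw)
            l_s = losses.scene_loss(seg, masks[sel], np.ones(sel.size, dtype=bool))
    else:
        l_s = Tensor(0.0)
    f_i = None
    l_i = None
    if model.config.num_instruments > 0:
        f_i, pres_pred = model.forward_instrument(f_b)
        if presence is not None and not phase_only:
            l_i = losses.instrument_loss(pres_pred, presence)
    _, phase = model.forward_phase(f_b, f_s, f_i)
    l_p = losses.phase_loss(phase, phase_ann)
    total = losses.encoder_loss(l_s, l_p, l_i)
    return total, float(l_s.data), float(l_p.data), \
        (float(l_i.data) if l_i is not None else None)


def train_encoder(videos: list[VideoRecord], encoder_config: enc.EncoderConfig,
                  config: TrainConfig, phase_only: bool = False,
                  log_fn=None, init_model: "enc.Encoder | None" = None):
    """Class-balanced multi-task encoder training.

    ``phase_only=True`` trains the same architecture with L_P alone (no scene
    or instrument supervision) — the single-task baseline.  ``init_model``
    continues training from an existing encoder (warm start / fine-tuning)
    instead of a fresh initialisation.  Returns (encoder, per-epoch log).
    The last epoch's weights are the result; no validation-based selection is
    performed.
    """
    if not videos:
        raise ValueError("empty dataset")
    model = init_model if init_model is not None else enc.build_encoder(encoder_config)
    model.train()
    labels = {v.video_id: v.phase_labels for v in videos}
    byid = {v.video_id: v for v in videos}
    opt = nn.SGD(model.parameters(), lr=0.0, momentum=config.momentum,
                 weight_decay=config.weight_decay)
    steps_per_epoch = int(np.ceil(
        config.samples_per_class * encoder_config.num_phases / config.batch_size))
    total_steps = config.epochs * steps_per_epoch
    epoch_log = []
    step = 0
    w, h = encoder_config.input_size
    for epoch in range(config.epochs):
        sample = balanced_sample_indices(labels, config.samples_per_class,
                                         seed=[config.seed, epoch],
                                         num_classes=encoder_config.num_phases)
        aug_rng = np.random.default_rng([config.seed, epoch, 1])
        ls_sum = lp_sum = li_sum = 0.0
        n_steps = 0
        pairs = list(sample)
        for start in range(0, len(pairs), config.batch_size):
            batch = pairs[start:start + config.batch_size]
            images = np.empty((len(batch), h, w, 3), dtype=np.uint8)
            batch_masks = np.full((len(batch), h, w), UNLABELLED, dtype=np.int64)
            annotated = np.zeros(len(batch), dtype=bool)
            phase_ann = np.empty(len(batch), dtype=int)
            presence = None
            for j, (vid, idx) in enumerate(batch):
                v = byid[vid]
                img = v.frames[idx]
                mask = v.masks.get(idx)
                if config.augment_geometric or config.augment_colour:
                    img, mask = augment_frame(img, mask, aug_rng,
                                              config.augment_geometric,
                                              config.augment_colour)
                images[j] = img
                if mask is not None:
                    batch_masks[j] = mask
                    annotated[j] = True
                phase_ann[j] = v.phase_labels[idx]
                if v.instrument_presence is not None:
                    if presence is None:
                        presence = np.zeros((len(batch),
                                             v.instrument_presence.shape[1]))
                    presence[j] = v.instrument_presence[idx]
            opt.lr = lr_at(step, total_steps, config)
            opt.zero_grad()
            total, l_s, l_p, l_i = _encoder_step(
                model, images, batch_masks, annotated, phase_ann, presence,
                phase_only, decoder_on_all=config.scene_decoder_on_all)
            total.backward()
            opt.step()
            ls_sum += l_s
            lp_sum += l_p
            li_sum += l_i or 0.0
            n_steps += 1
            if log_fn is not None:
                log_fn({"event": "step", "epoch": epoch, "step": step,
                        "L_S": l_s, "L_P": l_p, "L": float(total.data),
                        "lr": opt.lr})
            step += 1
        rec = {"event": "epoch", "epoch": epoch, "L_S": ls_sum / n_steps,
               "L_P": lp_sum / n_steps, "L": (ls_sum + lp_sum + li_sum) / n_steps}
        epoch_log.append(rec)
        if log_fn is not None:
            log_fn(rec)
    model.eval()
    return model, epoch_log


def extract_features(model: enc.Encoder, videos: list[VideoRecord],
                     batch_size: int = 32) -> dict:
    """Frozen-encoder per-frame fused features, video id -> (T, D)."""
    model.eval()
    out = {}
    for v in videos:
        feats = []
        for start in range(0, v.num_frames, batch_size):
            batch = v.frames[start:start + batch_size]
            feats.append(enc.extract_frame_feature(model, batch))
        out[v.video_id] = np.concatenate(feats, axis=0)
    return out


def train_tcn(features: dict, labels: dict, tcn_config: TCNConfig,
              config: TrainConfig, log_fn=None):
    """Whole-video temporal-model training with the truncated-MSE loss."""
    model = TCN(tcn_config)
    opt = nn.SGD(model.parameters(), lr=config.tcn_lr, momentum=config.momentum,
                 weight_decay=config.weight_decay)
    spec = ClampSpec(config.clamp_c)
    rng = np.random.default_rng([config.seed, 7])
    vids = sorted(features)
    epoch_log = []
    for epoch in range(config.tcn_epochs):
        order = rng.permutation(len(vids))
        loss_sum = 0.0
        for i in order:
            vid = vids[i]
            opt.zero_grad()
            stage_preds = model(features[vid])
            loss = losses.tcn_loss(stage_preds, labels[vid], spec,
                                   variant=config.tcn_loss_variant)
            loss.backward()
            opt.step()
            loss_sum += float(loss.data)
        rec = {"event": "tcn_epoch", "epoch": epoch, "L_T": loss_sum / len(vids)}
        epoch_log.append(rec)
        if log_fn is not None:
            log_fn(rec)
    model.eval()
    return model, epoch_log


def predict_videos(model: TCN, features: dict) -> dict:
    """Final-stage per-frame predictions: video id -> (argmax ids, probs)."""
    model.eval()
    out = {}
    for vid, feats in features.items():
        probs = model(feats)[-1].data
        out[vid] = (probs.argmax(axis=1), probs)
    return out


def run_two_stage(train_videos: list[VideoRecord], test_videos: list[VideoRecord],
                  encoder_config: enc.EncoderConfig, tcn_config: TCNConfig,
                  config: TrainConfig, phase_only: bool = False,
                  out_dir=None, log_fn=None) -> dict:
    """Full pipeline: encoder training, frozen feature extraction, temporal
    training, per-video prediction.  Returns every artefact in a dict."""
    model, enc_log = train_encoder(train_videos, encoder_config, config,
                                   phase_only=phase_only, log_fn=log_fn)
    all_videos = list(train_videos) + list(test_videos)
    feats = extract_features(model, all_videos)
    train_labels = {v.video_id: v.phase_labels for v in train_videos}
    tcn, tcn_log = train_tcn({v.video_id: feats[v.video_id] for v in train_videos},
                             train_labels, tcn_config, config, log_fn=log_fn)
    preds = predict_videos(tcn, feats)
    # frame-wise encoder argmax (no temporal model), for smoothing comparisons
    frame_preds = {}
    for v in all_videos:
        probs = []
        for start in range(0, v.num_frames, 32):
            out = model.forward(v.frames[start:start + 32], with_scene=True,
                                with_seg=False)
            probs.append(out["phase"].data)
        frame_preds[v.video_id] = np.concatenate(probs).argmax(axis=1)
    if out_dir is not None:
        from pathlib import Path

        from . import io as sio
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for vid, (ids, probs) in preds.items():
            sio.write_predictions(out_dir / f"{vid}.tsv", ids, probs)
    return {"encoder": model, "tcn": tcn, "features": feats,
            "predictions": preds, "frame_predictions": frame_preds,
            "encoder_log": enc_log, "tcn_log": tcn_log}


def make_cv_folds(video_ids: list, n_folds: int, n_test: int, pinned: set,
                  seed) -> list:
    """Cross-validation folds with ``pinned`` video ids always on the training
    side (the mask-bearing videos).  Returns [(train_ids, test_ids), ...]."""
    pinned = set(pinned)
    free = [v for v in video_ids if v not in pinned]
    if n_test > len(free):
        raise ValueError(f"cannot hold out {n_test} videos: only {len(free)} "
                         "are not pinned to training")
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(n_folds):
        test = set(rng.choice(len(free), size=n_test, replace=False).tolist())
        test_ids = [free[i] for i in sorted(test)]
        train_ids = [v for v in video_ids if v not in set(test_ids)]
        folds.append((train_ids, test_ids))
    return folds
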