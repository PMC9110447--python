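"""Training objectives.

* ``scene_loss`` — pixel-wise cross-entropy over annotated frames only; frames
  without a segmentation annotation contribute nothing (loss and gradients are
  exactly zero for a batch with no annotated frame).
* ``phase_loss`` — mean frame-level cross-entropy on softmax outputs.
* ``instrument_loss`` — mean per-instrument binary cross-entropy.
* ``encoder_loss`` — unweighted sum L = L_S + L_P (+ L_I).
* ``tcn_loss`` — per temporal stage, cross-entropy plus a truncated
  mean-squared error, summed over stages.  The truncation clamps the
  annotation-minus-prediction difference to [0, c] before squaring; c = 4 by
  default.  Alternative readings of the truncated term are selectable.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

UNLABELLED = -1  # sentinel class id for pixels without annotation
_LOG_EPS = 1e-12

TCN_LOSS_VARIANTS = ("clamp_then_square", "square_then_clamp", "smooth_logprob")


@dataclasses.dataclass
class ClampSpec:
    """Truncation bounds of the temporal MSE term: values clipped to [0, c]."""

    c: float = 4.0

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("maximum clamping value c must be positive")


def clamp(x, spec: ClampSpec = ClampSpec()):
    """Elementwise min(max(x, 0), c); works on arrays and graph tensors."""
    if isinstance(x, Tensor):
        return ad.clamp(x, 0.0, spec.c)
    return np.clip(np.asarray(x, dtype=float), 0.0, spec.c)


def _one_hot(labels: np.ndarray, num_classes: int, dtype=float) -> np.ndarray:
    out = np.zeros((labels.size, num_classes), dtype=dtype)
    out[np.arange(labels.size), labels.reshape(-1)] = 1.0
    return out


def phase_loss(pred, annotations) -> Tensor:
    """Mean cross-entropy of per-frame phase distributions.

    pred: (N, P) row-stochastic; annotations: (N,) integer class ids.
    """
    pred = ad.astensor(pred)
    ann = np.asarray(annotations, dtype=int)
    n, p = pred.data.shape
    if ann.shape != (n,):
        raise ValueError(f"annotation shape {ann.shape} does not match batch {n}")
    if ann.min() < 0 or ann.max() >= p:
        raise ValueError(f"phase id out of range [0,{p}): {ann.min()}..{ann.max()}")
    onehot = _one_hot(ann, p, pred.data.dtype)
    return ad.mul(ad.sum_(ad.mul(ad.log(pred, _LOG_EPS), onehot)), -1.0 / n)


def scene_loss(seg, masks, annotated) -> Tensor:
    """Sparse-masked segmentation cross-entropy.

    seg: (N, S, H, W) per-pixel class distributions; masks: (N, H, W) integer
    class ids with ``UNLABELLED`` for unlabelled pixels; annotated: (N,) bool
    flags.  Only annotated frames' labelled pixels enter the mean; a batch with
    no annotated frame returns the constant 0 with no gradient graph.
    """
    seg = ad.astensor(seg)
    masks = np.asarray(masks)
    annotated = np.asarray(annotated, dtype=bool)
    n, s = seg.data.shape[:2]
    if masks.shape != (n,) + seg.data.shape[2:]:
        raise ValueError(f"mask shape {masks.shape} does not match seg {seg.data.shape}")
    sel = np.flatnonzero(annotated)
    if sel.size == 0:
        return Tensor(0.0)
    m = masks[sel]
    labelled = m != UNLABELLED
    if not labelled.any():
        return Tensor(0.0)
    if m[labelled].min() < 0 or m[labelled].max() >= s:
        raise ValueError(f"scene class id out of range [0,{s}) on an annotated pixel")
    onehot = np.zeros((sel.size, s) + m.shape[1:], dtype=seg.data.dtype)
    idx = np.nonzero(labelled)
    onehot[idx[0], m[labelled], idx[1], idx[2]] = 1.0
    seg_sel = ad.take(seg, sel, axis=0)
    total = ad.sum_(ad.mul(ad.log(seg_sel, _LOG_EPS), onehot))
    return ad.mul(total, -1.0 / labelled.sum())


def instrument_loss(pred, presence) -> Tensor:
    """Mean per-instrument binary cross-entropy on sigmoid outputs."""
    pred = ad.astensor(pred)
    y = np.asarray(presence, dtype=float)
    if y.shape != pred.data.shape:
        raise ValueError(f"presence shape {y.shape} != prediction {pred.data.shape}")
    pos = ad.mul(ad.log(pred, _LOG_EPS), y)
    neg = ad.mul(ad.log(ad.mul(pred, -1.0) + 1.0, _LOG_EPS), 1.0 - y)
    return ad.mul(ad.sum_(pos + neg), -1.0 / y.size)


def encoder_loss(scene, phase, instrument=None):
    """Joint multi-task objective: unweighted sum of the present terms."""
    total = ad.astensor(scene) + ad.astensor(phase)
    if instrument is not None:
        total = total + ad.astensor(instrument)
    return total


def tcn_loss(stage_preds, annotations, spec: ClampSpec = ClampSpec(),
             variant: str = "clamp_then_square", smooth_lambda: float = 0.15) -> Tensor:
    """Temporal loss: per stage, cross-entropy + truncated MSE, summed.

    stage_preds: list of (T, P) row-stochastic prediction sequences, one per
    stage; annotations: (T,) integer phase ids applied to every stage.

    variants of the truncated term
      ``clamp_then_square`` (default): mean over T*P of clamp(one_hot - pred)^2
      ``square_then_clamp``: mean of clamp((one_hot - pred)^2)
      ``smooth_logprob``: temporal smoothing on consecutive-frame
        log-probability differences, clamp(|dlog p|)^2, weighted by
        ``smooth_lambda``.
    """
    if variant not in TCN_LOSS_VARIANTS:
        raise ValueError(f"unknown tcn_loss variant {variant!r}")
    if len(stage_preds) == 0:
        raise ValueError("tcn_loss requires at least one stage prediction")
    ann = np.asarray(annotations, dtype=int)
    total = None
    for pred in stage_preds:
        pred = ad.astensor(pred)
        t, p = pred.data.shape
        if ann.shape != (t,):
            raise ValueError(f"annotation length {ann.shape} does not match T={t}")
        if ann.min() < 0 or ann.max() >= p:
            raise ValueError(f"phase id out of range [0,{p})")
        onehot = _one_hot(ann, p, pred.data.dtype)
        ce = ad.mul(ad.sum_(ad.mul(ad.log(pred, _LOG_EPS), onehot)), -1.0 / t)
        if variant == "clamp_then_square":
            diff = ad.add(ad.mul(pred, -1.0), onehot)
            term = ad.mean(ad.power(ad.clamp(diff, 0.0, spec.c), 2.0))
        elif variant == "square_then_clamp":
            diff = ad.add(ad.mul(pred, -1.0), onehot)
            term = ad.mean(ad.clamp(ad.power(diff, 2.0), 0.0, spec.c))
        else:  # smooth_logprob
            if t > 1:
                logp = ad.log(pred, _LOG_EPS)
                d = ad.add(ad.take(logp, np.arange(1, t), axis=0),
                           ad.mul(ad.take(logp, np.arange(t - 1), axis=0), -1.0))
                mag = ad.sqrt(ad.power(d, 2.0) + 1e-16)
                term = ad.mul(ad.mean(ad.power(ad.clamp(mag, 0.0, spec.c), 2.0)),
                              smooth_lambda)
            else:
                term = ad.astensor(0.0)
        stage_total = ce + term
        total = stage_total if total is None else total + stage_total
    return total
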