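"""Phase and scene-segmentation metrics, fold aggregation, and the ribbon plot.

Phase metrics: accuracy ``(TP+TN)/(TP+FP+FN+TN)`` and F1
``TP/(TP + 0.5(FP+FN))`` from one-vs-rest counts, F1 macro-averaged over
classes.  Under one-vs-rest aggregation the multi-class accuracy reduces to
(#correct frames)/(#frames), which is how it is computed here.

Scene metrics: per annotated image and per class, pixel accuracy, IOU
``TP/(TP+FP+FN)`` and DICE ``2TP/(2TP+FP+FN)``, aggregated as the mean across
(image, class) pairs.  Classes absent from both prediction and annotation in
an image are skipped (the 0/0 case), and an explicit exclude list removes
classes with too little annotated data from the aggregate.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .losses import UNLABELLED


@dataclasses.dataclass
class ConfusionMatrix:
    """K x K integer counts; rows index the annotation, columns the prediction."""

    counts: np.ndarray

    @classmethod
    def from_labels(cls, ann, pred, num_classes: int) -> "ConfusionMatrix":
        ann = np.asarray(ann, dtype=int).reshape(-1)
        pred = np.asarray(pred, dtype=int).reshape(-1)
        if ann.shape != pred.shape:
            raise ValueError(f"length mismatch: {ann.shape} vs {pred.shape}")
        counts = np.zeros((num_classes, num_classes), dtype=np.int64)
        np.add.at(counts, (ann, pred), 1)
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self, c: int) -> int:
        return int(self.counts[c, c])

    def fp(self, c: int) -> int:
        return int(self.counts[:, c].sum() - self.counts[c, c])

    def fn(self, c: int) -> int:
        return int(self.counts[c, :].sum() - self.counts[c, c])

    def tn(self, c: int) -> int:
        return self.total - self.tp(c) - self.fp(c) - self.fn(c)


@dataclasses.dataclass
class MetricReport:
    """Container for phase (accuracy, f1) and scene (mPA, mIOU, mDICE) scores;
    unused fields stay None.  ``per_class`` maps metric name -> class -> value."""

    accuracy: float | None = None
    f1: float | None = None
    mPA: float | None = None
    mIOU: float | None = None
    mDICE: float | None = None
    per_class: dict = dataclasses.field(default_factory=dict)
    n: int = 0

    def as_dict(self) -> dict:
        out = {k: v for k, v in dataclasses.asdict(self).items() if v is not None}
        return out


def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = tp + 0.5 * (fp + fn)
    return tp / denom if denom > 0 else 0.0


def phase_metrics(pred, ann, num_classes: int | None = None) -> MetricReport:
    """Frame-level accuracy and macro F1 over one prediction/annotation pair.

    F1 is averaged over the classes present in the annotation or prediction.
    """
    pred = np.asarray(pred, dtype=int).reshape(-1)
    ann = np.asarray(ann, dtype=int).reshape(-1)
    if pred.shape != ann.shape:
        raise ValueError(f"length mismatch: pred {pred.shape}, ann {ann.shape}")
    if num_classes is None:
        num_classes = int(max(pred.max(initial=0), ann.max(initial=0))) + 1
    cm = ConfusionMatrix.from_labels(ann, pred, num_classes)
    present = sorted(set(ann.tolist()) | set(pred.tolist()))
    per_f1 = {c: f1_from_counts(cm.tp(c), cm.fp(c), cm.fn(c)) for c in present}
    acc = float((pred == ann).mean()) if pred.size else 0.0
    f1 = float(np.mean(list(per_f1.values()))) if per_f1 else 0.0
    return MetricReport(accuracy=acc, f1=f1, per_class={"f1": per_f1}, n=pred.size)


def phase_metrics_videos(pairs, num_classes: int | None = None,
                         average: str = "videos") -> MetricReport:
    """Aggregate phase metrics over several videos.

    ``average="videos"`` (default): compute per-video accuracy/F1 and average
    them.  ``average="pooled"``: concatenate all frames first.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no videos to evaluate")
    if average == "pooled":
        pred = np.concatenate([np.asarray(p) for p, _ in pairs])
        ann = np.concatenate([np.asarray(a) for _, a in pairs])
        return phase_metrics(pred, ann, num_classes)
    if average != "videos":
        raise ValueError(f"unknown averaging mode {average!r}")
    reports = [phase_metrics(p, a, num_classes) for p, a in pairs]
    return MetricReport(accuracy=float(np.mean([r.accuracy for r in reports])),
                        f1=float(np.mean([r.f1 for r in reports])),
                        n=sum(r.n for r in reports))


def scene_metrics(preds, anns, exclude=()) -> MetricReport:
    """mPA / mIOU / mDICE over annotated images.

    preds, anns: sequences of (H, W) integer masks; annotation pixels equal to
    ``UNLABELLED`` are ignored.  Scores are the mean over every (image, class)
    pair where the class appears in the image's prediction or annotation and is
    not excluded.
    """
    preds, anns = list(preds), list(anns)
    if len(preds) != len(anns):
        raise ValueError("pred/annotation image counts differ")
    if not preds:
        raise ValueError("scene_metrics requires at least one annotated image")
    exclude = set(exclude)
    pa_all, iou_all, dice_all = [], [], []
    per_class: dict[str, dict] = {"PA": {}, "IOU": {}, "DICE": {}}
    for pred, ann in zip(preds, anns):
        pred = np.asarray(pred, dtype=int)
        ann = np.asarray(ann, dtype=int)
        if pred.shape != ann.shape:
            raise ValueError(f"mask shape mismatch: {pred.shape} vs {ann.shape}")
        valid = ann != UNLABELLED
        if not valid.any():
            continue
        p, a = pred[valid], ann[valid]
        n = p.size
        classes = (set(np.unique(p).tolist()) | set(np.unique(a).tolist())) - exclude
        for c in sorted(classes):
            tp = int(np.sum((p == c) & (a == c)))
            fp = int(np.sum((p == c) & (a != c)))
            fn = int(np.sum((p != c) & (a == c)))
            if tp + fp + fn == 0:
                continue  # class absent from both: undefined, skipped
            tn = n - tp - fp - fn
            pa = (tp + tn) / n
            iou = tp / (tp + fp + fn)
            dice = 2 * tp / (2 * tp + fp + fn)
            pa_all.append(pa)
            iou_all.append(iou)
            dice_all.append(dice)
            for name, val in (("PA", pa), ("IOU", iou), ("DICE", dice)):
                per_class[name].setdefault(c, []).append(val)
    if not iou_all:
        raise ValueError("no annotated pixels found in any image")
    per_class = {name: {c: float(np.mean(v)) for c, v in d.items()}
                 for name, d in per_class.items()}
    return MetricReport(mPA=float(np.mean(pa_all)), mIOU=float(np.mean(iou_all)),
                        mDICE=float(np.mean(dice_all)), per_class=per_class,
                        n=len(iou_all))


def aggregate_folds(values) -> tuple[float, float]:
    """mean +/- std over fold-level scores (population std, ddof=0)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("no fold values to aggregate")
    return float(values.mean()), float(values.std())


def render_ribbon(ann, pred, palette: dict, column_width: int = 4,
                  bar_height: int = 24, gap: int = 6) -> np.ndarray:
    """Two horizontal colour bars, annotation above prediction, one block of
    ``column_width`` pixel columns per frame.  Returns an (H, W, 3) uint8 image.
    """
    ann = np.asarray(ann, dtype=int).reshape(-1)
    pred = np.asarray(pred, dtype=int).reshape(-1)
    if ann.shape != pred.shape:
        raise ValueError("annotation and prediction lengths differ")
    classes = set(ann.tolist()) | set(pred.tolist())
    missing = sorted(c for c in classes if c not in palette)
    if missing:
        raise ValueError(f"palette missing colours for classes {missing}")
    t = ann.size
    width = t * column_width
    img = np.full((2 * bar_height + gap, width, 3), 255, dtype=np.uint8)
    colours = {c: np.asarray(palette[c], dtype=np.uint8) for c in classes}
    for row, seq in ((0, ann), (bar_height + gap, pred)):
        for i, c in enumerate(seq):
            img[row:row + bar_height, i * column_width:(i + 1) * column_width] = colours[c]
    return img


def count_transitions(labels) -> int:
    """Number of phase-segment boundaries in a label sequence."""
    labels = np.asarray(labels).reshape(-1)
    if labels.size < 2:
        return 0
    return int(np.sum(labels[1:] != labels[:-1]))
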