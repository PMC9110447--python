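"""Procedural generator of phase-structured surgical-like videos.

Emulates the structure of a phase-annotated laparoscopic dataset with sparse
segmentation masks: each video walks through the phases in canonical order
with random dwell lengths; every frame shows a textured background, slowly
drifting "anatomy" blobs and fast-moving elongated "instrument" shapes.
Which object classes are visible is a deterministic function of the current
phase (the visibility table), so segmentation carries strictly more usable
signal about the phase than raw appearance — the mechanism that makes
sparse-mask supervision useful.  Two design choices enforce that mechanism:

* colour never identifies a class — all anatomy shares one per-video tissue
  tone and all instruments one metallic tone; classes differ only by
  consistent shape geometry;
* phase-independent *distractor* objects are rendered from the same colour
  families with in-between geometry and labelled background in the masks, so
  appearance statistics (object counts, foreground area) do not resolve the
  phase either — telling informative objects from clutter is exactly what
  the pixel annotation teaches.

Dense ground-truth masks exist for every frame; only a small configurable
fraction is *exposed* as annotation.

What this generator does not emulate: photorealistic tissue appearance,
smoke, blood, specular highlights, or real occlusion statistics.
"""

from __future__ import annotations

import dataclasses

import numpy as np

DEFAULT_VISIBILITY = {
    0: (1,),
    1: (1, 2, 4),
    2: (1, 2, 3, 5),
    3: (2, 3, 4, 5),
    4: (3,),
}

# image-space base tones: all anatomy classes share the tissue tone and all
# instruments the metallic tone, so *colour alone does not identify a class*;
# classes are told apart by consistent shape geometry.  This realises the
# design goal that phase identity requires knowing which objects are visible
# (segmentation-level information), not just global colour statistics.
_BACKGROUND_TONE = (95, 45, 45)
_ANATOMY_TONE = (175, 100, 70)
_INSTRUMENT_TONE = (190, 190, 200)

# class-specific geometry (fractions of image size): anatomy ellipse radii
# cycle through wide/round/tall; instrument bars through thin/thick.
_ANATOMY_SHAPES = [(0.30, 0.11), (0.17, 0.20), (0.09, 0.30)]
_INSTRUMENT_WIDTHS = [0.022, 0.060]

# distractor geometry sits between the class prototypes: same colour family,
# but an aspect ratio / bar width no informative class uses
_DISTRACTOR_ELLIPSE = (0.20, 0.13)
_DISTRACTOR_BAR_WIDTH = 0.040


@dataclasses.dataclass
class SynthSpec:
    """Study conditions of the synthetic benchmark.

    Defaults give 30 videos of 120 frames at 64x48 with 5 phases and 6 scene
    classes (background, 3 anatomy, 2 instruments), masks exposed on 5% of the
    frames of one third of the videos — small enough for CPU training in
    minutes while preserving the phase/scene coupling of the real task.
    """

    num_videos: int = 30
    frames_per_video: int = 120
    image_size: tuple = (64, 48)  # (W, H)
    num_phases: int = 5
    num_scene_classes: int = 6
    num_instruments: int = 2
    visibility: dict | None = None
    dwell_mean: float | None = None  # default: frames_per_video / num_phases
    dwell_std: float = 6.0
    min_dwell: int = 5
    mask_fraction: float = 0.05
    num_mask_videos: int | None = None  # default: num_videos // 3 (>= 1)
    train_fraction: float = 2.0 / 3.0
    noise_std: float = 10.0
    illumination_jitter: float = 0.12
    num_distractors: int = 3
    distractor_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.visibility is None:
            if self.num_phases == 5 and self.num_scene_classes == 6:
                self.visibility = dict(DEFAULT_VISIBILITY)
            else:
                raise ValueError("a visibility table is required for "
                                 "non-default phase/scene class counts")
        for p in range(self.num_phases):
            if p not in self.visibility:
                raise ValueError(f"visibility table does not cover phase {p}")
            for c in self.visibility[p]:
                if not 1 <= c < self.num_scene_classes:
                    raise ValueError(f"visibility class {c} out of range "
                                     f"[1,{self.num_scene_classes})")
        if not 0 < self.mask_fraction <= 1:
            raise ValueError("mask_fraction must be in (0, 1]")
        if round(self.mask_fraction * self.frames_per_video) < 1:
            raise ValueError("mask_fraction * frames_per_video must be >= 1")
        if self.dwell_mean is None:
            self.dwell_mean = self.frames_per_video / self.num_phases
        if self.num_mask_videos is None:
            self.num_mask_videos = max(1, self.num_videos // 3)

    @property
    def instrument_classes(self) -> list[int]:
        s = self.num_scene_classes
        return list(range(s - self.num_instruments, s))

    @property
    def anatomy_classes(self) -> list[int]:
        return list(range(1, self.num_scene_classes - self.num_instruments))


@dataclasses.dataclass
class SyntheticVideo:
    video_id: str
    frames: np.ndarray           # (T, H, W, 3) uint8
    phase_labels: np.ndarray     # (T,) int
    masks: np.ndarray            # (T, H, W) int — dense ground truth
    annotated_frames: np.ndarray  # sorted frame indices with exposed masks
    instrument_presence: np.ndarray  # (T, num_instruments) {0,1}
    draw_log: list | None = None  # per frame: list of (class_id, footprint)

    @property
    def num_frames(self) -> int:
        return len(self.phase_labels)


@dataclasses.dataclass
class DatasetSplit:
    train: list
    test: list

    @property
    def videos(self) -> list:
        return self.train + self.test


def sample_phase_sequence(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Piecewise-constant phase labels visiting 0..P-1 in order; dwell lengths
    Gaussian around the mean, never shorter than ``min_dwell``; the last phase
    absorbs any remaining frames."""
    t = spec.frames_per_video
    labels = np.empty(t, dtype=int)
    pos = 0
    for p in range(spec.num_phases):
        if pos >= t:
            break
        dwell = max(spec.min_dwell, int(round(rng.normal(spec.dwell_mean, spec.dwell_std))))
        if p == spec.num_phases - 1:
            dwell = t - pos
        labels[pos:pos + dwell] = p
        pos += dwell
    if pos < t:
        labels[pos:] = spec.num_phases - 1
    return labels


def _ellipse_footprint(xx, yy, cx, cy, rx, ry, angle) -> np.ndarray:
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _bar_footprint(xx, yy, x0, y0, angle, length, halfwidth) -> np.ndarray:
    """Elongated instrument shape: a thick segment from (x0, y0) at `angle`."""
    dx, dy = np.cos(angle), np.sin(angle)
    px, py = xx - x0, yy - y0
    along = px * dx + py * dy
    perp = np.abs(-px * dy + py * dx)
    return (along >= 0) & (along <= length) & (perp <= halfwidth)


def generate_video(spec: SynthSpec, video_seed, video_id: str | None = None,
                   keep_draw_log: bool = False) -> SyntheticVideo:
    """Render one video deterministically from (spec, video_seed)."""
    rng = np.random.default_rng(video_seed)
    w, h = spec.image_size
    t = spec.frames_per_video
    labels = sample_phase_sequence(spec, rng)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    # per-video appearance: one tissue tone shared by every anatomy class and
    # one metallic tone shared by every instrument (small per-class offsets are
    # re-drawn per video, so colour never identifies a class across videos)
    tissue = np.asarray(_ANATOMY_TONE, float) + rng.uniform(-20, 20, 3)
    metal = np.asarray(_INSTRUMENT_TONE, float) + rng.uniform(-20, 20, 3)
    colours = {0: np.asarray(_BACKGROUND_TONE, float) + rng.uniform(-15, 15, 3)}
    for c in spec.anatomy_classes:
        colours[c] = np.clip(tissue + rng.uniform(-6, 6, 3), 0, 255)
    for c in spec.instrument_classes:
        colours[c] = np.clip(metal + rng.uniform(-6, 6, 3), 0, 255)
    fx, fy = rng.uniform(0.5, 1.5, 2)
    phx, phy = rng.uniform(0, 2 * np.pi, 2)
    texture = 14.0 * (np.sin(2 * np.pi * fx * xx / w + phx)
                      + np.cos(2 * np.pi * fy * yy / h + phy))

    anatomy = {}
    for k, c in enumerate(spec.anatomy_classes):
        rx, ry = _ANATOMY_SHAPES[k % len(_ANATOMY_SHAPES)]
        anatomy[c] = {
            "cx": rng.uniform(0.25 * w, 0.75 * w), "cy": rng.uniform(0.25 * h, 0.75 * h),
            "rx": rx * w * rng.uniform(0.85, 1.15),
            "ry": ry * h * rng.uniform(0.85, 1.15),
            "angle": rng.normal(0, 0.25),  # near-canonical orientation
            "drift": rng.normal(0, 0.05, 2),  # slow per-frame centre drift
        }
    instruments = {}
    for k, c in enumerate(spec.instrument_classes):
        side = rng.integers(0, 4)
        hw = _INSTRUMENT_WIDTHS[k % len(_INSTRUMENT_WIDTHS)]
        instruments[c] = {"side": int(side),
                          "halfwidth": hw * w * rng.uniform(0.9, 1.1)}

    # phase-independent distractor clutter: same colour families, geometry
    # between the informative prototypes, labelled background in the mask
    distractors = []
    for k in range(spec.num_distractors):
        if k % 2 == 0:
            distractors.append({
                "kind": "ellipse",
                "cx": rng.uniform(0.2 * w, 0.8 * w), "cy": rng.uniform(0.2 * h, 0.8 * h),
                "rx": _DISTRACTOR_ELLIPSE[0] * w * rng.uniform(0.85, 1.15),
                "ry": _DISTRACTOR_ELLIPSE[1] * h * rng.uniform(0.85, 1.15),
                "angle": rng.normal(0, 0.25), "drift": rng.normal(0, 0.05, 2),
                "colour": np.clip(tissue + rng.uniform(-6, 6, 3), 0, 255),
            })
        else:
            distractors.append({
                "kind": "bar", "side": int(rng.integers(0, 4)),
                "halfwidth": _DISTRACTOR_BAR_WIDTH * w * rng.uniform(0.9, 1.1),
                "colour": np.clip(metal + rng.uniform(-6, 6, 3), 0, 255),
            })
    seg_id = np.concatenate([[0], np.cumsum(np.diff(labels) != 0)])
    n_segments = int(seg_id[-1]) + 1
    distractor_visible = rng.random((n_segments, max(spec.num_distractors, 1))) \
        < spec.distractor_rate

    frames = np.empty((t, h, w, 3), dtype=np.uint8)
    masks = np.empty((t, h, w), dtype=np.int64)
    presence = np.zeros((t, spec.num_instruments), dtype=np.int64)
    log = [] if keep_draw_log else None

    for i in range(t):
        visible = set(spec.visibility[int(labels[i])])
        frame_log = []
        mask = np.zeros((h, w), dtype=np.int64)
        img = np.empty((h, w, 3))
        img[:] = colours[0]
        img += texture[..., None]
        for k, d in enumerate(distractors):
            if not distractor_visible[seg_id[i], k]:
                continue
            if d["kind"] == "ellipse":
                fp = _ellipse_footprint(xx, yy, d["cx"] + i * d["drift"][0],
                                        d["cy"] + i * d["drift"][1],
                                        d["rx"], d["ry"], d["angle"])
            else:
                angle0 = {0: 0.0, 1: np.pi, 2: np.pi / 2, 3: -np.pi / 2}[d["side"]]
                origin = {0: (0.0, rng.uniform(0.2, 0.8) * h),
                          1: (w - 1.0, rng.uniform(0.2, 0.8) * h),
                          2: (rng.uniform(0.2, 0.8) * w, 0.0),
                          3: (rng.uniform(0.2, 0.8) * w, h - 1.0)}[d["side"]]
                fp = _bar_footprint(xx, yy, origin[0], origin[1],
                                    angle0 + rng.uniform(-0.5, 0.5),
                                    rng.uniform(0.35, 0.65) * max(w, h),
                                    d["halfwidth"])
            img[fp] = d["colour"]
            frame_log.append((0, fp))
        for c in spec.anatomy_classes:
            if c not in visible:
                continue
            a = anatomy[c]
            fp = _ellipse_footprint(xx, yy, a["cx"] + i * a["drift"][0],
                                    a["cy"] + i * a["drift"][1],
                                    a["rx"], a["ry"], a["angle"])
            mask[fp] = c
            img[fp] = colours[c]
            frame_log.append((c, fp))
        for k, c in enumerate(spec.instrument_classes):
            if c not in visible:
                continue
            ins = instruments[c]
            angle0 = {0: 0.0, 1: np.pi, 2: np.pi / 2, 3: -np.pi / 2}[ins["side"]]
            origin = {0: (0.0, rng.uniform(0.2, 0.8) * h),
                      1: (w - 1.0, rng.uniform(0.2, 0.8) * h),
                      2: (rng.uniform(0.2, 0.8) * w, 0.0),
                      3: (rng.uniform(0.2, 0.8) * w, h - 1.0)}[ins["side"]]
            angle = angle0 + rng.uniform(-0.5, 0.5)
            length = rng.uniform(0.35, 0.65) * max(w, h)
            fp = _bar_footprint(xx, yy, origin[0], origin[1], angle, length,
                                ins["halfwidth"])
            mask[fp] = c
            img[fp] = colours[c]
            frame_log.append((c, fp))
            presence[i, k] = 1
        gain = 1.0 + rng.normal(0.0, spec.illumination_jitter)
        img = img * gain + rng.normal(0.0, spec.noise_std, img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
        masks[i] = mask
        if keep_draw_log:
            log.append(frame_log)

    n_ann = int(round(spec.mask_fraction * t))
    annotated = np.sort(rng.choice(t, size=n_ann, replace=False))
    return SyntheticVideo(video_id=video_id or "video",
                          frames=frames, phase_labels=labels, masks=masks,
                          annotated_frames=annotated,
                          instrument_presence=presence, draw_log=log)


def generate_dataset(spec: SynthSpec) -> DatasetSplit:
    """Generate all videos and split train/test with mask-bearing videos pinned
    to the training side."""
    if spec.num_videos < 2:
        raise ValueError("need at least 2 videos to split")
    n_train = int(round(spec.train_fraction * spec.num_videos))
    n_train = min(max(n_train, 1), spec.num_videos - 1)
    if spec.num_mask_videos > n_train:
        raise ValueError(f"{spec.num_mask_videos} mask-bearing videos cannot be "
                         f"pinned into a training split of {n_train}")
    if spec.num_mask_videos < 1:
        raise ValueError("segmentation supervision requires >= 1 mask-bearing video")
    root = np.random.default_rng(spec.seed)
    mask_ids = set(root.choice(spec.num_videos, size=spec.num_mask_videos,
                               replace=False).tolist())
    videos = []
    for i in range(spec.num_videos):
        v = generate_video(spec, video_seed=[spec.seed, i], video_id=f"video{i:02d}")
        if i not in mask_ids:
            v.annotated_frames = np.empty(0, dtype=int)
        videos.append(v)
    # mask-bearing videos first, then the rest, both in id order; split by count
    with_masks = [v for i, v in enumerate(videos) if i in mask_ids]
    without = [v for i, v in enumerate(videos) if i not in mask_ids]
    ordered = with_masks + without
    return DatasetSplit(train=ordered[:n_train], test=ordered[n_train:])


def replay_mask(frame_log, shape) -> np.ndarray:
    """Re-rasterise a frame's mask from its draw log (later draws occlude)."""
    mask = np.zeros(shape, dtype=np.int64)
    for class_id, footprint in frame_log:
        mask[footprint] = class_id
    return mask
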