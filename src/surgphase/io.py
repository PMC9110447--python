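"""On-disk formats, dataset manifests and class catalogs.

Layout written by the generator and consumed by the trainers::

    dataset_root/
      manifest.json
      video00/
        frames/000000.png ...          # RGB frames at the working frame rate
        phases.tsv                     # "frame<TAB>phase-name", with header
        masks/000007.png ...           # class-index PNG, annotated frames only
        instruments.tsv                # binary presence columns, with header

Conventions: 0-based contiguous frame indices, masks row-major with origin
top-left, scene class 0 reserved for background.  Phase files accept both
phase names (case-insensitive) and numeric ids.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from PIL import Image

from .losses import UNLABELLED
from .synthetic import DatasetSplit, SyntheticVideo

logger = logging.getLogger("surgphase")

CHOLEC80_PHASES = (
    "preparation",
    "calot-triangle-dissection",
    "clipping-cutting",
    "gallbladder-dissection",
    "gallbladder-packaging",
    "cleaning-coagulation",
    "gallbladder-retraction",
)

CHOLECSEG8K_CLASSES = (
    "background",
    "abdominal-wall",
    "liver",
    "gastrointestinal-tract",
    "fat",
    "connective-tissue",
    "blood",
    "cystic-duct",
    "gallbladder",
    "hepatic-vein",
    "liver-ligament",
    "grasper",
    "hook",
)


def _auto_palette(n: int) -> dict:
    """Deterministic, visually distinct colours; bijective over class ids."""
    rng = np.random.default_rng(12345)
    hues = (np.arange(n) / n + 0.13) % 1.0
    out = {}
    for i, h in enumerate(hues):
        # simple HSV->RGB at s=0.75, v jittered deterministically
        v = 0.95 - 0.25 * (i % 2)
        s = 0.75
        k = (h * 6) % 6
        c = v * s
        x = c * (1 - abs(k % 2 - 1))
        rgb = [(c, x, 0), (x, c, 0), (0, c, x), (0, x, c), (x, 0, c), (c, 0, x)][int(k)]
        out[i] = tuple(int(round(255 * (ch + v - c))) for ch in rgb)
    del rng
    assert len(set(out.values())) == n, "palette collision"
    return out


@dataclasses.dataclass
class ClassCatalog:
    """Ordered class names and a bijective colour palette per class id."""

    phase_names: tuple
    scene_class_names: tuple
    instrument_names: tuple = ()
    phase_palette: dict = None
    scene_palette: dict = None

    def __post_init__(self):
        for names in (self.phase_names, self.scene_class_names, self.instrument_names):
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate class names in {names}")
        if self.phase_palette is None:
            self.phase_palette = _auto_palette(len(self.phase_names))
        if self.scene_palette is None:
            self.scene_palette = _auto_palette(len(self.scene_class_names))
        for palette, names in ((self.phase_palette, self.phase_names),
                               (self.scene_palette, self.scene_class_names)):
            if sorted(palette) != list(range(len(names))):
                raise ValueError("palette must cover exactly the class ids")
            if len(set(palette.values())) != len(names):
                raise ValueError("palette colours must be distinct")

    def phase_id(self, token: str, line_no: int | None = None) -> int:
        token = token.strip()
        lowered = [n.lower() for n in self.phase_names]
        if token.lower() in lowered:
            return lowered.index(token.lower())
        if token.isdigit() and int(token) < len(self.phase_names):
            return int(token)
        where = f" at line {line_no}" if line_no is not None else ""
        raise ValueError(f"unknown phase label {token!r}{where}")

    @classmethod
    def cholec80(cls) -> "ClassCatalog":
        return cls(CHOLEC80_PHASES, CHOLECSEG8K_CLASSES, ("grasper", "hook"))

    @classmethod
    def synthetic(cls, num_phases: int, num_scene_classes: int,
                  num_instruments: int = 0) -> "ClassCatalog":
        return cls(tuple(f"phase{i}" for i in range(num_phases)),
                   tuple(["background"] +
                         [f"class{i}" for i in range(1, num_scene_classes)]),
                   tuple(f"instrument{i}" for i in range(num_instruments)))


@dataclasses.dataclass
class VideoRecord:
    """One video in memory: dense frames and phase labels, sparse masks."""

    video_id: str
    frames: np.ndarray                 # (T, H, W, 3) uint8
    phase_labels: np.ndarray           # (T,)
    masks: dict                        # frame index -> (H, W) int mask
    instrument_presence: np.ndarray | None = None  # (T, I) or None

    @property
    def num_frames(self) -> int:
        return len(self.phase_labels)

    @classmethod
    def from_synthetic(cls, v: SyntheticVideo) -> "VideoRecord":
        masks = {int(i): v.masks[i] for i in v.annotated_frames}
        return cls(v.video_id, v.frames, v.phase_labels, masks,
                   v.instrument_presence)


# ---------------------------------------------------------------------------
# phase annotation files
# ---------------------------------------------------------------------------

def write_phase_annotations(path, labels, catalog: ClassCatalog):
    path = Path(path)
    lines = ["Frame\tPhase"]
    for i, lab in enumerate(np.asarray(labels, dtype=int)):
        lines.append(f"{i}\t{catalog.phase_names[lab]}")
    path.write_text("\n".join(lines) + "\n")


def read_phase_annotations(path, catalog: ClassCatalog, source_fps: int = 1,
                           target_fps: int = 1) -> np.ndarray:
    """Read a tab-separated phase file and subsample from ``source_fps`` to
    ``target_fps`` by keeping every (source/target)-th record starting at 0."""
    if source_fps % target_fps != 0:
        raise ValueError(f"source_fps {source_fps} not divisible by "
                         f"target_fps {target_fps}")
    stride = source_fps // target_fps
    labels, prev_frame = [], -1
    with open(path) as fh:
        for line_no, line in enumerate(fh):
            line = line.strip()
            if not line or line_no == 0:  # header
                continue
            frame_str, token = line.split("\t")
            frame = int(frame_str)
            if frame <= prev_frame:
                raise ValueError(f"non-monotone frame index {frame} at line {line_no + 1}")
            prev_frame = frame
            labels.append(catalog.phase_id(token, line_no + 1))
    return np.asarray(labels[::stride], dtype=int)


# ---------------------------------------------------------------------------
# masks and frames
# ---------------------------------------------------------------------------

def write_frame(path, frame: np.ndarray):
    Image.fromarray(np.asarray(frame, dtype=np.uint8)).save(path)


def read_frame(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_mask(path, mask: np.ndarray):
    """Class-index PNG (8-bit single channel)."""
    arr = np.asarray(mask)
    store = np.where(arr == UNLABELLED, 255, arr).astype(np.uint8)
    Image.fromarray(store, mode="L").save(path)


def write_mask_palette(path, mask: np.ndarray, catalog: ClassCatalog):
    """Colour PNG using the catalog's scene palette (for visual inspection and
    palette-PNG round-trip reading)."""
    arr = np.asarray(mask, dtype=int)
    rgb = np.zeros(arr.shape + (3,), dtype=np.uint8)
    for cid, colour in catalog.scene_palette.items():
        rgb[arr == cid] = colour
    Image.fromarray(rgb).save(path)


def read_mask(path, catalog: ClassCatalog) -> np.ndarray:
    """Read a class-index or palette-colour mask PNG.

    Greyscale images are class indices (255 = unlabelled sentinel).  RGB
    images are mapped through the catalog's scene palette; unlisted colours
    map to the unlabelled sentinel with a logged warning.
    """
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim == 2:
        out = arr.astype(np.int64)
        out[out == 255] = UNLABELLED
        s = len(catalog.scene_class_names)
        if out.max(initial=0) >= s:
            raise ValueError(f"mask {path} has class id >= {s}")
        return out
    arr = arr[..., :3]
    out = np.full(arr.shape[:2], UNLABELLED, dtype=np.int64)
    matched = np.zeros(arr.shape[:2], dtype=bool)
    for cid, colour in catalog.scene_palette.items():
        hit = np.all(arr == np.asarray(colour, dtype=np.uint8), axis=-1)
        out[hit] = cid
        matched |= hit
    n_unknown = int((~matched).sum())
    if n_unknown:
        logger.warning(json.dumps({"event": "unknown_mask_colours",
                                   "path": str(path), "pixels": n_unknown}))
    return out


# ---------------------------------------------------------------------------
# instrument presence
# ---------------------------------------------------------------------------

def write_instrument_presence(path, presence: np.ndarray, catalog: ClassCatalog):
    presence = np.asarray(presence, dtype=int)
    names = catalog.instrument_names or tuple(
        f"instrument{i}" for i in range(presence.shape[1]))
    lines = ["Frame\t" + "\t".join(names)]
    for i, row in enumerate(presence):
        lines.append(f"{i}\t" + "\t".join(str(int(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_instrument_presence(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh):
            line = line.strip()
            if not line or line_no == 0:
                continue
            rows.append([int(v) for v in line.split("\t")[1:]])
    return np.asarray(rows, dtype=int)


# ---------------------------------------------------------------------------
# dataset directory + manifest
# ---------------------------------------------------------------------------

def write_video(root, video: VideoRecord, catalog: ClassCatalog) -> dict:
    vdir = Path(root) / video.video_id
    (vdir / "frames").mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(video.frames):
        write_frame(vdir / "frames" / f"{i:06d}.png", frame)
    write_phase_annotations(vdir / "phases.tsv", video.phase_labels, catalog)
    entry = {"video_id": video.video_id, "frame_dir": f"{video.video_id}/frames",
             "phase_file": f"{video.video_id}/phases.tsv", "mask_dir": None,
             "instrument_file": None,
             "annotated_frames": sorted(int(i) for i in video.masks)}
    if video.masks:
        (vdir / "masks").mkdir(exist_ok=True)
        for i, mask in video.masks.items():
            write_mask(vdir / "masks" / f"{i:06d}.png", mask)
        entry["mask_dir"] = f"{video.video_id}/masks"
    if video.instrument_presence is not None:
        write_instrument_presence(vdir / "instruments.tsv",
                                  video.instrument_presence, catalog)
        entry["instrument_file"] = f"{video.video_id}/instruments.tsv"
    return entry


def write_dataset(split: DatasetSplit, root, catalog: ClassCatalog,
                  fps: int = 1) -> Path:
    """Write a train/test dataset directory with a manifest; returns its path."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {"fps": fps, "sampling_fps": fps,
                "num_phases": len(catalog.phase_names),
                "num_scene_classes": len(catalog.scene_class_names),
                "phase_names": list(catalog.phase_names),
                "scene_class_names": list(catalog.scene_class_names),
                "instrument_names": list(catalog.instrument_names),
                "train": [], "test": []}
    for part, videos in (("train", split.train), ("test", split.test)):
        for v in videos:
            rec = v if isinstance(v, VideoRecord) else VideoRecord.from_synthetic(v)
            manifest[part].append(write_video(root, rec, catalog))
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return root / "manifest.json"


def load_manifest(path) -> dict:
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    manifest = json.loads(path.read_text())
    manifest["_root"] = str(path.parent)
    root = path.parent
    for part in ("train", "test"):
        for entry in manifest[part]:
            for key in ("frame_dir", "phase_file", "mask_dir", "instrument_file"):
                if entry.get(key) and not (root / entry[key]).exists():
                    raise FileNotFoundError(f"manifest references missing path "
                                            f"{entry[key]}")
    return manifest


def catalog_from_manifest(manifest: dict) -> ClassCatalog:
    return ClassCatalog(tuple(manifest["phase_names"]),
                        tuple(manifest["scene_class_names"]),
                        tuple(manifest.get("instrument_names", ())))


def load_video(manifest: dict, entry: dict, catalog: ClassCatalog) -> VideoRecord:
    root = Path(manifest["_root"])
    labels = read_phase_annotations(root / entry["phase_file"], catalog,
                                    manifest["fps"], manifest["sampling_fps"])
    frame_dir = root / entry["frame_dir"]
    paths = sorted(frame_dir.glob("*.png"))
    frames = np.stack([read_frame(p) for p in paths])
    if len(frames) != len(labels):
        raise ValueError(f"{entry['video_id']}: {len(frames)} frames but "
                         f"{len(labels)} phase labels")
    masks = {}
    if entry.get("mask_dir"):
        for i in entry["annotated_frames"]:
            masks[int(i)] = read_mask(root / entry["mask_dir"] / f"{i:06d}.png",
                                      catalog)
    presence = None
    if entry.get("instrument_file"):
        presence = read_instrument_presence(root / entry["instrument_file"])
    return VideoRecord(entry["video_id"], frames, labels, masks, presence)


def load_dataset(path) -> tuple[list, list, ClassCatalog]:
    """(train videos, test videos, catalog) from a dataset directory."""
    manifest = load_manifest(path)
    catalog = catalog_from_manifest(manifest)
    train = [load_video(manifest, e, catalog) for e in manifest["train"]]
    test = [load_video(manifest, e, catalog) for e in manifest["test"]]
    return train, test, catalog


# ---------------------------------------------------------------------------
# feature container and prediction files
# ---------------------------------------------------------------------------

def write_features(path, features: dict):
    """Per-video frame features: one (T, D) array per video id, stored as a
    single .npz with a JSON sidecar documenting D and the frame ordering."""
    path = Path(path)
    arrays = {vid: np.asarray(arr) for vid, arr in features.items()}
    np.savez(path, **arrays)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    dims = {vid: list(arr.shape) for vid, arr in arrays.items()}
    sidecar = {"feature_dim": next(iter(dims.values()))[1] if dims else 0,
               "frame_order": "row t is frame index t at the sampling fps",
               "videos": dims}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_features(path) -> dict:
    path = Path(path)
    if not path.exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as data:
        return {vid: data[vid].copy() for vid in data.files}


def write_predictions(path, pred_ids, probs=None):
    """Per-frame predictions as TSV: frame, argmax phase id[, P probabilities]."""
    pred_ids = np.asarray(pred_ids, dtype=int)
    lines = ["Frame\tPhase" + ("\tProbs" if probs is not None else "")]
    for i, pid in enumerate(pred_ids):
        row = f"{i}\t{pid}"
        if probs is not None:
            row += "\t" + "\t".join(f"{v:.6f}" for v in np.asarray(probs[i]))
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def read_predictions(path) -> np.ndarray:
    ids = []
    with open(path) as fh:
        for line_no, line in enumerate(fh):
            line = line.strip()
            if not line or line_no == 0:
                continue
            ids.append(int(line.split("\t")[1]))
    return np.asarray(ids, dtype=int)
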