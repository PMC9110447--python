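"""Multi-task frame encoder for surgical phase estimation.

A shared residual backbone (depth 18/50/152 with the final residual stage
removed) feeds task-specific branches: a *scene* branch that predicts
pixel-wise segmentation of anatomy and instruments, a *phase* branch that
predicts the surgical phase, and an optional *instrument-presence* branch.
Each branch owns its own copy of the final residual stage, so the branch
feature maps share one shape and can be fused.

Three fusion mechanisms are provided:

``fast_norm``
    a linear combination with learnable non-negative scalar weights,
    ``f = sum_i ReLU(a_i) / (sum_j ReLU(a_j) + eps) * f_i``;
``concat_conv``
    channel concatenation followed by a 1x1 convolution and batch-norm;
``conv_concat_conv``
    per-branch 1x1 convolution + batch-norm + ReLU before concatenation,
    then a 1x1 convolution + batch-norm.

An optional skip connection adds the pre-fusion phase feature map to the
fused map.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

_BLOCK_LAYOUTS = {
    18: (nn.BasicBlock, (2, 2, 2, 2)),
    50: (nn.Bottleneck, (3, 4, 6, 3)),
    152: (nn.Bottleneck, (3, 8, 36, 3)),
}
FUSION_KINDS = ("fast_norm", "concat_conv", "conv_concat_conv")


@dataclasses.dataclass
class EncoderConfig:
    """Architecture hyperparameters of the multi-task encoder.

    ``num_instruments = 0`` disables the instrument-presence branch (fusion
    over 2 branches); any positive value enables it (fusion over 3 branches).
    ``base_width`` scales every stage width; 64 gives the standard residual
    network (branch channels 512 for depth 18, 2048 for depths 50/152).
    ``input_size`` is (W, H) in pixels.
    """

    backbone_depth: int = 50
    num_phases: int = 7
    num_scene_classes: int = 13
    num_instruments: int = 0
    fusion_kind: str = "fast_norm"
    use_skip: bool = False
    input_size: tuple = (400, 300)
    pretrained_init: bool = False
    pretrained_path: str | None = None
    base_width: int = 64
    fusion_epsilon: float = 1e-4
    stem_pool: bool = True  # disable for small inputs (CIFAR-style stem):
                            # halves the output stride so the scene feature
                            # map keeps enough resolution to localise
    seed: int = 0

    def validate(self):
        if self.backbone_depth not in _BLOCK_LAYOUTS:
            raise ValueError(f"unknown backbone_depth {self.backbone_depth}; "
                             f"expected one of {sorted(_BLOCK_LAYOUTS)}")
        if self.fusion_kind not in FUSION_KINDS:
            raise ValueError(f"unknown fusion_kind {self.fusion_kind!r}; "
                             f"expected one of {FUSION_KINDS}")
        if self.num_phases < 2:
            raise ValueError("num_phases must be >= 2")
        if self.num_scene_classes < 2:
            raise ValueError("num_scene_classes must be >= 2")
        if self.num_instruments < 0:
            raise ValueError("num_instruments must be >= 0")
        w, h = self.input_size
        if w < 32 or h < 32:
            raise ValueError("input_size must be at least 32x32 pixels")
        if self.pretrained_init and not self.pretrained_path:
            raise ValueError("pretrained_init requires pretrained_path "
                             "(no pre-trained weights are bundled)")

    @property
    def num_branches(self) -> int:
        return 3 if self.num_instruments > 0 else 2

    @property
    def branch_channels(self) -> int:
        block, _ = _BLOCK_LAYOUTS[self.backbone_depth]
        return 8 * self.base_width * block.expansion


@dataclasses.dataclass
class FusionWeights:
    """Learnable scalars of the fast-normalised fusion: one alpha per branch."""

    alphas: list
    epsilon: float = 1e-4

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def fast_norm_coefficients(alphas, epsilon: float) -> np.ndarray:
    a = np.maximum(np.asarray(alphas, dtype=float), 0.0)
    return a / (a.sum() + epsilon)


def fuse_fast_normalized(branch_features, weights: FusionWeights):
    """Weighted average of feature maps with ReLU-rectified normalised scalars.

    ``branch_features`` is a list of same-shape arrays or Tensors; returns the
    same type.  All-negative alphas yield the all-zeros map (epsilon guards the
    division).
    """
    if len(branch_features) == 0:
        raise ValueError("fuse_fast_normalized requires at least one feature map")
    if len(weights.alphas) != len(branch_features):
        raise ValueError(f"{len(weights.alphas)} alphas for "
                         f"{len(branch_features)} feature maps")
    shapes = {tuple(np.shape(f.data if isinstance(f, Tensor) else f))
              for f in branch_features}
    if len(shapes) != 1:
        raise ValueError(f"feature map shapes differ: {sorted(shapes)}")
    coeffs = fast_norm_coefficients(weights.alphas, weights.epsilon)
    if isinstance(branch_features[0], Tensor):
        out = branch_features[0] * coeffs[0]
        for f, c in zip(branch_features[1:], coeffs[1:]):
            out = out + f * c
        return out
    out = coeffs[0] * np.asarray(branch_features[0], dtype=float)
    for f, c in zip(branch_features[1:], coeffs[1:]):
        out = out + c * np.asarray(f, dtype=float)
    return out


class FastNormalizedFusion(nn.Module):
    """Trainable fast-normalised fusion; alphas start at 1 (equal contribution)."""

    def __init__(self, num_branches: int, epsilon: float = 1e-4):
        super().__init__()
        self.alphas = [nn.Parameter(1.0) for _ in range(num_branches)]
        self.epsilon = epsilon

    def forward(self, features: list) -> Tensor:
        if len(features) != len(self.alphas):
            raise ValueError(f"expected {len(self.alphas)} features, got {len(features)}")
        rect = [ad.relu(a) for a in self.alphas]
        denom = rect[0]
        for r in rect[1:]:
            denom = denom + r
        inv = ad.power(denom + self.epsilon, -1.0)
        out = features[0] * (rect[0] * inv)
        for f, r in zip(features[1:], rect[1:]):
            out = out + f * (r * inv)
        return out

    def coefficients(self) -> np.ndarray:
        return fast_norm_coefficients([a.data for a in self.alphas], self.epsilon)


class ConcatConvFusion(nn.Module):
    """Fusion by concatenation + 1x1 convolution (variant "a"), or with
    per-branch 1x1 conv + batch-norm + ReLU before concatenation (variant "b")."""

    def __init__(self, num_branches: int, channels: int, variant: str = "a", rng=None):
        super().__init__()
        if variant not in ("a", "b"):
            raise ValueError(f"variant must be 'a' or 'b', got {variant!r}")
        self.variant = variant
        if variant == "b":
            self.pre = [nn.Sequential(nn.Conv2d(channels, channels, 1, rng=rng),
                                      nn.BatchNorm2d(channels), nn.ReLU())
                        for _ in range(num_branches)]
        self.conv = nn.Conv2d(num_branches * channels, channels, 1, rng=rng)
        self.bn = nn.BatchNorm2d(channels)
        self.num_branches = num_branches

    def forward(self, features: list) -> Tensor:
        if len(features) != self.num_branches:
            raise ValueError(f"expected {self.num_branches} features, got {len(features)}")
        shapes = {f.data.shape for f in features}
        if len(shapes) != 1:
            raise ValueError(f"feature map shapes differ: {sorted(shapes)}")
        if self.variant == "b":
            features = [p(f) for p, f in zip(self.pre, features)]
        return self.bn(self.conv(ad.concat(features, axis=1)))


def fuse_concat_conv(branch_features, fusion: ConcatConvFusion, use_skip: bool = False,
                     phase_feature: Tensor | None = None) -> Tensor:
    """Apply a convolutional fusion module, optionally adding the pre-fusion
    phase feature map back onto the fused output (skip connection)."""
    out = fusion(branch_features)
    if use_skip:
        if phase_feature is None:
            raise ValueError("use_skip requires the pre-fusion phase feature map")
        out = out + phase_feature
    return out


class SceneSegmentationModule(nn.Module):
    """Scene-branch decoder: x4 bilinear upscale, 3x3 conv + batch-norm with a
    four-fold channel reduction, ReLU, 1x1 conv to S classes, bilinear upscale
    to the input resolution, softmax over classes."""

    def __init__(self, in_channels: int, num_classes: int, rng=None):
        super().__init__()
        mid = max(in_channels // 4, 1)
        self.conv3 = nn.Conv2d(in_channels, mid, 3, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(mid)
        self.conv1 = nn.Conv2d(mid, num_classes, 1, bias=True, rng=rng)

    def forward(self, f_s: Tensor, out_hw: tuple) -> Tensor:
        h, w = f_s.data.shape[2], f_s.data.shape[3]
        x = ad.interpolate_bilinear(f_s, (4 * h, 4 * w))
        x = ad.relu(self.bn(self.conv3(x)))
        x = self.conv1(x)
        x = ad.interpolate_bilinear(x, out_hw)
        return ad.softmax(x, axis=1)


class Encoder(nn.Module):
    """The multi-task encoder: image -> (scene segmentation, phase distribution
    [, instrument presence])."""

    def __init__(self, config: EncoderConfig):
        super().__init__()
        config.validate()
        self.config = config
        block, layout = _BLOCK_LAYOUTS[config.backbone_depth]
        w = config.base_width
        rng = np.random.default_rng(config.seed)

        stem = [nn.Conv2d(3, w, 7, stride=2, padding=3, rng=rng),
                nn.BatchNorm2d(w), nn.ReLU()]
        if config.stem_pool:
            stem.append(nn.MaxPool2d(3, 2, 1))
        in_ch = w
        stages = []
        for i, n_blocks in enumerate(layout[:3]):
            ch = w * (2 ** i)
            stride = 1 if i == 0 else 2
            blocks = [block(in_ch, ch, stride, rng=rng)]
            in_ch = ch * block.expansion
            blocks += [block(in_ch, ch, rng=rng) for _ in range(n_blocks - 1)]
            stages.append(nn.Sequential(*blocks))
        self.backbone = nn.Sequential(*stem, *stages)
        self._backbone_channels = in_ch

        def make_head():
            ch = 8 * w
            blocks = [block(in_ch, ch, 2, rng=rng)]
            blocks += [block(ch * block.expansion, ch, rng=rng)
                       for _ in range(layout[3] - 1)]
            return nn.Sequential(*blocks)

        self.scene_head = make_head()
        self.phase_head = make_head()
        cb = config.branch_channels
        self.scene_module = SceneSegmentationModule(cb, config.num_scene_classes, rng=rng)
        if config.num_instruments > 0:
            self.instrument_head = make_head()
            self.instrument_fc = nn.Linear(cb, config.num_instruments, rng=rng)
        else:
            self.instrument_head = None
            self.instrument_fc = None
        if config.fusion_kind == "fast_norm":
            self.fusion = FastNormalizedFusion(config.num_branches, config.fusion_epsilon)
        else:
            variant = "a" if config.fusion_kind == "concat_conv" else "b"
            self.fusion = ConcatConvFusion(config.num_branches, cb, variant, rng=rng)
        self.fc = nn.Linear(cb, config.num_phases, rng=rng)

        if config.pretrained_init:
            state = dict(np.load(config.pretrained_path))
            self.load_state_dict(state)

    # -- forward pieces ----------------------------------------------------
    def preprocess(self, images) -> Tensor:
        """uint8 HxWx3 image or NxHxWx3 batch -> normalised (N,3,H,W) tensor."""
        arr = np.asarray(images)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ValueError(f"expected (N,)HxWx3 images, got shape {arr.shape}")
        if arr.shape[1] < 32 or arr.shape[2] < 32:
            raise ValueError("images must be at least 32x32 after resize")
        x = arr.astype(nn.DTYPE) / 255.0
        x = (x - 0.5) / 0.25
        return Tensor(np.ascontiguousarray(x.transpose(0, 3, 1, 2)))

    def forward_backbone(self, x: Tensor) -> Tensor:
        return self.backbone(x)

    def forward_scene(self, f_b: Tensor, out_hw: tuple):
        f_s = self.scene_head(f_b)
        seg = self.scene_module(f_s, out_hw)
        return f_s, seg

    def forward_instrument(self, f_b: Tensor):
        if self.instrument_head is None:
            raise ValueError("instrument branch is disabled (num_instruments=0)")
        f_i = self.instrument_head(f_b)
        presence = ad.sigmoid(self.instrument_fc(ad.global_avg_pool(f_i)))
        return f_i, presence

    def forward_phase(self, f_b: Tensor, f_s: Tensor | None, f_i: Tensor | None = None):
        """Fuse branch features and classify the phase.

        With ``f_s=None`` the forward is single-task: only the phase feature
        enters the fusion (its own fast-norm coefficient still applies)."""
        f_p = self.phase_head(f_b)
        if f_s is None:
            if not isinstance(self.fusion, FastNormalizedFusion):
                raise ValueError("single-task forward requires fast_norm fusion")
            a = ad.relu(self.fusion.alphas[1])
            fused = f_p * (a * ad.power(a + self.fusion.epsilon, -1.0))
        else:
            feats = [f_s, f_p]
            if self.config.num_instruments > 0:
                if f_i is None:
                    raise ValueError("instrument branch enabled but f_I not provided")
                feats.append(f_i)
            fused = self.fusion(feats)
            if self.config.use_skip:
                fused = fused + f_p
        phase = ad.softmax(self.fc(ad.global_avg_pool(fused)), axis=-1)
        return fused, phase

    def forward(self, images, with_scene: bool = True,
                with_instrument: bool | None = None, with_seg: bool = True):
        """Full multi-task forward pass; returns a dict of every intermediate.

        ``with_scene=False`` runs the single-task phase path (scene branch not
        evaluated).  ``with_seg=False`` computes the scene feature map for the
        fusion but skips the segmentation decoder (enough for phase prediction
        and feature extraction).  ``with_instrument`` defaults to whether the
        branch exists.
        """
        x = self.preprocess(images)
        out_hw = (x.data.shape[2], x.data.shape[3])
        f_b = self.forward_backbone(x)
        result = {"f_B": f_b}
        if with_instrument is None:
            with_instrument = self.config.num_instruments > 0
        f_i = None
        if with_instrument:
            f_i, presence = self.forward_instrument(f_b)
            result["f_I"] = f_i
            result["instrument"] = presence
        if with_scene and with_seg:
            f_s, seg = self.forward_scene(f_b, out_hw)
            result["f_S"] = f_s
            result["seg"] = seg
        elif with_scene:
            f_s = self.scene_head(f_b)
            result["f_S"] = f_s
        else:
            f_s = None
        fused, phase = self.forward_phase(f_b, f_s, f_i)
        result["f"] = fused
        result["phase"] = phase
        return result


# ---------------------------------------------------------------------------
# spec-level functional surface
# ---------------------------------------------------------------------------

def build_encoder(config: EncoderConfig) -> Encoder:
    """Construct the multi-task encoder; raises on invalid configuration."""
    return Encoder(config)


def forward_scene(encoder: Encoder, image):
    """image -> (scene feature map f_S, per-pixel class distribution)."""
    x = encoder.preprocess(image)
    f_b = encoder.forward_backbone(x)
    return encoder.forward_scene(f_b, (x.data.shape[2], x.data.shape[3]))


def forward_phase(encoder: Encoder, f_b, f_s, f_i=None):
    return encoder.forward_phase(f_b, f_s, f_i)


def forward_instrument(encoder: Encoder, f_b):
    return encoder.forward_instrument(f_b)


def extract_frame_feature(encoder: Encoder, image) -> np.ndarray:
    """Global-average-pooled fused feature, before the fully connected layer.

    Deterministic for fixed weights; run with the encoder in eval mode.
    Returns (D,) for a single image, (N, D) for a batch.
    """
    single = np.asarray(image).ndim == 3
    out = encoder.forward(image, with_scene=True, with_seg=False)
    feat = ad.global_avg_pool(out["f"]).data
    return feat[0] if single else feat


# ---------------------------------------------------------------------------
# checkpoint i/o: one .npz of arrays + a JSON sidecar with the config
# ---------------------------------------------------------------------------

def save_encoder(encoder: Encoder, path):
    path = Path(path)
    np.savez(path, **encoder.state_dict())
    cfg = dataclasses.asdict(encoder.config)
    cfg["input_size"] = list(cfg["input_size"])
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(cfg, indent=2))


def load_encoder(path) -> Encoder:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg = json.loads(sidecar.read_text())
    cfg["input_size"] = tuple(cfg["input_size"])
    encoder = Encoder(EncoderConfig(**cfg))
    with np.load(path) as data:
        encoder.load_state_dict(dict(data))
    return encoder
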