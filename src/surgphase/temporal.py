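"""Multi-stage dilated causal temporal convolutional network.

Each stage is a stack of dilated residual layers (dilation doubling per
layer, causal left padding) built solely from 1-D convolutions — no pooling,
no fully connected layers — so the per-frame feature dimension is constant
and the parameter count is independent of the sequence length.  Stage s > 1
refines the softmax output of stage s-1.  Output row t depends on input rows
0..t only, which is what makes the model usable intra-operatively.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


@dataclasses.dataclass
class TCNConfig:
    """Defaults follow the standard multi-stage TCN settings: two stages of
    nine dilated layers (dilations 2^0 .. 2^8), 64 hidden channels, kernel 3."""

    input_dim: int = 2048
    num_phases: int = 7
    num_stages: int = 2
    layers_per_stage: int = 9
    hidden_channels: int = 64
    kernel_size: int = 3
    seed: int = 0

    def validate(self):
        if min(self.num_stages, self.layers_per_stage, self.hidden_channels,
               self.input_dim) < 1:
            raise ValueError("TCN dimensions must be positive")
        if self.num_phases < 2:
            raise ValueError("num_phases must be >= 2")
        if self.kernel_size < 2:
            raise ValueError("kernel_size must be >= 2")


class DilatedResidualLayer(nn.Module):
    def __init__(self, channels, kernel, dilation, rng=None):
        super().__init__()
        self.conv_dilated = nn.Conv1dCausal(channels, channels, kernel, dilation, rng=rng)
        self.conv_out = nn.Conv1dCausal(channels, channels, 1, rng=rng)

    def forward(self, x):
        return x + self.conv_out(ad.relu(self.conv_dilated(x)))


class TCNStage(nn.Module):
    def __init__(self, in_dim, config: TCNConfig, rng=None):
        super().__init__()
        h = config.hidden_channels
        self.conv_in = nn.Conv1dCausal(in_dim, h, 1, rng=rng)
        self.layers = [DilatedResidualLayer(h, config.kernel_size, 2 ** i, rng=rng)
                       for i in range(config.layers_per_stage)]
        self.conv_out = nn.Conv1dCausal(h, config.num_phases, 1, rng=rng)

    def forward(self, x):
        x = self.conv_in(x)
        for layer in self.layers:
            x = layer(x)
        return ad.softmax(self.conv_out(x), axis=1)


class TCN(nn.Module):
    """features (T, D) -> one row-stochastic (T, P) sequence per stage."""

    def __init__(self, config: TCNConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.stages = [TCNStage(config.input_dim if s == 0 else config.num_phases,
                                config, rng=rng)
                       for s in range(config.num_stages)]

    def forward(self, features) -> list[Tensor]:
        feats = features if isinstance(features, Tensor) else Tensor(features)
        if feats.data.ndim != 2:
            raise ValueError(f"expected (T, D) features, got shape {feats.data.shape}")
        t, d = feats.data.shape
        if d != self.config.input_dim:
            raise ValueError(f"feature dim {d} does not match config input_dim "
                             f"{self.config.input_dim}")
        x = ad.reshape(ad.transpose(feats, (1, 0)), (1, d, t))
        outputs = []
        for stage in self.stages:
            probs = stage(x)  # (1, P, T)
            outputs.append(ad.reshape(ad.transpose(probs, (0, 2, 1)), (t, -1)))
            x = probs
        return outputs


@dataclasses.dataclass
class ReceptiveField:
    per_stage: int
    total: int


def build_tcn(config: TCNConfig) -> TCN:
    return TCN(config)


def tcn_forward(tcn: TCN, features) -> list[Tensor]:
    """Run all stages; the final list entry is the model's prediction."""
    return tcn(features)


def save_tcn(tcn: TCN, path):
    import json
    from pathlib import Path
    path = Path(path)
    np.savez(path, **tcn.state_dict())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(dataclasses.asdict(tcn.config), indent=2))


def load_tcn(path) -> TCN:
    import json
    from pathlib import Path
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    cfg = TCNConfig(**json.loads(path.with_suffix(path.suffix + ".json").read_text()))
    tcn = TCN(cfg)
    with np.load(path) as data:
        tcn.load_state_dict(dict(data))
    return tcn


def receptive_field(config: TCNConfig) -> ReceptiveField:
    """Closed-form causal receptive field in frames.

    One stage of L layers with kernel k and dilations 2^0..2^{L-1} sees
    1 + (k-1)(2^L - 1) frames; stacked stages compose additively minus the
    overlap: total = 1 + num_stages * (k-1) * (2^L - 1).
    """
    config.validate()
    k, L = config.kernel_size, config.layers_per_stage
    per_stage = 1 + (k - 1) * (2 ** L - 1)
    total = 1 + config.num_stages * (k - 1) * (2 ** L - 1)
    return ReceptiveField(per_stage=per_stage, total=total)
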