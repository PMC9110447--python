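import numpy as np
import pytest

from surgphase import encoder as enc
from surgphase import io, synthetic


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest sensible multi-task encoder: depth-18 at base_width 4."""
    return enc.EncoderConfig(backbone_depth=18, num_phases=5, num_scene_classes=6,
                             input_size=(64, 48), base_width=4, seed=7)


@pytest.fixture(scope="session")
def tiny_encoder(tiny_config):
    return enc.build_encoder(tiny_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_split():
    """A small synthetic dataset shared across tests (8 videos of 40 frames)."""
    spec = synthetic.SynthSpec(num_videos=8, frames_per_video=40,
                               num_mask_videos=3, seed=11)
    return spec, synthetic.generate_dataset(spec)


@pytest.fixture(scope="session")
def small_records(small_split):
    _, split = small_split
    train = [io.VideoRecord.from_synthetic(v) for v in split.train]
    test = [io.VideoRecord.from_synthetic(v) for v in split.test]
    return train, test
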