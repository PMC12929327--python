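import numpy as np
import pytest

from metacvs.backbone import tiny_config
from metacvs.dataset_io import LabeledFrameClip
from metacvs.synthetic import SceneConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_cfg():
    return tiny_config()


@pytest.fixture
def clip_factory(tiny_cfg):
    """Random clips shaped for the tiny profile."""
    rng = np.random.default_rng(1234)

    def make(dual: bool, cfg=None, procedure="p0", t=0):
        cfg = cfg or tiny_cfg
        frames = rng.random((cfg.frame_length, cfg.input_size, cfg.input_size, 3))
        mask = (rng.integers(0, cfg.n_classes, (cfg.input_size, cfg.input_size))
                if dual else None)
        criteria = tuple(bool(x) for x in rng.integers(0, 2, 3))
        return LabeledFrameClip(frames, criteria, mask, procedure, t)

    return make


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small synthetic dataset on disk, shared across tests."""
    out = tmp_path_factory.mktemp("synth")
    cfg = SceneConfig(n_procedures=8, frames_per_procedure=8,
                      dual_label_fraction=0.3, seed=5)
    records = generate_dataset(cfg, out)
    return cfg, out, records
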