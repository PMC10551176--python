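import numpy as np
import pytest

from smokeformer.synthetic_data import SynthConfig, build_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A 50-image 64x64 dataset (40 train / 10 test, 4:1 in each split)."""
    out = tmp_path_factory.mktemp("tiny_ds")
    cfg = SynthConfig.reduced(total=50, size=64, seed=7)
    manifest = build_dataset(cfg, str(out))
    return cfg, manifest
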