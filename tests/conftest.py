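import numpy as np
import pytest

from mgaca.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_synth_config():
    return SynthConfig(n_volumes=6, slices_per_volume=(3, 5),
                       image_size=(64, 64), control_fraction=0.5,
                       roi_size_range=(12, 28), seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_synth_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("synth")
    manifest = generate_dataset(tiny_synth_config, out)
    return out, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
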