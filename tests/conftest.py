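import numpy as np
import pytest

from dspmcf import SynthConfig, generate
from dspmcf.graph import ElectrodeGraph


@pytest.fixture(scope="session")
def tiny_dataset():
    """3 subjects, 16 channels, 5 bands, 3 classes, 8 time steps."""
    cfg = SynthConfig(
        n_subjects=3,
        n_channels=16,
        n_bands=5,
        n_classes=3,
        time_steps=8,
        samples_per_subject_per_class=12,
        class_separation=3.0,
        subject_shift_scale=0.3,
        noise_sd=0.3,
        spatial_length_scale=0.6,
        rng_seed=3,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def tiny_graph(tiny_dataset):
    return ElectrodeGraph.from_coords(np.asarray(tiny_dataset.coords))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
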