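import numpy as np
import pytest

from melafuse.bleach import extract_curve
from melafuse.simgen import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def clean_records():
    """Small noise-free dataset: exact decay curves, exact channel means."""
    config = SynthConfig(
        n_per_class=4, image_size=16, n_channels=4, noise_sd=0.0,
        decay_rates=(0.5, 0.25, 0.05), seed=123,
    )
    return config, generate_dataset(config)


@pytest.fixture(scope="session")
def noisy_records():
    """Default-condition dataset used by feature/selection tests."""
    config = SynthConfig(n_per_class=20, image_size=16, n_channels=3, seed=7)
    return config, generate_dataset(config)


@pytest.fixture(scope="session")
def noisy_curves(noisy_records):
    config, records = noisy_records
    curves = [
        extract_curve(r.frames, r.lesion_mask, expected_len=config.n_frames,
                      lesion_id=r.record_id)
        for r in records
    ]
    labels = np.array([r.label.index for r in records])
    return curves, labels
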