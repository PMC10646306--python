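import numpy as np
import pandas as pd
import pytest

from scenevep import synth
from scenevep.model import ArchitectureSpec
from scenevep.preprocess import EpochSet


@pytest.fixture(scope="session")
def tiny_stimuli():
    """26 surrogate images, 2 per category, with their stimulus table."""
    return synth.generate_stimulus_set(n_per_category=2, seed=1)


@pytest.fixture(scope="session")
def four_class_effects():
    return synth.planted_category_effects(
        ("office", "city", "coast", "mountain"),
        amplitude_uv=15.0, noise_sd=2.0, blink_rate=5.0)


@pytest.fixture()
def tiny_arch():
    """A shrunken architecture for fast training tests: same layer stack,
    100 time points, 4 electrodes."""
    return ArchitectureSpec(n_channels=4, n_times=100, conv1_filters=4,
                            conv1_kernel=16, conv1_pad=8, conv2_filters=6,
                            pool2=2, conv3_kernel=8, conv3_pad=4, pool3=4)


def make_epochset(data, image_ids, participant_ids=None, time_ms=None,
                  channels=None, rejected=None):
    """Assemble an EpochSet from arrays (test helper)."""
    n = data.shape[0]
    if channels is None:
        from scenevep.montage import CHANNELS_19
        channels = CHANNELS_19[: data.shape[1]]
    if time_ms is None:
        time_ms = np.arange(-400, 800)[: data.shape[2]]
    trials = pd.DataFrame({
        "image_id": image_ids,
        "participant_id": participant_ids or ["P00"] * n,
        "repetition": list(range(n)),
        "rejected": rejected if rejected is not None else [False] * n,
        "reason": [""] * n,
    })
    return EpochSet(data=np.asarray(data, np.float32),
                    time_ms=np.asarray(time_ms), channels=tuple(channels),
                    trials=trials)
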