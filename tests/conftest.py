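import numpy as np
import pytest

import cuestate as cs


def rle_oracle(labels, boundaries=None):
    """Independent run-length encoder: list of (label, length, start, end).

    Runs are split at the given epoch boundaries. Deliberately naive
    (pure-python loop) so it cannot share bugs with the vectorised
    implementation under test.
    """
    labels = list(labels)
    bset = set() if boundaries is None else set(int(b) for b in boundaries)
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[i - 1] or i in bset:
            runs.append((labels[start], i - start, start, i))
            start = i
    return runs


@pytest.fixture(scope="session")
def montage():
    return cs.standard_64_montage()


@pytest.fixture(scope="session")
def truth(montage):
    return cs.default_ground_truth(seed=11, montage=montage)


@pytest.fixture(scope="session")
def small_recording(truth):
    """One noiseless-ish smoking block: 1 trial x 20 s at 250 Hz."""
    return cs.generate_recording(truth, None, "smoking", n_trials=1, trial_s=20.0, seed=5)


def make_epochset(data_3d, srate=250.0, names=None):
    data_3d = np.asarray(data_3d, float)
    if names is None:
        names = tuple(f"ch{i}" for i in range(data_3d.shape[1]))
    return cs.EpochSet(
        epochs=data_3d,
        srate=srate,
        channel_names=tuple(names),
        kept_mask=np.ones(data_3d.shape[0], dtype=bool),
    )
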