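import numpy as np
import pytest

from alphakit import synth_eeg


@pytest.fixture(scope="session")
def montage16():
    return synth_eeg.make_symmetric_montage(16)


@pytest.fixture(scope="session")
def montage32():
    return synth_eeg.make_symmetric_montage(32)


@pytest.fixture(scope="session")
def cluster_idx(montage16):
    return {s: montage16.cluster_indices(s) for s in ("left", "right")}


@pytest.fixture(scope="session")
def both_clusters(cluster_idx):
    return np.concatenate([cluster_idx["left"], cluster_idx["right"]])
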