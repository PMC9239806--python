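import numpy as np
import pytest

from mpvit.synth import desk_spec, generate_dataset
from mpvit.train import load_split_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_dataset(tmp_path_factory):
    """Small separable synthetic dataset shared by the training-level tests."""
    root = tmp_path_factory.mktemp("desk_data")
    spec = desk_spec(seed=7, n_train_per_class=40, n_test_per_class=20)
    manifest = generate_dataset(spec, root)
    xtr, ytr = load_split_arrays(root, manifest, "train", 64)
    xte, yte = load_split_arrays(root, manifest, "test", 64)
    return {
        "root": root, "spec": spec, "manifest": manifest,
        "xtr": xtr, "ytr": ytr, "xte": xte, "yte": yte,
    }
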