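import numpy as np
import pytest

from misnet import ModelSpec, TrainConfig, build_model
from misnet.features import DEFeatures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_spec():
    """A small but structurally complete model: 3 sources, 3 classes."""
    return ModelSpec(n_sources=3, n_classes=3, common_widths=(10, 8, 6),
                     branch_widths=(6, 4), seed=7)


@pytest.fixture
def toy_state(toy_spec):
    return build_model(toy_spec)


@pytest.fixture
def fast_config():
    """Config sized for seconds-scale training in unit tests."""
    return TrainConfig(lr=0.01, batch_size=16, epochs_main=3,
                       epochs_pretrain=3, seed=0, batches_per_iteration=2)


@pytest.fixture
def separable_domains(rng):
    """Three linearly separable 2-class domains in 10 dims, no shift."""
    domains = []
    w = rng.standard_normal(10)
    for d in range(3):
        X = rng.standard_normal((80, 10))
        y = (X @ w > 0).astype(int)
        X[y == 1] += 0.8 * w / np.linalg.norm(w)
        domains.append(DEFeatures(X, labels=y, subject_id=f"s{d}"))
    return domains
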