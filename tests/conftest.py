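import numpy as np
import pytest

from cssnn import (
    CSSNN,
    SyntheticSpec,
    TrainConfig,
    fit,
    gen_sparse_frames,
    train_test_split,
)

# Desk-scale study protocol: T=10 (the deployment timestep count), gentle
# per-epoch LR decay, batch 18, AdamW at 1e-3.
DESK_CFG = dict(epochs=30, lr_decay=0.9, batch_size=18, T=10, seed=3)
ARCH = "784-cs78-fc64-fc10"  # CR = 78/784 ~ 0.1


@pytest.fixture(scope="session")
def sparse_data():
    """Class-balanced synthetic sparse-frame task with a disjoint split."""
    X, y = gen_sparse_frames(SyntheticSpec(seed=3))
    return train_test_split(X, y, test_fraction=0.25, seed=3)


@pytest.fixture(scope="session")
def trained_cssnn(sparse_data):
    """A CSSNN trained at CR~0.1, Sample=20 under the desk protocol."""
    Xtr, ytr, _, _ = sparse_data
    model = CSSNN.build(ARCH, sample=20, T=10, seed=3)
    fit(model, Xtr, ytr, TrainConfig(**DESK_CFG))
    return model


@pytest.fixture(scope="session")
def trained_grm(sparse_data):
    """The compressed-learning baseline: frozen GRM encoder, same SNN."""
    Xtr, ytr, _, _ = sparse_data
    model = CSSNN.build(ARCH, encoder_kind="grm", T=10, seed=3)
    fit(model, Xtr, ytr, TrainConfig(**DESK_CFG))
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
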