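import numpy as np
import pytest

from mvmrmr.data import MultiViewDataset, View


def make_view(matrix, name="v", sample_ids=None, feature_names=None):
    matrix = np.asarray(matrix, dtype=float)
    if feature_names is None:
        feature_names = tuple(f"f{j}" for j in range(matrix.shape[1]))
    return View(
        name=name,
        matrix=matrix,
        feature_names=feature_names,
        sample_ids=sample_ids,
    )


def make_mvd(matrices, y, names=None):
    names = names or [f"v{i + 1}" for i in range(len(matrices))]
    views = tuple(
        make_view(m, name=n, feature_names=tuple(f"{n}_f{j}" for j in range(np.asarray(m).shape[1])))
        for m, n in zip(matrices, names)
    )
    return MultiViewDataset(views=views, labels=np.asarray(y))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def balanced_labels():
    """Deterministic balanced 0/1 labels for 30 samples."""
    y = np.zeros(30, dtype=int)
    y[::2] = 1
    return y


@pytest.fixture
def small_mvd(rng, balanced_labels):
    """Two small random views on [0,1] with one informative feature each."""
    y = balanced_labels
    m = len(y)
    X1 = rng.uniform(size=(m, 5))
    X2 = rng.uniform(size=(m, 4))
    X1[:, 1] = 0.2 + 0.6 * y + 0.05 * rng.normal(size=m)
    X2[:, 0] = 0.3 + 0.5 * y + 0.05 * rng.normal(size=m)
    X1 = np.clip(X1, 0, 1)
    X2 = np.clip(X2, 0, 1)
    return make_mvd([X1, X2], y)
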