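import numpy as np
import pytest

from fascal.feature_store import FeatureSet, LayerFeatureBank, ReferenceBank


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_class_1d():
    """Class A rows {-1, 1}, class B rows {1, 3}: means 0 and 2, global 1,
    within-variance 1, between-variance 1, mean between-class distance 2."""
    return FeatureSet(
        features=np.array([[-1.0], [1.0], [1.0], [3.0]]),
        labels=np.array([0, 0, 1, 1]),
        layer_id=1,
    )


def random_feature_set(rng, n_classes=3, per_class=5, dim=4, layer_id=0):
    labels = np.repeat(np.arange(n_classes), per_class)
    x = rng.normal(size=(labels.size, dim)) + 2.0 * rng.normal(
        size=(n_classes, dim)
    )[labels]
    return FeatureSet(features=x, labels=labels, layer_id=layer_id)


@pytest.fixture
def small_bank(rng):
    labels = np.repeat(np.arange(3), 4)
    layers = {}
    for lid, dim in [(1, 3), (2, 5)]:
        layers[lid] = FeatureSet(
            features=rng.normal(size=(labels.size, dim)).astype(np.float32),
            labels=labels,
            class_names=["a", "b", "c"],
            layer_id=lid,
        )
    return LayerFeatureBank(
        layers=layers,
        sample_ids=[f"s{i}" for i in range(labels.size)],
        class_names=["a", "b", "c"],
    )


@pytest.fixture
def reference_1d():
    return ReferenceBank(features=np.array([[0.0], [1.0], [10.0]]))
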