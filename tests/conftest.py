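import numpy as np
import pytest

from nemtie.data import LabeledFeatureTable


@pytest.fixture
def toy_table():
    """Tiny separable table: f0 equals the label, f1 is fixed noise."""
    rng = np.random.default_rng(7)
    C = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
    X = np.column_stack([C.astype(float), rng.standard_normal(10)])
    return LabeledFeatureTable(
        sample_ids=tuple(f"s{i}" for i in range(10)),
        feature_names=("perfect", "noise"),
        X=X,
        C=C,
    )


def make_table(X, C, names=None):
    X = np.asarray(X, dtype=float)
    names = names or tuple(f"f{j}" for j in range(X.shape[1]))
    return LabeledFeatureTable(
        sample_ids=tuple(f"s{i}" for i in range(X.shape[0])),
        feature_names=tuple(names),
        X=X,
        C=np.asarray(C, dtype=int),
    )


@pytest.fixture
def gaussian_table():
    """100 samples, 5 features; f0 is strongly class-shifted, rest are noise."""
    rng = np.random.default_rng(42)
    C = np.array([0, 1] * 50)
    X = rng.standard_normal((100, 5))
    X[:, 0] += 3.0 * C
    return make_table(X, C)
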