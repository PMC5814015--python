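import numpy as np
import pytest

from svmhdmr import (
    FeatureTable,
    SyntheticSpec,
    generate_synthetic,
    normalize_features,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(values, labels, names=None, **kwargs):
    values = np.asarray(values, dtype=float)
    if names is None:
        names = [f"x{i + 1}" for i in range(values.shape[1])]
    return FeatureTable(values=values, feature_names=list(names),
                        labels=np.asarray(labels), **kwargs)


@pytest.fixture
def planted_table():
    """159x24 normalized table with 6 correlated informative features."""
    k, n = 6, 24
    corr = np.eye(n)
    corr[:k, :k] = 0.3
    np.fill_diagonal(corr, 1.0)
    spec = SyntheticSpec(
        n_samples=159,
        n_features=n,
        informative=tuple(range(k)),
        effect_weights=tuple(2.0 - 0.2 * i for i in range(k)),
        correlation=corr,
        label_noise=0.05,
        seed=7,
    )
    return normalize_features(generate_synthetic(spec))


@pytest.fixture
def separable_table(rng):
    """Linearly separable 2-feature table with a comfortable margin."""
    n = 40
    x = rng.standard_normal((n, 2))
    labels = np.where(x[:, 0] > 0, 1, -1)
    x[:, 0] += labels * 1.5  # push the classes apart
    return make_table(x, labels)


@pytest.fixture
def csv_factory(tmp_path):
    def write(name, header, rows):
        path = tmp_path / name
        lines = [",".join(header)]
        lines += [",".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return write
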