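import numpy as np
import pytest

import accmode as am


@pytest.fixture
def small_separable_table():
    """Featurized separable scenario, small enough for fast unit tests."""
    raw = am.generate_dataset(am.separable(n_segments=90, seed=7))
    return am.compute_features(raw)


@pytest.fixture
def two_cloud_table():
    """Two well-separated Gaussian clouds (means +-5, unit variance)."""
    rng = np.random.default_rng(42)
    a = rng.normal(5.0, 1.0, size=(20, 3))
    b = rng.normal(-5.0, 1.0, size=(20, 3))
    values = np.vstack([a, b])
    labels = ["A"] * 20 + ["B"] * 20
    return am.FeatureTable(["f1", "f2", "f3"], values, labels)


@pytest.fixture
def raw_csv(tmp_path):
    """Write a tiny labeled 3-axis interleaved raw CSV and return its path."""
    path = tmp_path / "raw.csv"
    path.write_text(
        "1,2,3,4,5,6,Standing\n"
        "0.5,1.5,2.5,3.5,4.5,5.5,Flapping\n"
        "-1,-2,-3,1,2,3,Standing\n"
    )
    return path
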