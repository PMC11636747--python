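import numpy as np
import pytest

from csacfgd.head import StandInExtractor, extract_features
from csacfgd.synth import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_corpus():
    """50 images per class, the desk-scale study corpus."""
    return generate_dataset(GeneratorConfig(n_per_class=50, seed=7))


@pytest.fixture(scope="session")
def standin_extractor():
    return StandInExtractor(seed=0)


@pytest.fixture(scope="session")
def corpus_features(small_corpus, standin_extractor):
    """Frozen stand-in features and labels of the desk corpus."""
    X, y = extract_features(small_corpus, standin_extractor)
    return X, y


@pytest.fixture(scope="session")
def blob_features():
    """Linearly separable two-blob feature fixture (d=10, n=200)."""
    rng = np.random.default_rng(42)
    n = 100
    X0 = rng.normal(-2.0, 1.0, size=(n, 10))
    X1 = rng.normal(2.0, 1.0, size=(n, 10))
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n), np.ones(n)])
    order = rng.permutation(2 * n)
    return X[order], y[order]
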