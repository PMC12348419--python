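import numpy as np
import pytest

from transpred.feature_assembly import FeatureMatrix
from transpred.go_dataset import LabeledDataset
from transpred.synthetic import SyntheticSpec, gen_labeled_sequences


@pytest.fixture(scope="session")
def small_dataset():
    """27 labeled proteins (13/14) with strong class signal."""
    spec = SyntheticSpec(n_per_class=(13, 14), signal_strength=1.0, seed=7)
    proteins, tdis, labels = gen_labeled_sequences(spec)
    dataset = LabeledDataset(samples=sorted(labels.items()))
    return proteins, tdis, labels, dataset


@pytest.fixture(scope="session")
def carrier_dataset():
    """54 labeled proteins (26/28), matching the carrier task's shape."""
    spec = SyntheticSpec(n_per_class=(26, 28), signal_strength=1.0, seed=0)
    proteins, tdis, labels = gen_labeled_sequences(spec)
    dataset = LabeledDataset(samples=sorted(labels.items()))
    return proteins, tdis, labels, dataset


@pytest.fixture()
def random_matrix():
    rng = np.random.default_rng(42)
    n, d = 40, 30
    return FeatureMatrix(
        sample_ids=tuple(f"S{i:03d}" for i in range(n)),
        feature_names=tuple(f"f{j:03d}" for j in range(d)),
        values=rng.normal(size=(n, d)),
        feature_id="RAND",
    )
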