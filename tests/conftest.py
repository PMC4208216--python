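import numpy as np
import pytest

from wcesum.ensemble import LabeledDataset, train_ensemble
from wcesum.multifractal import extract_features
from wcesum.synthgen import SyntheticSpec, generate_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def capsule_sequence():
    """Default-sized synthetic capsule sequence with ground truth (fixed seed)."""
    return generate_sequence(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def small_sequence():
    """A quick 3-scene sequence on small frames for cheap pipeline tests."""
    spec = SyntheticSpec(n_scenes=3, copies_per_scene=4, noninformative_fraction=0.25, frame_size=(64, 64), seed=5)
    return generate_sequence(spec)


@pytest.fixture(scope="session")
def trained_frame_classifier():
    """Ensemble trained on a sequence disjoint (by seed) from every test sequence."""
    seq, truth = generate_sequence(SyntheticSpec(seed=100))
    X = np.stack([extract_features(f).e_alpha for f in seq.frames])
    y = np.array([int(t.is_informative) for t in truth])
    return train_ensemble(LabeledDataset(X, y), K=5, kernel="rbf", agg_rule="median", seed=7)
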