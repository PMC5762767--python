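import numpy as np
import pytest

from sdamll.datamodel import MultiLabelDataset
from sdamll.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def tiny_dataset():
    """Four instances, three labels, hand-written features in [0,1]."""
    return MultiLabelDataset(
        features=np.array(
            [
                [0.9, 0.1, 0.0, 0.2],
                [0.8, 0.2, 0.1, 0.0],
                [0.0, 0.9, 0.8, 0.1],
                [0.1, 0.0, 0.9, 0.7],
            ]
        ),
        labels=[{1}, {1, 2}, {2}, {3}],
        label_names=["pathA", "pathB", "pathC"],
        feature_names=["t1", "t2", "t3", "t4"],
        instance_ids=["g1", "g2", "g3", "g4"],
    )


@pytest.fixture(scope="session")
def small_signal_dataset():
    """Small separable synthetic corpus shared by training tests."""
    spec = SyntheticSpec(
        n_instances=120,
        n_labels=4,
        n_terms=60,
        signature_terms_per_label=10,
        labels_per_instance={1: 0.5, 2: 0.5},
        signal_strength=5.0,
        background_rate=0.05,
        seed=7,
    )
    return generate(spec)
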