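import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_training_features():
    """Cropped-cell features, 12 cells per class (shared across tests)."""
    from mitomorph.workflows import build_training_features

    return build_training_features(12, seed=11)


@pytest.fixture(scope="session")
def small_model(small_training_features):
    """Forest trained on the small training set (100 trees)."""
    from mitomorph.classify import train_rf
    from mitomorph.features import FEATURE_COLUMNS

    feats = small_training_features
    return train_rf(
        feats,
        feats["label"].to_numpy(),
        feats["batch"].to_numpy(),
        n_trees=100,
        seed=11,
        feature_names=list(FEATURE_COLUMNS),
    )


@pytest.fixture(scope="session")
def clean_image():
    """One noise-free fragmented-class multi-cell image with truth masks."""
    from mitomorph.simulate import generate_cell_image

    return generate_cell_image((0.0, 1.0, 0.0), 4, seed=5, noise=False)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
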