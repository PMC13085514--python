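import numpy as np
import pytest

from soildt50.features import FeatureMatrix


@pytest.fixture
def make_matrix():
    """Build a FeatureMatrix from a raw 2-D array."""

    def _make(X, names=None, ids=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, m = X.shape
        return FeatureMatrix(
            compound_ids=ids or [f"c{i}" for i in range(n)],
            feature_names=names or [f"f{j}" for j in range(m)],
            values=X,
        )

    return _make


@pytest.fixture(scope="session")
def small_synthetic():
    """A small deterministic synthetic data set shared across tests."""
    from soildt50.synthetic_data import SyntheticSpec, generate_compounds

    spec = SyntheticSpec(
        n_compounds=40,
        replicate_range=(3, 8),
        true_sigma_range=(0.2, 0.4),
        noise_sd=0.2,
        seed=1234,
    )
    return generate_compounds(spec)
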