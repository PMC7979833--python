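import numpy as np
import pytest

import rhodoscreen as rs


def make_encoded(X, y=None, ids=None, subfamily=None):
    """Wrap a design matrix (and optional responses) as EncodedSamples."""
    n = X.shape[0]
    ids = ids or [f"s{i:03d}" for i in range(n)]
    return [
        rs.EncodedSample(
            id=ids[i],
            x=np.asarray(X[i], dtype=float),
            lambda_max=None if y is None else float(y[i]),
            subfamily=subfamily,
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def small_sim():
    """Small synthetic dataset exercising the full encode->fit pipeline."""
    return rs.simulate_dataset(
        rs.SimulationSpec(
            n_train=120,
            n_candidates=15,
            n_pocket_positions=8,
            n_features=6,
            n_nonzero_coefficients=5,
            coefficient_scale=10.0,
            noise_sd=3.0,
            seed=3,
        )
    )


@pytest.fixture(scope="session")
def small_posterior(small_sim):
    cfg = rs.BlassoConfig(n_samples=800, burn_in=200, seed=7)
    return rs.fit_blasso(
        small_sim.train_encoded, cfg, standardizer=small_sim.standardizer
    )


@pytest.fixture()
def toy_feature_table():
    """2-feature table over the full alphabet (A=(1,2), G=(3,4), rest zeros)."""
    values = {aa: np.zeros(2) for aa in rs.encoding.AMINO_ACIDS}
    values["A"] = np.array([1.0, 2.0])
    values["G"] = np.array([3.0, 4.0])
    return rs.FeatureTable(feature_names=("f1", "f2"), values=values)
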