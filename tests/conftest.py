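import numpy as np
import pytest

from fabo.data_model import CandidatePool, PropertyOracle
from fabo.synthetic import SyntheticTaskSpec, make_pool


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_pool():
    """5 candidates, 4 features, with a group map."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((5, 4))
    names = ["geo_a", "geo_b", "chem_a", "chem_b"]
    groups = {"geo_a": "geometric", "geo_b": "geometric",
              "chem_a": "chemical", "chem_b": "chemical"}
    return CandidatePool(np.array([f"m{i}" for i in range(5)]), X, names, groups)


@pytest.fixture
def tiny_oracle(tiny_pool):
    vals = {i: float(v) for i, v in zip(tiny_pool.ids, [3.0, 1.0, 4.0, 1.5, 2.0])}
    return PropertyOracle(vals, "maximize")


@pytest.fixture(scope="session")
def small_task():
    """Small sparse-geometric task shared by campaign-level tests."""
    spec = SyntheticTaskSpec(
        n_candidates=300, n_geometric=8, n_chemical=40,
        task="sparse_geometric", n_informative_chemical=4, seed=13,
    )
    return make_pool(spec)
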