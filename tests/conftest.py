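import numpy as np
import pandas as pd
import pytest

from figp2 import SyntheticSpec, generate_synthetic, parse_formula


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def linear_data(rng):
    """Noiseless y = 0.5*logp + 6.9 over 50 rows."""
    X = pd.DataFrame({"logp": rng.uniform(-1, 4, 50)})
    y = 0.5 * X["logp"].to_numpy() + 6.9
    return X, y


@pytest.fixture
def rational_dataset():
    """Noisy two-feature dataset from a rational ground truth."""
    spec = SyntheticSpec(
        parse_formula("0.5*logp + 2/(tpsa + 1) + 6.5"),
        {"logp": (-1.0, 4.0), "tpsa": (0.0, 10.0)},
        n_samples=120,
        noise_sigma=0.1,
        seed=3,
    )
    return generate_synthetic(spec)


def random_trees(n, features, depth_range, seed, **kwargs):
    """A reproducible batch of random trees for property sweeps."""
    from figp2 import build_random_tree

    gen = np.random.default_rng(seed)
    return [build_random_tree(features, depth_range, gen, **kwargs) for _ in range(n)]
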