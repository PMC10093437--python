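import math

import numpy as np
import pytest

from ecvalidate import SyntheticSpec, generate_boundary_dataset


def brute_force_ec(a, b):
    """Independent oracle: literal enumeration of intersection and union."""
    a, b = set(a), set(b)
    union = set()
    for x in a:
        union.add(x)
    for x in b:
        union.add(x)
    inter = [x for x in a if x in b]
    if len(union) == 0:
        return math.nan
    return len(inter) / len(union)


@pytest.fixture(scope="session")
def boundary_ds():
    """Small two-Gaussian dataset shared by engine-level tests."""
    return generate_boundary_dataset(
        SyntheticSpec(n_samples=100, n_features=3, class_separation=2.0, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(20230401)
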